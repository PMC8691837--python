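"""Persistence: HDF5 event containers, FCS 3.1 scalar export, run configs.

The event container stores one matrix per waveform modality, columnar
scalar / fluorescence / label tables, and a provenance block (schema
version, config hash, seed, software version) sufficient to regenerate the
file.  Scalar channels additionally export to FCS 3.1 so conventional
cytometry software can read the simulated events.
"""

from __future__ import annotations

import hashlib
import json

from dataclasses import dataclass, field, fields as dc_fields

import h5py
import numpy as np
import yaml

from . import __version__
from .optics import NoiseModel, ScalarConfig
from .phantoms import ClassSpec, MorphologyParams, PopulationSpec
from .pipeline import OpticsConfig
from .signal_chain import AcquisitionConfig, Event

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "write_events",
    "read_events",
    "export_fcs",
    "load_config",
    "config_hash",
]

SCHEMA_VERSION = "1"
_STR = h5py.string_dtype(encoding="utf-8")


# ---------------------------------------------------------------------------
# event container


def write_events(
    events: list[Event], path, provenance: dict | None = None
) -> None:
    """Write events to an HDF5 container; lossless, bit-exact round trip."""
    if not events:
        raise ValueError("refusing to write an empty event list")
    n = len(events)
    modalities = sorted(events[0].waveforms)
    scalar_names = sorted(events[0].scalars)
    fluor_names = sorted(events[0].fluorescence)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["software_version"] = __version__
        f.attrs["n_events"] = n
        for key, value in (provenance or {}).items():
            f.attrs[f"provenance_{key}"] = value
        wf = f.create_group("waveforms")
        for m in modalities:
            wf.create_dataset(m, data=np.vstack([ev.waveforms[m] for ev in events]))
        sc = f.create_group("scalars")
        for s in scalar_names:
            sc.create_dataset(s, data=np.array([ev.scalars[s] for ev in events]))
        fl = f.create_group("fluorescence")
        for ch in fluor_names:
            fl.create_dataset(ch, data=np.array([ev.fluorescence[ch] for ev in events]))
        lab = f.create_group("labels")
        lab.create_dataset("event_id", data=np.array([ev.event_id for ev in events]))
        lab.create_dataset(
            "true", data=np.array([ev.true_class for ev in events], dtype=object), dtype=_STR
        )
        lab.create_dataset(
            "predicted",
            data=np.array([ev.predicted_class or "" for ev in events], dtype=object),
            dtype=_STR,
        )
        lab.create_dataset(
            "batch", data=np.array([ev.batch_id for ev in events], dtype=object), dtype=_STR
        )


def read_events(path) -> list[Event]:
    """Read a container back into Event records, validating schema and counts."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"container schema version {version!r} != supported {SCHEMA_VERSION!r}"
            )
        n = int(f.attrs["n_events"])
        waveforms = {m: f["waveforms"][m][...] for m in f["waveforms"]}
        scalars = {s: f["scalars"][s][...] for s in f["scalars"]}
        fluor = {c: f["fluorescence"][c][...] for c in f["fluorescence"]}
        ids = f["labels"]["event_id"][...]
        true = [t.decode() if isinstance(t, bytes) else t for t in f["labels"]["true"][...]]
        pred = [t.decode() if isinstance(t, bytes) else t for t in f["labels"]["predicted"][...]]
        batch = [t.decode() if isinstance(t, bytes) else t for t in f["labels"]["batch"][...]]
    sizes = (
        {w.shape[0] for w in waveforms.values()}
        | {v.size for v in scalars.values()}
        | {v.size for v in fluor.values()}
        | {ids.size, len(true), len(pred), len(batch)}
    )
    if sizes != {n}:
        raise ValueError(f"inconsistent group sizes {sizes} for declared n_events={n}")
    events = []
    for i in range(n):
        events.append(
            Event(
                event_id=int(ids[i]),
                waveforms={m: waveforms[m][i].copy() for m in waveforms},
                scalars={s: float(scalars[s][i]) for s in scalars},
                fluorescence={c: float(fluor[c][i]) for c in fluor},
                true_class=true[i],
                predicted_class=pred[i] or None,
                batch_id=batch[i],
            )
        )
    return events


# ---------------------------------------------------------------------------
# FCS 3.1 export (scalar channels only)


def export_fcs(events: list[Event], path) -> None:
    """Write scalar and fluorescence channels as a minimal FCS 3.1 file.

    Channels: FSC-H, FSC-W, FSC-A, SSC, BSC plus one channel per
    fluorescence color; 32-bit little-endian floats, list mode.
    """
    if not events:
        raise ValueError("no events to export")
    channel_map = [
        ("FSC-H", "fsc_height"),
        ("FSC-W", "fsc_width"),
        ("FSC-A", "fsc_area"),
        ("SSC", "ssc"),
        ("BSC", "bsc"),
    ]
    fluor_names = sorted(events[0].fluorescence)
    names = [n for n, _ in channel_map] + [f"FL-{c}" for c in fluor_names]
    data = np.array(
        [
            [ev.scalars[k] for _, k in channel_map]
            + [ev.fluorescence[c] for c in fluor_names]
            for ev in events
        ],
        dtype="<f4",
    )
    n_events, n_par = data.shape

    text: dict[str, str] = {
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        # fixed-width placeholders so the TEXT length is offset-independent
        "$BEGINDATA": "%012d",
        "$ENDDATA": "%012d",
    }
    for i, name in enumerate(names, start=1):
        rng_max = float(np.nanmax(data[:, i - 1])) if n_events else 1.0
        text[f"$P{i}N"] = name
        text[f"$P{i}B"] = "32"
        text[f"$P{i}E"] = "0,0"
        text[f"$P{i}R"] = str(int(max(rng_max, 1.0)) + 1)

    delim = "/"
    def render(begin_data: int, end_data: int) -> bytes:
        items = dict(text)
        items["$BEGINDATA"] = "%012d" % begin_data
        items["$ENDDATA"] = "%012d" % end_data
        body = delim + delim.join(f"{k}{delim}{v}" for k, v in items.items()) + delim
        return body.encode("ascii")

    header_len = 58
    text_start = header_len
    text_bytes = render(0, 0)
    text_end = text_start + len(text_bytes) - 1
    data_start = text_end + 1
    data_end = data_start + data.nbytes - 1
    text_bytes = render(data_start, data_end)
    assert text_end == text_start + len(text_bytes) - 1  # fixed-width fields keep length stable

    header = b"FCS3.1    " + "".join(
        f"{v:>8d}" for v in (text_start, text_end, data_start, data_end, 0, 0)
    ).encode("ascii")
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_bytes)
        fh.write(data.tobytes())


# ---------------------------------------------------------------------------
# pattern exchange (reproducibility: masks are plain CSV matrices)


def export_pattern_csv(pattern, path) -> None:
    np.savetxt(path, pattern.mask, delimiter=",", fmt="%.10g")


def import_pattern_csv(path, pitch: float = 0.5):
    from .optics import IlluminationPattern

    mask = np.atleast_2d(np.loadtxt(path, delimiter=","))
    pat = IlluminationPattern(mask=mask, pitch=pitch, fill_fraction=float(mask.mean()))
    pat.validate()
    return pat


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated top-level configuration for a simulated run."""

    population: PopulationSpec
    optics: OpticsConfig
    acquisition: AcquisitionConfig
    noise: NoiseModel
    seed: int
    raw: dict = field(default_factory=dict)


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in config section {name!r}")
    return cls(**section)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    allowed = {"population", "optics", "acquisition", "noise", "seed"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown top-level config keys {sorted(unknown)}")
    seed = int(raw.get("seed", 0))

    pop = dict(raw["population"])
    classes = []
    for cdef in pop.pop("classes"):
        cdef = dict(cdef)
        morph = _build(MorphologyParams, cdef.pop("morphology", {}), "morphology")
        classes.append(
            ClassSpec(
                name=cdef.pop("name"),
                morphology=morph,
                spread=cdef.pop("spread", {}),
                stain_amounts=cdef.pop("stain_amounts", {}),
                mixing_fraction=cdef.pop("mixing_fraction", 1.0),
            )
        )
        if cdef:
            raise ValueError(f"unknown class keys {sorted(cdef)}")
    pop.setdefault("seed", seed)
    if "canvas_shape" in pop:
        pop["canvas_shape"] = tuple(pop["canvas_shape"])
    population = _build(PopulationSpec, {**pop, "classes": tuple(classes)}, "population")
    population.validate()

    opt = dict(raw.get("optics", {}))
    if "modalities" in opt:
        opt["modalities"] = tuple(opt["modalities"])
    if "pattern_shape" in opt:
        opt["pattern_shape"] = tuple(opt["pattern_shape"])
    if "scalars" in opt:
        opt["scalars"] = _build(ScalarConfig, opt["scalars"], "optics.scalars")
    optics_cfg = _build(OpticsConfig, opt, "optics")
    acq = _build(AcquisitionConfig, dict(raw.get("acquisition", {})), "acquisition")
    acq.validate()
    noise_section = dict(raw.get("noise", {}))
    noise_section.setdefault("seed", seed)
    noise = _build(NoiseModel, noise_section, "noise")
    noise.validate()
    return RunConfig(
        population=population, optics=optics_cfg, acquisition=acq, noise=noise,
        seed=seed, raw=raw,
    )


def config_hash(raw: dict) -> str:
    """Stable hash of a configuration dict, for provenance blocks."""
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
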