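"""Compressive ghost-motion-imaging forward model.

A cell moving through a static structured-illumination mask H produces a 1D
temporal waveform: at each sample the single-pixel detector integrates the
product of the mask and the cell's contrast map, translated one pixel per
sample along the flow axis.  The waveform is therefore the column-summed
'full' cross-correlation of mask and map — a linear, shift-equivariant
measurement whose exact discrete form admits a brute-force oracle.

Scalar channels (FSC pulse, SSC, BSC) and per-channel fluorescence
intensities emulate the low-content outputs of a conventional cytometer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IlluminationPattern",
    "ModalityConfig",
    "ScalarConfig",
    "NoiseModel",
    "RawSignal",
    "MODALITY_SOURCES",
    "generate_pattern",
    "gmi_waveform",
    "scalar_channels",
    "fluorescence_intensity",
    "add_noise",
]

#: which phantom contrast map each GMI modality reads; the modalities differ
#: by detection geometry (diffracted / side / back / forward scattered /
#: bright field), not by the measurement math.
MODALITY_SOURCES: dict[str, str] = {
    "dGMI": "transmission",
    "ssGMI": "scatter",
    "bsGMI": "scatter",
    "fsGMI": "transmission",
    "bfGMI": "absorption",
}


@dataclass(frozen=True)
class IlluminationPattern:
    """Structured-illumination mask H, flow extent F x lateral extent W."""

    mask: np.ndarray
    pitch: float = 0.5
    fill_fraction: float = 0.5
    seed: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def validate(self) -> None:
        if self.mask.ndim != 2 or min(self.mask.shape) < 1:
            raise ValueError("mask must be 2D with extents >= 1")
        if np.any(self.mask < 0) or np.any(self.mask > 1):
            raise ValueError("mask entries must lie in [0, 1]")


@dataclass(frozen=True)
class ModalityConfig:
    """Per-modality acquisition settings.

    With the default geometry the object translates exactly one pattern
    pixel per sample (sample_period = pitch / flow_speed), so the waveform
    is a pure discrete correlation.
    """

    modality: str = "dGMI"
    gain: float = 1.0
    background: float = 0.0
    flow_speed_um_s: float = 1.0e6
    pitch: float = 0.5
    n_fringes: int = 1

    @property
    def contrast_source(self) -> str:
        return MODALITY_SOURCES[self.modality]

    @property
    def sample_period_s(self) -> float:
        return self.pitch / self.flow_speed_um_s

    def validate(self) -> None:
        if self.modality not in MODALITY_SOURCES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.flow_speed_um_s <= 0 or self.pitch <= 0:
            raise ValueError("flow speed and pitch must be > 0")
        if self.n_fringes < 1:
            raise ValueError("n_fringes must be >= 1")


@dataclass(frozen=True)
class ScalarConfig:
    """Transfer settings for the conventional scalar channels."""

    fsc_gain: float = 1.0
    ssc_gain: float = 1.0
    bsc_gain: float = 0.9
    fluor_gain: float = 1.0
    fsc_strip: int = 8  # flow extent (rows) of the uniform FSC strip


@dataclass(frozen=True)
class NoiseModel:
    """Detection noise: scaled Poisson shot noise plus Gaussian read noise.

    shot_scale is the photon budget per signal unit: measured value is
    Poisson(shot_scale * x) / shot_scale, so larger shot_scale means less
    relative shot noise.  shot_scale = 0 disables shot noise.
    """

    shot_scale: float = 0.0
    read_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.shot_scale < 0 or self.read_sigma < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class RawSignal:
    """A single-channel sampled signal."""

    samples: np.ndarray
    sample_period: float
    channel: str = ""

    def validate(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"channel {self.channel!r} has non-finite samples")


def generate_pattern(
    flow_extent: int,
    lateral_extent: int,
    fill_fraction: float,
    seed: int,
    pitch: float = 0.5,
    n_fringes: int = 1,
) -> IlluminationPattern:
    """Draw an i.i.d. Bernoulli(fill_fraction) binary mask.

    With ``n_fringes > 1`` the mask is the average of that many independent
    Bernoulli sub-masks (several detector sub-apertures summed), yielding a
    graded mask still confined to [0, 1].
    """
    if flow_extent < 1 or lateral_extent < 1:
        raise ValueError("pattern extents must be >= 1")
    if not 0.0 < fill_fraction < 1.0:
        raise ValueError(f"fill_fraction must be in (0, 1), got {fill_fraction}")
    rng = np.random.default_rng(seed)
    sub = rng.random((n_fringes, flow_extent, lateral_extent)) < fill_fraction
    mask = sub.mean(axis=0).astype(float)
    pattern = IlluminationPattern(mask=mask, pitch=pitch, fill_fraction=fill_fraction, seed=seed)
    pattern.validate()
    return pattern


def gmi_waveform(
    contrast_map: np.ndarray,
    pattern: IlluminationPattern,
    cfg: ModalityConfig | None = None,
) -> RawSignal:
    """Simulate the waveform of one cell crossing the pattern.

    Sample t is ``gain * sum(mask * map shifted by t-(h-1) flow pixels)
    + background`` over the mask/map overlap; the output has F + h - 1
    samples (zero-padded entry and exit, full traversal recorded).
    """
    cfg = cfg or ModalityConfig()
    cfg.validate()
    pattern.validate()
    m = np.asarray(contrast_map, dtype=float)
    if m.ndim != 2:
        raise ValueError("contrast map must be 2D")
    if not np.all(np.isfinite(m)):
        raise ValueError("contrast map must be finite")
    h, w = m.shape
    F, W = pattern.shape
    if w > W:
        raise ValueError(f"map lateral width {w} exceeds pattern width {W}")

    # out[s + (h-1) - i] += mask[s, :w] . map[i, :]  for every mask row s
    inner = pattern.mask[:, :w] @ m.T  # (F, h)
    out = np.zeros(F + h - 1)
    for i in range(h):
        out[(h - 1) - i : (h - 1) - i + F] += inner[:, i]
    out = cfg.gain * out + cfg.background
    return RawSignal(samples=out, sample_period=cfg.sample_period_s, channel=cfg.modality)


def scalar_channels(
    phantom, cfg: ScalarConfig | None = None, sample_period: float = 1.0
) -> tuple[RawSignal, float, float]:
    """Conventional cytometer channels from a phantom.

    The FSC pulse is the flow-axis sliding average of transmission row-sums
    through a uniform strip of ``fsc_strip`` rows (so the pulse area equals
    fsc_gain times the total transmission — FSC area tracks projected cell
    size).  SSC and BSC are gain-scaled totals of the scatter map; BSC uses
    an independent gain but carries the same information as SSC.
    """
    cfg = cfg or ScalarConfig()
    transmission = phantom.contrast_maps["transmission"]
    scatter = phantom.contrast_maps["scatter"]
    row_sums = transmission.sum(axis=1)
    strip = np.full(cfg.fsc_strip, 1.0 / cfg.fsc_strip)
    pulse = cfg.fsc_gain * np.convolve(row_sums, strip, mode="full")
    fsc = RawSignal(samples=pulse, sample_period=sample_period, channel="FSC")
    ssc = float(cfg.ssc_gain * scatter.sum())
    bsc = float(cfg.bsc_gain * scatter.sum())
    return fsc, ssc, bsc


def fluorescence_intensity(
    phantom,
    channel: str,
    cfg: ScalarConfig | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Total fluorescence of one channel: gain * map total (+ optional noise)."""
    cfg = cfg or ScalarConfig()
    if channel not in phantom.fluorescence_maps:
        raise KeyError(f"unknown fluorescence channel {channel!r}")
    value = float(cfg.fluor_gain * phantom.fluorescence_maps[channel].sum())
    if noise is not None and (noise.shot_scale > 0 or noise.read_sigma > 0):
        sig = add_noise(
            RawSignal(samples=np.array([value]), sample_period=1.0, channel=channel),
            noise,
            rng=rng,
        )
        value = float(sig.samples[0])
    return value


def add_noise(
    signal: RawSignal, model: NoiseModel, rng: np.random.Generator | None = None
) -> RawSignal:
    """Apply the detection noise model; deterministic given model.seed.

    An explicit ``rng`` overrides the model seed (used by the pipeline to
    give every event its own derived stream).
    """
    model.validate()
    signal.validate()
    x = np.asarray(signal.samples, dtype=float)
    if rng is None:
        rng = np.random.default_rng(model.seed)
    if model.shot_scale > 0:
        if np.any(x < 0):
            raise ValueError("shot noise requires a nonnegative signal")
        x = rng.poisson(model.shot_scale * x).astype(float) / model.shot_scale
    if model.read_sigma > 0:
        x = x + rng.normal(0.0, model.read_sigma, size=x.shape)
    return RawSignal(samples=x, sample_period=signal.sample_period, channel=signal.channel)
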