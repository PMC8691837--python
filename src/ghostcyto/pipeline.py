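"""End-to-end simulation: population spec -> acquired Event stream.

For every phantom the pipeline draws the modality waveforms through their
illumination patterns, forms the scalar channels, applies detection noise
from a per-event derived stream, and runs the acquisition chain.  Phantoms
whose (noisy) FSC pulse never satisfies the trigger are counted as dropouts,
so every simulated cell becomes exactly one Event or one counted dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import optics, phantoms, signal_chain
from .optics import ModalityConfig, NoiseModel, RawSignal, ScalarConfig, generate_pattern
from .phantoms import CellPhantom, PopulationSpec, sample_population
from .signal_chain import AcquisitionConfig, Event, assemble_event

__all__ = ["OpticsConfig", "SimulationReport", "build_patterns", "acquire_phantom", "simulate_events"]


@dataclass(frozen=True)
class OpticsConfig:
    """Pattern geometry and modality set for one simulated instrument."""

    modalities: tuple[str, ...] = ("dGMI", "ssGMI")
    pattern_shape: tuple[int, int] = (128, 32)
    fill_fraction: float = 0.5
    pattern_seed: int = 7
    pitch: float = 0.5
    gain: float = 1.0
    background: float = 0.0
    n_fringes: int = 1
    scalars: ScalarConfig = field(default_factory=ScalarConfig)

    def validate(self) -> None:
        for m in self.modalities:
            if m not in optics.MODALITY_SOURCES:
                raise ValueError(f"unknown modality {m!r}")


@dataclass
class SimulationReport:
    """Events plus per-run accounting (conservation: n_in = n_events + n_dropout)."""

    events: list[Event]
    n_input: int
    n_dropout: int


def build_patterns(cfg: OpticsConfig) -> dict[str, optics.IlluminationPattern]:
    """One independent pattern per modality, seeded from cfg.pattern_seed."""
    cfg.validate()
    return {
        m: generate_pattern(
            cfg.pattern_shape[0],
            cfg.pattern_shape[1],
            cfg.fill_fraction,
            seed=cfg.pattern_seed + 101 * i,
            pitch=cfg.pitch,
            n_fringes=cfg.n_fringes,
        )
        for i, m in enumerate(cfg.modalities)
    }


def acquire_phantom(
    phantom: CellPhantom,
    patterns: dict[str, optics.IlluminationPattern],
    opt_cfg: OpticsConfig,
    acq_cfg: AcquisitionConfig,
    noise: NoiseModel,
    event_id: int,
    rng: np.random.Generator | None = None,
) -> Event | None:
    """Simulate one cell's acquisition; None when the trigger never fires."""
    n_total = opt_cfg.pattern_shape[0] + phantom.shape[0] - 1
    channels: dict[str, RawSignal] = {}
    for m, pattern in patterns.items():
        mc = ModalityConfig(
            modality=m, gain=opt_cfg.gain, background=opt_cfg.background, pitch=opt_cfg.pitch
        )
        channels[m] = optics.gmi_waveform(phantom.contrast_maps[mc.contrast_source], pattern, mc)

    fsc_pulse, ssc, bsc = optics.scalar_channels(phantom, opt_cfg.scalars)
    # pad FSC onto the common clock (all channels share t = 0 at cell entry)
    padded = np.zeros(n_total)
    padded[: fsc_pulse.samples.size] = fsc_pulse.samples
    channels["FSC"] = RawSignal(samples=padded, sample_period=fsc_pulse.sample_period, channel="FSC")

    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=noise.seed, spawn_key=(event_id,)))
    noisy = {k: optics.add_noise(v, noise, rng=rng) for k, v in channels.items()}

    scalars = {"ssc": ssc, "bsc": bsc}
    if noise.read_sigma > 0:
        scalars = {k: v + float(rng.normal(0.0, noise.read_sigma)) for k, v in scalars.items()}
    fluor = {
        ch: optics.fluorescence_intensity(phantom, ch, opt_cfg.scalars, noise=noise, rng=rng)
        for ch in phantom.fluorescence_maps
    }
    return assemble_event(
        noisy,
        acq_cfg,
        event_id=event_id,
        fluorescence=fluor,
        scalars=scalars,
        true_class=phantom.true_class,
        batch_id=phantom.batch_id,
    )


def simulate_events(
    spec: PopulationSpec,
    opt_cfg: OpticsConfig | None = None,
    acq_cfg: AcquisitionConfig | None = None,
    noise: NoiseModel | None = None,
) -> SimulationReport:
    """Simulate a whole population through the instrument.

    The population's ``noise_scale`` (set by batch effects) multiplies the
    read-noise amplitude and divides the photon budget, emulating a noisier
    acquisition for that batch.
    """
    opt_cfg = opt_cfg or OpticsConfig()
    acq_cfg = acq_cfg or AcquisitionConfig()
    noise = noise or NoiseModel(seed=spec.seed)
    if spec.noise_scale != 1.0:
        noise = NoiseModel(
            shot_scale=noise.shot_scale / spec.noise_scale if noise.shot_scale > 0 else 0.0,
            read_sigma=noise.read_sigma * spec.noise_scale,
            seed=noise.seed,
        )
    patterns = build_patterns(opt_cfg)
    events: list[Event] = []
    n_dropout = 0
    for i, phantom in enumerate(sample_population(spec)):
        ev = acquire_phantom(phantom, patterns, opt_cfg, acq_cfg, noise, event_id=i)
        if ev is None:
            n_dropout += 1
        else:
            events.append(ev)
    return SimulationReport(events=events, n_input=spec.n_events, n_dropout=n_dropout)
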