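"""Acquisition chain: raw channel signals -> aligned fixed-length Events.

Mirrors the electronics of a real instrument: DC removal with a single-pole
high-pass filter, a fixed trigger condition on the forward-scatter channel,
extraction of a fixed-length segment from every channel at the same time
window, and FSC pulse features (height / width / area) used downstream for
debris and doublet gating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .optics import RawSignal

__all__ = [
    "AcquisitionConfig",
    "Event",
    "highpass",
    "detect_trigger",
    "extract_segment",
    "pulse_features",
    "assemble_event",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Trigger, filtering and segmentation settings.

    The defaults give 128-sample segments with 8 samples of pre-trigger
    headroom, comfortably above the >100 samples a ghost-imaging waveform
    needs to carry image content.
    """

    highpass_alpha: float = 0.995
    trigger_threshold: float = 5.0
    trigger_min_run: int = 3
    segment_length: int = 128
    pre_trigger: int = 8
    width_fraction: float = 0.5

    def validate(self) -> None:
        if not 0.0 < self.highpass_alpha < 1.0:
            raise ValueError("highpass_alpha must be in (0, 1)")
        if self.trigger_min_run < 1:
            raise ValueError("trigger_min_run must be >= 1")
        if self.segment_length < 1:
            raise ValueError("segment_length must be >= 1")
        if not 0 <= self.pre_trigger < self.segment_length:
            raise ValueError("pre_trigger must be in [0, segment_length)")
        if not 0.0 < self.width_fraction < 1.0:
            raise ValueError("width_fraction must be in (0, 1)")


@dataclass
class Event:
    """One cell's complete multimodal record."""

    event_id: int
    waveforms: dict[str, np.ndarray]
    scalars: dict[str, float]
    fluorescence: dict[str, float]
    true_class: str = "unknown"
    predicted_class: str | None = None
    batch_id: str = "batch0"

    def validate(self) -> None:
        lengths = {len(w) for w in self.waveforms.values()}
        if len(lengths) > 1:
            raise ValueError(f"waveform lengths differ: {lengths}")
        for k, v in self.scalars.items():
            if not np.isfinite(v):
                raise ValueError(f"scalar {k!r} is not finite")


def highpass(signal: RawSignal, alpha: float) -> RawSignal:
    """Single-pole recursive high-pass: y[t] = alpha*(y[t-1] + x[t] - x[t-1]).

    Initialised with x[-1] = x[0] and y[-1] = 0, so a constant input maps to
    exactly zero from the first sample (exact DC rejection).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    x = np.asarray(signal.samples, dtype=float)
    if x.size == 0:
        raise ValueError("cannot filter an empty signal")
    # transfer function b = [a, -a], a = [1, -a]; initial state encodes x[-1]=x[0]
    y, _ = lfilter([alpha, -alpha], [1.0, -alpha], x, zi=np.array([-alpha * x[0]]))
    return RawSignal(samples=y, sample_period=signal.sample_period, channel=signal.channel)


def detect_trigger(fsc_signal: RawSignal, threshold: float, min_run: int) -> int | None:
    """First index starting a run of >= min_run samples strictly above threshold."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    above = np.asarray(fsc_signal.samples) > threshold
    if not above.any():
        return None
    # run-length encode the boolean mask
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            return int(s)
    return None


def extract_segment(
    signal: RawSignal, trigger_index: int, cfg: AcquisitionConfig
) -> np.ndarray:
    """Fixed-length window starting at trigger_index - pre_trigger, zero-padded.

    Every channel of an event is cut with the same window, so channels stay
    time-aligned.
    """
    cfg.validate()
    x = np.asarray(signal.samples, dtype=float)
    start = trigger_index - cfg.pre_trigger
    out = np.zeros(cfg.segment_length)
    lo = max(start, 0)
    hi = min(start + cfg.segment_length, x.size)
    if hi > lo:
        out[lo - start : hi - start] = x[lo:hi]
    return out


def pulse_features(fsc_segment: np.ndarray, width_fraction: float = 0.5) -> tuple[float, float, float]:
    """(height, width, area) of an FSC pulse.

    height = max sample; width = number of samples above width_fraction *
    height; area = sum.  An all-zero segment yields (0, 0, 0).
    """
    x = np.asarray(fsc_segment, dtype=float)
    if x.size == 0:
        raise ValueError("empty segment")
    height = float(x.max())
    if height <= 0:
        return 0.0, 0.0, float(x.sum())
    width = float(np.count_nonzero(x > width_fraction * height))
    return height, width, float(x.sum())


def assemble_event(
    channel_signals: dict[str, RawSignal],
    cfg: AcquisitionConfig,
    event_id: int,
    fluorescence: dict[str, float] | None = None,
    scalars: dict[str, float] | None = None,
    true_class: str = "unknown",
    batch_id: str = "batch0",
    filter_channels: bool = True,
) -> Event | None:
    """Run the chain on one cell's channel signals; None when no trigger fires.

    ``channel_signals`` must contain an "FSC" channel; all channels are
    high-pass filtered (unless ``filter_channels`` is False), the trigger is
    searched on the filtered FSC, and one aligned segment per non-FSC
    channel is stored as the event's waveforms.  FSC pulse features are
    computed from the FSC segment; extra scalars (SSC, BSC) and
    fluorescence intensities are attached unchanged.
    """
    cfg.validate()
    if "FSC" not in channel_signals:
        raise ValueError("an FSC channel is required for triggering")
    signals = dict(channel_signals)
    if filter_channels:
        signals = {k: highpass(v, cfg.highpass_alpha) for k, v in signals.items()}

    trigger = detect_trigger(signals["FSC"], cfg.trigger_threshold, cfg.trigger_min_run)
    if trigger is None:
        return None

    fsc_segment = extract_segment(signals["FSC"], trigger, cfg)
    height, width, area = pulse_features(fsc_segment, cfg.width_fraction)
    waveforms = {
        name: extract_segment(sig, trigger, cfg)
        for name, sig in signals.items()
        if name != "FSC"
    }
    all_scalars = {
        "fsc_height": height,
        "fsc_width": width,
        "fsc_area": area,
    }
    all_scalars.update(scalars or {})
    event = Event(
        event_id=event_id,
        waveforms=waveforms,
        scalars=all_scalars,
        fluorescence=dict(fluorescence or {}),
        true_class=true_class,
        batch_id=batch_id,
    )
    event.validate()
    return event
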