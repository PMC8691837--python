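"""Supervision machinery: scatter gates, fluorescence-threshold labels,
hierarchical gating schemes, and balanced / stratified train-test splits.

Conventions are fixed for determinism: polygon boundaries count as inside,
fluorescence thresholds are strict (> threshold is positive), and gates
operate on raw scalar values (log display is a rendering choice only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon

from .signal_chain import Event

__all__ = [
    "Gate",
    "GatingScheme",
    "LabelRule",
    "rectangle_gate",
    "apply_gate",
    "threshold_label",
    "hierarchical_gate",
    "balanced_split",
    "fraction_split",
]


def _feature(event: Event, name: str) -> float:
    if name in event.scalars:
        return event.scalars[name]
    if name in event.fluorescence:
        return event.fluorescence[name]
    raise KeyError(f"event {event.event_id} has no feature {name!r}")


@dataclass(frozen=True)
class Gate:
    """A simple polygon in a 2D scalar-feature plane."""

    name: str
    x_feature: str
    y_feature: str
    vertices: tuple[tuple[float, float], ...]

    def polygon(self) -> Polygon:
        poly = Polygon(self.vertices)
        if len(self.vertices) < 3 or not poly.is_valid:
            raise ValueError(f"gate {self.name!r} must be a simple polygon with >= 3 vertices")
        return poly


def rectangle_gate(name: str, x_feature: str, y_feature: str,
                   x_range: tuple[float, float], y_range: tuple[float, float]) -> Gate:
    (x0, x1), (y0, y1) = x_range, y_range
    return Gate(name, x_feature, y_feature, ((x0, y0), (x1, y0), (x1, y1), (x0, y1)))


@dataclass(frozen=True)
class GatingScheme:
    """Ordered (gate, action) list; action is "keep" or a class name.

    A "keep" gate discards events outside it; the first matching class gate
    assigns its class.  Events reaching the end unassigned are "ungated".
    """

    steps: tuple[tuple[Gate, str], ...]


@dataclass(frozen=True)
class LabelRule:
    """Binary fluorescence-threshold label: positive iff intensity > threshold."""

    channel: str
    threshold: float
    positive_class: str = "positive"
    negative_class: str = "negative"


def apply_gate(events: list[Event], gate: Gate) -> np.ndarray:
    """Boolean inclusion mask; boundary points count as inside."""
    poly = gate.polygon()
    mask = np.empty(len(events), dtype=bool)
    for i, ev in enumerate(events):
        p = Point(_feature(ev, gate.x_feature), _feature(ev, gate.y_feature))
        mask[i] = poly.covers(p)
    return mask


def threshold_label(events: list[Event], rule: LabelRule) -> np.ndarray:
    """Per-event class labels from a fluorescence threshold (strict >)."""
    labels = np.empty(len(events), dtype=object)
    for i, ev in enumerate(events):
        if rule.channel not in ev.fluorescence:
            raise KeyError(f"event {ev.event_id} has no fluorescence channel {rule.channel!r}")
        labels[i] = (
            rule.positive_class
            if ev.fluorescence[rule.channel] > rule.threshold
            else rule.negative_class
        )
    return labels


def hierarchical_gate(events: list[Event], scheme: GatingScheme) -> np.ndarray:
    """Ordered gating: first matching class gate wins; counts are conserved."""
    labels = np.full(len(events), "ungated", dtype=object)
    active = np.ones(len(events), dtype=bool)
    assigned = np.zeros(len(events), dtype=bool)
    for gate, action in scheme.steps:
        inside = apply_gate(events, gate)
        if action == "keep":
            active &= inside
        else:
            take = active & inside & ~assigned
            labels[take] = action
            assigned |= take
    return labels


def balanced_split(
    events: list[Event] | np.ndarray,
    labels: np.ndarray,
    n_train_per_class: int,
    n_test_per_class: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-per-class train/test index sets, sampled without replacement.

    Emulates a protocol of drawing a fixed number of cells per label with no
    overlap between training and test draws.
    """
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    need = n_train_per_class + n_test_per_class
    for cls in sorted(set(labels.tolist())):
        members = np.flatnonzero(labels == cls)
        if members.size < need:
            raise ValueError(
                f"class {cls!r} has {members.size} events, needs {need} for the split"
            )
        chosen = rng.choice(members, size=need, replace=False)
        train_idx.append(chosen[:n_train_per_class])
        test_idx.append(chosen[n_train_per_class:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def fraction_split(
    events: list[Event] | np.ndarray,
    labels: np.ndarray,
    train_fraction: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified split with per-class train size = round(fraction * size)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in sorted(set(labels.tolist())):
        members = np.flatnonzero(labels == cls)
        if members.size < 2:
            warnings.warn(f"class {cls!r} has < 2 events; sending all to train")
            train_idx.append(members)
            continue
        perm = rng.permutation(members)
        n_tr = int(round(train_fraction * members.size))
        n_tr = min(max(n_tr, 1), members.size - 1)
        train_idx.append(perm[:n_tr])
        test_idx.append(perm[n_tr:])
    test = np.concatenate(test_idx) if test_idx else np.array([], dtype=int)
    return np.sort(np.concatenate(train_idx)), np.sort(test)
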