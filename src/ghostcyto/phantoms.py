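"""Synthetic cell phantoms and mixed populations.

A phantom is a small stack of 2D pixel maps (transmission, scatter,
absorption, plus one map per fluorescence channel) standing in for one cell
as seen by the different optical contrasts of a ghost cytometer.  Populations
mix several morphology classes with per-class parameter spread, optional
batch (donor) effects, and fully seeded randomness so that a given
(spec, seed) pair always reproduces the same stream of phantoms.

The flow axis is always index 0 of every map: the cell moves along it when
it traverses the structured illumination.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "MorphologyParams",
    "CellPhantom",
    "ClassSpec",
    "PopulationSpec",
    "BatchEffect",
    "GeometryOverflowError",
    "make_phantom",
    "make_doublet",
    "sample_population",
    "apply_batch_effect",
]

#: fields of MorphologyParams that batch-effect drift may shift
_DRIFTABLE = (
    "diameter_um",
    "nucleus_fraction",
    "granularity",
    "eccentricity",
    "membrane_irregularity",
    "optical_density",
)


class GeometryOverflowError(ValueError):
    """The requested cell does not fit on the phantom canvas."""


@dataclass(frozen=True)
class MorphologyParams:
    """Stain-free morphological parameters of one cell.

    Parameters
    ----------
    diameter_um:
        Major-axis diameter of the cell body in micrometres (> 0).
    nucleus_fraction:
        Area fraction of the (denser) nucleus, in [0, 1].
    granularity:
        Amplitude of multiplicative speckle texture (>= 0); drives the
        variance of the scatter contrast and therefore SSC/BSC spread.
    eccentricity:
        Ellipse eccentricity of the cell body, in [0, 1).
    membrane_irregularity:
        Relative amplitude of low-order boundary perturbations (>= 0);
        models blebbing / apoptotic morphology.
    optical_density:
        Overall contrast scale of the cell body (>= 0).
    texture_seed:
        Extra entropy mixed into the texture random stream.
    """

    diameter_um: float = 10.0
    nucleus_fraction: float = 0.3
    granularity: float = 0.2
    eccentricity: float = 0.2
    membrane_irregularity: float = 0.0
    optical_density: float = 1.0
    texture_seed: int = 0

    def validate(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError(f"diameter_um must be > 0, got {self.diameter_um}")
        if not 0.0 <= self.nucleus_fraction <= 1.0:
            raise ValueError("nucleus_fraction must be in [0, 1]")
        if self.granularity < 0:
            raise ValueError("granularity must be >= 0")
        if not 0.0 <= self.eccentricity < 1.0:
            raise ValueError("eccentricity must be in [0, 1)")
        if self.membrane_irregularity < 0:
            raise ValueError("membrane_irregularity must be >= 0")
        if self.optical_density < 0:
            raise ValueError("optical_density must be >= 0")


@dataclass
class CellPhantom:
    """Multi-contrast pixel maps for one cell (flow axis = index 0)."""

    pixel_pitch: float
    contrast_maps: dict[str, np.ndarray]
    fluorescence_maps: dict[str, np.ndarray]
    true_class: str = "unknown"
    batch_id: str = "batch0"

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.contrast_maps.values())).shape

    def validate(self) -> None:
        shapes = {m.shape for m in self.contrast_maps.values()} | {
            m.shape for m in self.fluorescence_maps.values()
        }
        if len(shapes) != 1:
            raise ValueError(f"all phantom maps must share one shape, got {shapes}")
        for name, m in {**self.contrast_maps, **self.fluorescence_maps}.items():
            if np.any(m < 0):
                raise ValueError(f"map {name!r} has negative values")


@dataclass(frozen=True)
class ClassSpec:
    """One morphology class inside a population.

    ``morphology`` holds the per-field means; ``spread`` maps field name to a
    Gaussian standard deviation (unlisted fields have zero spread).
    ``stain_amounts`` gives the total fluorescence deposited per channel.
    """

    name: str
    morphology: MorphologyParams
    spread: dict[str, float] = field(default_factory=dict)
    stain_amounts: dict[str, float] = field(default_factory=dict)
    mixing_fraction: float = 1.0


@dataclass(frozen=True)
class BatchEffect:
    """Donor-to-donor variation applied to a whole population.

    gain_scale multiplies optical density (and hence every contrast map and
    downstream scalar), morphology_drift adds per-field shifts to the class
    means, and noise_scale multiplies the acquisition noise amplitude.
    """

    gain_scale: float = 1.0
    morphology_drift: dict[str, float] = field(default_factory=dict)
    noise_scale: float = 1.0

    def validate(self) -> None:
        if not self.gain_scale > 0:
            raise ValueError("gain_scale must be > 0")
        for k in self.morphology_drift:
            if k not in _DRIFTABLE:
                raise ValueError(f"unknown drift field {k!r}")


@dataclass(frozen=True)
class PopulationSpec:
    """A mixed population: classes, event count, seed, optional batch effect."""

    classes: tuple[ClassSpec, ...]
    n_events: int
    seed: int
    pixel_pitch: float = 0.5
    canvas_shape: tuple[int, int] = (64, 32)
    batch_id: str = "batch0"
    batch_effects: BatchEffect | None = None
    noise_scale: float = 1.0

    def validate(self) -> None:
        if len(self.classes) == 0:
            raise ValueError("population needs at least one class")
        if self.n_events <= 0:
            raise ValueError("n_events must be > 0")
        total = sum(c.mixing_fraction for c in self.classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixing fractions must sum to 1, got {total}")
        for c in self.classes:
            c.morphology.validate()


def _boundary_perturbation(theta: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-order radial perturbation with unit-normalised amplitude."""
    if amplitude == 0:
        return np.zeros_like(theta)
    orders = np.arange(3, 7)
    c = rng.standard_normal(orders.size)
    s = rng.standard_normal(orders.size)
    norm = math.sqrt(float(np.sum(c**2 + s**2))) or 1.0
    f = sum(
        c[k] * np.cos(m * theta) + s[k] * np.sin(m * theta)
        for k, m in enumerate(orders)
    )
    return amplitude * f / norm


def _speckle(shape: tuple[int, int], granularity: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean multiplicative gamma speckle with per-pixel sd = granularity."""
    if granularity == 0:
        return np.ones(shape)
    k = 1.0 / granularity**2
    return rng.gamma(shape=k, scale=1.0 / k, size=shape)


def make_phantom(
    params: MorphologyParams,
    pitch: float = 0.5,
    shape: tuple[int, int] = (64, 32),
    seed: int = 0,
    stain_amounts: dict[str, float] | None = None,
    true_class: str = "unknown",
    batch_id: str = "batch0",
) -> CellPhantom:
    """Render one cell phantom.

    The cell body is an ellipse with major axis ``diameter_um / pitch``
    pixels along the flow axis, perturbed radially by
    ``membrane_irregularity``.  The transmission map carries a denser
    nucleus, the scatter map carries unit-mean speckle whose variance grows
    with ``granularity``, and each fluorescence map integrates exactly to
    its stain amount.  Deterministic given (params, seed).
    """
    params.validate()
    if pitch <= 0:
        raise ValueError("pitch must be > 0")
    stain_amounts = dict(stain_amounts or {})

    F, W = shape
    a = params.diameter_um / (2.0 * pitch)  # semi-major (flow)
    b = a * math.sqrt(1.0 - params.eccentricity**2)  # semi-minor (lateral)
    margin = 1.0 + params.membrane_irregularity
    if 2 * a * margin > F or 2 * b * margin > W:
        raise GeometryOverflowError(
            f"cell of diameter {params.diameter_um} um (irregularity "
            f"{params.membrane_irregularity}) does not fit on a {F}x{W} canvas "
            f"at {pitch} um/px"
        )

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed), int(params.texture_seed)))
    )
    yy, xx = np.meshgrid(
        np.arange(F) - (F - 1) / 2.0, np.arange(W) - (W - 1) / 2.0, indexing="ij"
    )
    theta = np.arctan2(xx / max(b, 1e-9), yy / max(a, 1e-9))
    rho = np.sqrt((yy / a) ** 2 + (xx / b) ** 2)
    boundary = 1.0 + _boundary_perturbation(theta, params.membrane_irregularity, rng)
    support = rho <= boundary

    od = params.optical_density
    nucleus = rho <= math.sqrt(params.nucleus_fraction)  # area-fraction scaled

    def textured(base: np.ndarray) -> np.ndarray:
        # speckle redistributes intensity within the cell but conserves the
        # total, so scalar channels (map totals) stay texture-independent
        out = base * _speckle(shape, params.granularity, rng)
        total = out.sum()
        return out * (base.sum() / total) if total > 0 else out

    transmission = textured(np.where(support, od * (1.0 + 0.5 * nucleus), 0.0))
    scatter = textured(np.where(support, 0.5 * od, 0.0))
    absorption = 0.8 * transmission

    n_support = max(int(support.sum()), 1)
    fluor = {
        ch: np.where(support, amount / n_support, 0.0)
        for ch, amount in stain_amounts.items()
    }

    phantom = CellPhantom(
        pixel_pitch=pitch,
        contrast_maps={
            "transmission": transmission,
            "scatter": scatter,
            "absorption": absorption,
        },
        fluorescence_maps=fluor,
        true_class=true_class,
        batch_id=batch_id,
    )
    phantom.validate()
    return phantom


def make_doublet(a: CellPhantom, b: CellPhantom, flow_offset: int) -> CellPhantom:
    """Merge two phantoms into a doublet by shifting *b* along the flow axis.

    Emulates two cells traversing the interrogation region together; the
    resulting forward-scatter pulse is wider than a singlet's at matched
    height, which is the handle doublet gates use.
    """
    F, W = a.shape
    if b.shape != (F, W):
        raise ValueError("doublet partners must share canvas shape")

    def shift(m: np.ndarray) -> np.ndarray:
        out = np.zeros_like(m)
        if flow_offset >= 0:
            out[flow_offset:] = m[: F - flow_offset]
        else:
            out[:F + flow_offset] = m[-flow_offset:]
        return out

    contrast = {k: a.contrast_maps[k] + shift(b.contrast_maps[k]) for k in a.contrast_maps}
    channels = set(a.fluorescence_maps) | set(b.fluorescence_maps)
    zeros = np.zeros((F, W))
    fluor = {
        ch: a.fluorescence_maps.get(ch, zeros) + shift(b.fluorescence_maps.get(ch, zeros))
        for ch in channels
    }
    return CellPhantom(
        pixel_pitch=a.pixel_pitch,
        contrast_maps=contrast,
        fluorescence_maps=fluor,
        true_class="doublet",
        batch_id=a.batch_id,
    )


def _event_seed(spec_seed: int, index: int) -> np.random.SeedSequence:
    # counter-based per-event seeding: one SeedSequence per (population seed, event index)
    return np.random.SeedSequence(entropy=int(spec_seed), spawn_key=(int(index),))


def _draw_params(cls: ClassSpec, rng: np.random.Generator, index: int) -> MorphologyParams:
    values = dataclasses.asdict(cls.morphology)
    for fname, sd in cls.spread.items():
        if fname not in values:
            raise ValueError(f"unknown morphology field {fname!r}")
        values[fname] = float(values[fname]) + float(rng.normal(0.0, sd))
    values["diameter_um"] = max(values["diameter_um"], 1e-3)
    values["nucleus_fraction"] = float(np.clip(values["nucleus_fraction"], 0.0, 1.0))
    values["granularity"] = max(values["granularity"], 0.0)
    values["eccentricity"] = float(np.clip(values["eccentricity"], 0.0, 0.999))
    values["membrane_irregularity"] = max(values["membrane_irregularity"], 0.0)
    values["optical_density"] = max(values["optical_density"], 0.0)
    values["texture_seed"] = index
    return MorphologyParams(**values)


def sample_population(spec: PopulationSpec) -> Iterator[CellPhantom]:
    """Yield ``spec.n_events`` phantoms with class labels and batch ids.

    Class membership is multinomial in the mixing fractions; each event owns
    an independent random stream derived from (spec.seed, event index), so
    identical specs yield bitwise-identical streams.
    """
    spec.validate()
    fractions = np.array([c.mixing_fraction for c in spec.classes])
    class_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(spec.seed), spawn_key=(0xC1A55,))
    )
    assignments = class_rng.choice(len(spec.classes), size=spec.n_events, p=fractions)
    for i in range(spec.n_events):
        cls = spec.classes[int(assignments[i])]
        ss = _event_seed(spec.seed, i)
        rng = np.random.default_rng(ss)
        params = _draw_params(cls, rng, i)
        phantom_seed = int(rng.integers(0, 2**31 - 1))
        yield make_phantom(
            params,
            pitch=spec.pixel_pitch,
            shape=spec.canvas_shape,
            seed=phantom_seed,
            stain_amounts=cls.stain_amounts,
            true_class=cls.name,
            batch_id=spec.batch_id,
        )


def apply_batch_effect(spec: PopulationSpec, effect: BatchEffect, batch_id: str) -> PopulationSpec:
    """Return a copy of *spec* representing the same population from another batch.

    Class morphology means are shifted by ``morphology_drift``, optical
    density (and stains) scaled by ``gain_scale``, and the population's
    acquisition-noise multiplier set to ``noise_scale``.
    """
    effect.validate()
    new_classes = []
    for cls in spec.classes:
        values = dataclasses.asdict(cls.morphology)
        for fname, delta in effect.morphology_drift.items():
            values[fname] = float(values[fname]) + float(delta)
        values["optical_density"] = values["optical_density"] * effect.gain_scale
        stains = {ch: v * effect.gain_scale for ch, v in cls.stain_amounts.items()}
        new_classes.append(
            replace(cls, morphology=MorphologyParams(**values), stain_amounts=stains)
        )
    return replace(
        spec,
        classes=tuple(new_classes),
        batch_id=batch_id,
        batch_effects=effect,
        noise_scale=spec.noise_scale * effect.noise_scale,
    )
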