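"""Shipped benchmark populations and instrument settings.

These define the package's reference study conditions:

* ``two_class_spec`` — two size-matched cell lines that differ only in
  internal texture, one of them stained.  Their forward-scatter histograms
  overlap almost completely, so scalar channels barely separate them while
  the compressive waveforms do.  This is the desk-scale analog of
  classifying two morphologically similar cell lines by their stain-free
  waveforms.
* ``wbc_like_spec`` — a six-class population emulating a five-part white
  blood cell differential plus a rare (<10%) spiked progenitor class, with
  class-specific size, granularity, and optical density.

All parameters are fixed here, once; experiments consume these specs
unchanged so results are comparable across runs and seeds.
"""

from __future__ import annotations

import numpy as np

from .cnn import CnnConfig
from .gating import LabelRule
from .optics import NoiseModel
from .phantoms import ClassSpec, MorphologyParams, PopulationSpec
from .pipeline import OpticsConfig, simulate_events
from .signal_chain import AcquisitionConfig
from .svm import SvmConfig

__all__ = [
    "default_noise",
    "default_acquisition",
    "two_class_spec",
    "two_class_optics",
    "two_class_label_rule",
    "waveform_svm_config",
    "scalar_svm_config",
    "wbc_like_spec",
    "wbc_optics",
    "wbc_cnn_config",
    "simulate_benchmark",
]

# Detection noise: photon budget of 4 counts per signal unit (shot) plus
# half a signal unit of read noise — enough to blur per-sample values
# without drowning the texture signature the waveforms carry.
def default_noise(seed: int = 0) -> NoiseModel:
    return NoiseModel(shot_scale=4.0, read_sigma=0.5, seed=seed)


def default_acquisition() -> AcquisitionConfig:
    return AcquisitionConfig()


def two_class_spec(n_per_class: int = 1000, seed: int = 0) -> PopulationSpec:
    """Size-matched, texture-differing two-class mixture (50/50), one stained."""
    smooth = ClassSpec(
        name="line_a",
        morphology=MorphologyParams(
            diameter_um=10.0, nucleus_fraction=0.3, granularity=0.1,
            eccentricity=0.2, optical_density=1.0,
        ),
        spread={"diameter_um": 0.5, "optical_density": 0.05},
        stain_amounts={"green": 2.0},  # autofluorescence only
        mixing_fraction=0.5,
    )
    textured = ClassSpec(
        name="line_b",
        morphology=MorphologyParams(
            diameter_um=10.0, nucleus_fraction=0.3, granularity=0.7,
            eccentricity=0.2, optical_density=1.0,
        ),
        spread={"diameter_um": 0.5, "optical_density": 0.05},
        stain_amounts={"green": 200.0},
        mixing_fraction=0.5,
    )
    return PopulationSpec(
        classes=(smooth, textured), n_events=2 * n_per_class, seed=seed
    )


def two_class_optics() -> OpticsConfig:
    return OpticsConfig(modalities=("dGMI", "ssGMI"))


def two_class_label_rule() -> LabelRule:
    return LabelRule(channel="green", threshold=50.0,
                     positive_class="line_b", negative_class="line_a")


def waveform_svm_config(seed: int = 0) -> SvmConfig:
    """High-content route: the dGMI waveform segment (128 features)."""
    return SvmConfig(kernel="rbf", modality_set=("dGMI",), n_trials=10,
                     n_train_per_class=300, n_test_per_class=300, seed=seed)


def scalar_svm_config(seed: int = 0) -> SvmConfig:
    """Conventional baseline: a decision boundary in the FSC/SSC plane."""
    return SvmConfig(kernel="rbf", modality_set=("fsc_area", "ssc"), n_trials=10,
                     n_train_per_class=300, n_test_per_class=300, seed=seed)


_WBC_CLASSES = (
    # name, fraction, diameter, granularity, optical_density, nucleus
    ("neutrophil", 0.40, 12.0, 0.50, 1.00, 0.35),
    ("lymphocyte", 0.25, 7.0, 0.10, 0.90, 0.70),
    ("monocyte", 0.12, 15.0, 0.30, 1.00, 0.45),
    ("eosinophil", 0.10, 13.0, 0.80, 1.10, 0.35),
    ("basophil", 0.08, 10.0, 0.60, 1.20, 0.50),
    ("hsc", 0.05, 9.0, 0.15, 0.80, 0.60),
)


def wbc_like_spec(n_events: int = 1500, seed: int = 0) -> PopulationSpec:
    """Six-class differential with one rare (<10%) progenitor-like class."""
    classes = tuple(
        ClassSpec(
            name=name,
            morphology=MorphologyParams(
                diameter_um=d, nucleus_fraction=nuc, granularity=g,
                eccentricity=0.2, optical_density=od,
            ),
            spread={"diameter_um": 0.4, "optical_density": 0.04, "granularity": 0.03},
            mixing_fraction=frac,
        )
        for name, frac, d, g, od, nuc in _WBC_CLASSES
    )
    return PopulationSpec(classes=classes, n_events=n_events, seed=seed)


def wbc_like_balanced_spec(n_events: int = 1200, seed: int = 0) -> PopulationSpec:
    """The six wbc-like classes at equal mixing fractions.

    Used for controls that assume no majority class (e.g. the
    permutation-null chance check, where an imbalanced population lets a
    label-blind classifier collapse onto the most frequent class).
    """
    from dataclasses import replace

    base = wbc_like_spec(n_events=n_events, seed=seed)
    return replace(
        base, classes=tuple(replace(c, mixing_fraction=1 / 6) for c in base.classes)
    )


def wbc_optics() -> OpticsConfig:
    return OpticsConfig(modalities=("dGMI", "bsGMI", "fsGMI", "bfGMI"))


def wbc_cnn_config(seed: int = 0) -> CnnConfig:
    """Desk-scale training settings for the six-class benchmark.

    Keeps the recipe (5 conv blocks, Adam, categorical cross-entropy,
    patience 30, batch ceiling 1024) but raises the learning rate to 1e-3
    and caps epochs at 150: with ~1e3 events there are only a handful of
    optimizer steps per epoch, so the instrument-scale rate of 1e-5 would
    leave the weights essentially at initialization.  Channel widths are
    likewise halved relative to the package default — ample capacity for
    ~1e3 events at a fraction of the cost.
    """
    return CnnConfig(
        waveform_modalities=("dGMI", "bsGMI", "fsGMI", "bfGMI"),
        scalar_features=("fsc_area", "bsc"),
        n_classes=6,
        channels=(8, 16, 32, 32, 32),
        learning_rate=1e-3,
        max_epochs=150,
        patience=30,
        seed=seed,
    )


def simulate_benchmark(spec: PopulationSpec, optics: OpticsConfig, seed: int = 0):
    """Run a spec through the default instrument; returns (events, report)."""
    report = simulate_events(
        spec, optics, default_acquisition(), default_noise(seed=seed)
    )
    return report.events, report
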