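"""Linear-inversion image recovery from compressive waveforms.

This module certifies that the ghost-motion-imaging forward model preserves
image information: waveforms acquired under several independent illumination
patterns stack into a linear system A vec(object) = measurements, and with at
least pixel-count rows from independent Bernoulli patterns the object is
recovered exactly (noise-free) by least squares.  The classification pipeline
never reconstructs images — this is a validation oracle for the measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import IlluminationPattern

__all__ = ["SensingSystem", "sensing_matrix", "reconstruct_image"]

MAX_OBJECT_SIDE = 64  # dense solver; larger objects are out of scope


@dataclass
class SensingSystem:
    """Stacked measurement operator for a set of illumination patterns."""

    patterns: list[IlluminationPattern]
    object_shape: tuple[int, int]
    matrix: np.ndarray  # rows = sum of waveform lengths, cols = pixel count


def sensing_matrix(
    patterns: list[IlluminationPattern], object_shape: tuple[int, int]
) -> SensingSystem:
    """Build the operator whose product with vec(object) reproduces gmi_waveform.

    Row (p, t) holds the entries of pattern p's mask that overlap the object
    translated t - (h - 1) pixels along the flow axis.
    """
    h, w = object_shape
    if h > MAX_OBJECT_SIDE or w > MAX_OBJECT_SIDE:
        raise ValueError(f"object larger than {MAX_OBJECT_SIDE}x{MAX_OBJECT_SIDE} not supported")
    rows = []
    for pattern in patterns:
        pattern.validate()
        F, W = pattern.shape
        if w > W:
            raise ValueError(f"object width {w} exceeds pattern width {W}")
        for t in range(F + h - 1):
            row = np.zeros((h, w))
            for i in range(h):
                s = t - (h - 1) + i
                if 0 <= s < F:
                    row[i] = pattern.mask[s, :w]
            rows.append(row.ravel())
    return SensingSystem(patterns=list(patterns), object_shape=object_shape, matrix=np.vstack(rows))


def reconstruct_image(
    waveforms: np.ndarray, system: SensingSystem, ridge: float = 0.0
) -> np.ndarray:
    """Regularized least-squares inversion of the stacked waveforms.

    With ridge = 0 the system must have full column rank (otherwise an error
    advises regularization); with ridge > 0 the Tikhonov solution
    (A^T A + ridge I)^-1 A^T b is returned.
    """
    b = np.asarray(waveforms, dtype=float).ravel()
    A = system.matrix
    if b.size != A.shape[0]:
        raise ValueError(f"got {b.size} samples, sensing matrix has {A.shape[0]} rows")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    if ridge == 0.0:
        if np.linalg.matrix_rank(A) < A.shape[1]:
            raise ValueError(
                "sensing matrix is rank-deficient; use ridge > 0 or add patterns"
            )
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
    else:
        n = A.shape[1]
        x = np.linalg.solve(A.T @ A + ridge * np.eye(n), A.T @ b)
    return x.reshape(system.object_shape)
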