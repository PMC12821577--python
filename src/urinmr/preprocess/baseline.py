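"""Baseline correction by asymmetric least squares (AsLS).

A smooth baseline is estimated by penalised least squares with a
second-difference roughness penalty and asymmetric weights: points above
the current baseline (peaks) get weight ``asymmetry`` (≈0), points below
get ``1 - asymmetry`` (≈1), so the fit tracks the lower envelope of the
spectrum while ignoring peaks.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solveh_banded

from ..datatypes import Spectrum

__all__ = ["asls_baseline", "correct_baseline"]


def _penalty_banded(n: int, lam: float) -> np.ndarray:
    """Upper banded form (3 diagonals) of λ·D2'D2 for n points."""
    ab = np.zeros((3, n))
    ab[0, 2:] = lam  # second super-diagonal of D'D is 1
    d1 = np.zeros(n - 1)
    d1[0] = -2.0
    d1[-1] = -2.0
    d1[1:-1] = -4.0
    ab[1, 1:] = lam * d1
    d0 = np.full(n, 6.0)
    d0[0] = d0[-1] = 1.0
    d0[1] = d0[-2] = 5.0
    ab[2] = lam * d0
    return ab


def asls_baseline(
    y: np.ndarray, smoothness: float = 1e7, asymmetry: float = 0.001, n_iter: int = 10
) -> np.ndarray:
    """Estimate the baseline of an intensity vector.

    ``smoothness`` (λ) scales the second-difference penalty; ``asymmetry``
    (p) is the weight of points above the baseline.  The pentadiagonal
    system (W + λD'D) z = W y is solved in banded form.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    if not 0 < asymmetry < 1:
        raise ValueError("asymmetry must be in (0, 1)")
    y = np.asarray(y, dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise ValueError("intensities must be finite")
    n = y.size
    if n < 3:
        return np.zeros_like(y)
    penalty = _penalty_banded(n, smoothness)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        ab = penalty.copy()
        ab[2] += w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def correct_baseline(
    spectrum: Spectrum, smoothness: float = 1e7, asymmetry: float = 0.001, n_iter: int = 10
) -> Spectrum:
    """Return the spectrum minus its estimated AsLS baseline."""
    z = asls_baseline(spectrum.intensity, smoothness, asymmetry, n_iter)
    return spectrum.copy(intensity=spectrum.intensity - z)
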