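"""Segment-wise spectral alignment (interval-correlation-shifting style).

The ppm axis is cut into segments with boundaries snapped to low-intensity
points of the mean spectrum; each segment of each spectrum is shifted by
the integer lag (within a bounded window) that maximises its correlation
with the reference segment, and the gaps opened by the shift are filled
with the segment's edge values.
"""

from __future__ import annotations

import numpy as np

from ..datatypes import Spectrum, stack_spectra

__all__ = ["align_spectra", "segment_boundaries"]


def segment_boundaries(
    mean_profile: np.ndarray, target_len: int, snap_window: int
) -> np.ndarray:
    """Indices cutting the axis into ~``target_len``-point segments, each
    boundary moved to the local minimum of ``mean_profile`` nearby."""
    n = mean_profile.size
    n_seg = max(1, round(n / target_len))
    bounds = [0]
    for k in range(1, n_seg):
        b = round(k * n / n_seg)
        lo = max(bounds[-1] + 1, b - snap_window)
        hi = min(n - 1, b + snap_window)
        if lo >= hi:
            continue
        b = lo + int(np.argmin(mean_profile[lo:hi]))
        if b > bounds[-1]:
            bounds.append(b)
    bounds.append(n)
    return np.asarray(bounds, dtype=int)


def _best_lag(seg: np.ndarray, ref: np.ndarray, max_lag: int) -> int:
    """Integer lag in [-max_lag, max_lag] maximising the Pearson correlation
    of the (edge-padded) shifted segment with the reference.

    Normalised correlation, not a raw inner product: edge padding duplicates
    a boundary value, and on monotone peak flanks an unnormalised score
    rewards that duplication, shifting segments that are already aligned.
    """
    rc = ref - ref.mean()
    rn = float(rc @ rc)
    if rn == 0.0:
        return 0
    best_lag, best_score = 0, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        shifted = _shift(seg, lag)
        sc = shifted - shifted.mean()
        sn = float(sc @ sc)
        score = float(sc @ rc) / np.sqrt(sn * rn) if sn > 0 else 0.0
        if score > best_score + 1e-12 or (
            abs(score - best_score) <= 1e-12 and abs(lag) < abs(best_lag)
        ):
            best_score = score
            best_lag = lag
    return best_lag


def _shift(v: np.ndarray, lag: int) -> np.ndarray:
    """Shift right by ``lag`` points (left when negative), edge-filling."""
    if lag == 0:
        return v
    out = np.empty_like(v)
    if lag > 0:
        out[lag:] = v[:-lag]
        out[:lag] = v[0]
    else:
        out[:lag] = v[-lag:]
        out[lag:] = v[-1]
    return out


def align_spectra(
    spectra,
    reference="mean",
    max_shift_ppm: float = 0.02,
    segment_ppm: float = 0.12,
    snap_window_ppm: float = 0.02,
):
    """Align a set of spectra sharing one axis; returns new Spectrum objects.

    ``reference`` is ``"mean"`` (default), an integer index into the set, or
    a :class:`Spectrum` on the same axis.
    """
    spectra = list(spectra)
    if len(spectra) < 2 and not isinstance(reference, Spectrum):
        raise ValueError("need at least 2 spectra to align")
    ppm, mat, ids = stack_spectra(spectra)
    step = abs(float(np.mean(np.diff(ppm))))
    max_lag = max(1, int(round(max_shift_ppm / step)))
    target_len = max(2 * max_lag + 2, int(round(segment_ppm / step)))
    snap = max(1, int(round(snap_window_ppm / step)))
    if isinstance(reference, Spectrum):
        ref = reference.intensity
    elif reference == "mean":
        ref = mat.mean(axis=0)
    else:
        ref = mat[int(reference)]
    bounds = segment_boundaries(mat.mean(axis=0), target_len, snap)
    out = np.empty_like(mat)
    for i in range(mat.shape[0]):
        row = mat[i]
        aligned = np.empty_like(row)
        for s, e in zip(bounds[:-1], bounds[1:]):
            if e - s < 2 * max_lag:
                raise ValueError("segment shorter than twice the maximum shift")
            lag = _best_lag(row[s:e], ref[s:e], max_lag)
            aligned[s:e] = _shift(row[s:e], lag)
        out[i] = aligned
    return [Spectrum(ppm.copy(), out[i], sample_id=ids[i]) for i in range(mat.shape[0])]
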