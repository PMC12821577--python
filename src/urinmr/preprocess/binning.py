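"""Adaptive intelligent (AI) binning and exclusion of solvent/reference regions.

Bin boundaries are found by recursive bisection.  A candidate bin spanning
points ``s..e`` (inclusive) is scored, per sample, by the product of the
differences between the bin maximum and the two end intensities, raised to
a resolution exponent r, and summed over samples:

    BV(s, e) = sum_i [ (max_i - I_i[s]) * (max_i - I_i[e]) ]^r

A split at the best interior point is accepted only when the two sub-bin
values sum to more than the parent value AND both sub-bins exceed a noise
threshold estimated from a signal-free region; the recursion then descends
into both halves.  Peaks thus end up inside bins with boundaries in the
valleys between them, while featureless stretches remain unsplit.
"""

from __future__ import annotations

import numpy as np

from ..datatypes import BinnedMatrix, Spectrum, stack_spectra

__all__ = [
    "ai_binning",
    "uniform_binning",
    "bin_value",
    "noise_sigma",
    "noise_threshold",
    "exclude_regions",
]


def bin_value(mat: np.ndarray, s: int, e: int, r: float) -> float:
    """Bin-value index of points ``s..e`` (inclusive) of a samples × points
    matrix."""
    seg = mat[:, s : e + 1]
    mx = seg.max(axis=1)
    prod = (mx - mat[:, s]) * (mx - mat[:, e])
    return float(np.sum(np.maximum(prod, 0.0) ** r))


def _bin_values_all_splits(mat, s, e, r):
    """Vectorised BV of every prefix [s..j] and suffix [j+1..e]."""
    seg = mat[:, s : e + 1]
    left_max = np.maximum.accumulate(seg, axis=1)
    right_max = np.maximum.accumulate(seg[:, ::-1], axis=1)[:, ::-1]
    first = seg[:, :1]
    last = seg[:, -1:]
    # left bin [s..j]: ends are seg[:,0] and seg[:,j]
    left_bv = np.sum(np.maximum((left_max - first) * (left_max - seg), 0.0) ** r, axis=0)
    right_bv = np.sum(np.maximum((right_max - seg) * (right_max - last), 0.0) ** r, axis=0)
    return left_bv, right_bv


def noise_sigma(mat: np.ndarray) -> float:
    """Robust point-noise scale of a signal-free matrix slice (median
    absolute first difference; insensitive to slow baseline drift)."""
    d = np.diff(mat, axis=1)
    return float(1.4826 * np.median(np.abs(d)) / np.sqrt(2.0))


def noise_threshold(n_samples: int, length: int, sigma: float, r: float,
                    safety: float = 4.0) -> float:
    """Expected bin value of a pure-noise bin of ``length`` points.

    The end-to-maximum differences of a noise bin scale like the extreme
    value of ``length`` Gaussian draws, sigma*sqrt(2 ln L); the threshold is
    that scale squared (one factor per bin end), inflated by ``safety``,
    raised to r and summed over samples.  A genuine sub-bin must exceed it.
    """
    ln = np.log(max(length, 2))
    return n_samples * (safety * sigma * sigma * 2.0 * ln) ** r


def _split_bin(mat, s, e, r, sigma, safety, min_pts, out):
    if e - s + 1 < 2 * min_pts:
        out.append((s, e))
        return
    n_samples = mat.shape[0]
    parent = bin_value(mat, s, e, r)
    left_bv, right_bv = _bin_values_all_splits(mat, s, e, r)
    # split after local index j: left [s..s+j], right [s+j+1..e]
    j_lo, j_hi = min_pts - 1, (e - s + 1) - min_pts - 1
    sums = left_bv[j_lo : j_hi + 1] + right_bv[j_lo + 1 : j_hi + 2]
    j_rel = int(np.argmax(sums))
    j = j_lo + j_rel
    bl, br = left_bv[j], right_bv[j + 1]
    thr_l = noise_threshold(n_samples, j + 1, sigma, r, safety)
    thr_r = noise_threshold(n_samples, e - s - j, sigma, r, safety)
    if bl + br > parent and bl > thr_l and br > thr_r:
        _split_bin(mat, s, s + j, r, sigma, safety, min_pts, out)
        _split_bin(mat, s + j + 1, e, r, sigma, safety, min_pts, out)
    else:
        out.append((s, e))


def ai_binning(
    spectra,
    resolution_r: float = 0.5,
    noise_region: tuple = (9.5, 10.0),
    min_bin_points: int = 4,
    noise_safety: float = 4.0,
) -> BinnedMatrix:
    """Adaptive intelligent binning of an aligned spectrum set.

    ``noise_region`` is a (lo, hi) ppm interval containing no peaks, used to
    calibrate the noise threshold; bin integrals are trapezoidal areas per
    sample.  The returned bins partition the full retained axis.
    """
    ppm, mat, ids = stack_spectra(spectra)
    lo, hi = sorted(noise_region)
    noise_mask = (ppm >= lo) & (ppm <= hi)
    if noise_mask.sum() < 8:
        raise ValueError("noise_region must cover >= 8 axis points")
    sigma = noise_sigma(mat[:, noise_mask])
    out: list = []
    _split_bin(mat, 0, mat.shape[1] - 1, resolution_r, sigma, noise_safety,
               min_bin_points, out)
    out.sort()
    edges = np.array([[ppm[s], ppm[e]] for s, e in out])  # descending axis: hi, lo
    x_asc = ppm[::-1]
    values = np.empty((mat.shape[0], len(out)))
    n = ppm.size
    for b, (s, e) in enumerate(out):
        sl = slice(n - 1 - e, n - s)  # same points on the ascending axis
        values[:, b] = np.trapezoid(mat[:, ::-1][:, sl], x_asc[sl], axis=1)
    return BinnedMatrix(
        values,
        edges,
        ids,
        metadata={
            "method": "ai_binning",
            "resolution_r": resolution_r,
            "noise_region": [lo, hi],
            "noise_sigma": sigma,
            "noise_safety": noise_safety,
            "min_bin_points": min_bin_points,
        },
    )


def uniform_binning(spectra, bin_width_ppm: float = 0.04) -> BinnedMatrix:
    """Fixed-width binning: trapezoidal area per sample in each interval.

    Simpler than AI binning and with deterministic edges — useful when a
    stable bin ↔ ppm-range mapping matters more than peak-adaptive
    boundaries."""
    ppm, mat, ids = stack_spectra(spectra)
    lo, hi = float(ppm.min()), float(ppm.max())
    if bin_width_ppm > hi - lo:
        raise ValueError("bin width exceeds the axis span")
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width_ppm - 1e-9)))
    edges_asc = lo + bin_width_ppm * np.arange(n_bins + 1)
    edges_asc[-1] = hi
    x_asc = ppm[::-1]
    y_asc = mat[:, ::-1]
    values = np.empty((mat.shape[0], n_bins))
    idx = np.searchsorted(x_asc, edges_asc)
    for b in range(n_bins):
        s, e = idx[b], min(idx[b + 1] + 1, x_asc.size)
        if e - s < 2:
            values[:, b] = 0.0
            continue
        values[:, b] = np.trapezoid(y_asc[:, s:e], x_asc[s:e], axis=1)
    order = np.arange(n_bins)[::-1]  # descending ppm order
    bin_edges = np.column_stack([edges_asc[1:], edges_asc[:-1]])[order]
    return BinnedMatrix(
        values[:, order], bin_edges, ids,
        metadata={"method": "uniform_binning", "bin_width_ppm": bin_width_ppm},
    )


def _intervals_overlap(a_lo, a_hi, b_lo, b_hi):
    return a_hi > b_lo and a_lo < b_hi


def exclude_regions(obj, regions, on_empty: str = "error"):
    """Remove bins (or axis points) intersecting the given ppm intervals.

    ``obj`` is a :class:`BinnedMatrix` or a list of :class:`Spectrum`;
    ``regions`` is an iterable of (lo, hi) ppm pairs.  Removing everything
    raises unless ``on_empty="allow"``.
    """
    regions = [tuple(sorted(map(float, r))) for r in regions]
    if isinstance(obj, BinnedMatrix):
        if not regions:
            return obj
        keep = np.array(
            [
                not any(_intervals_overlap(lo, hi, r[0], r[1]) for r in regions)
                for hi, lo in obj.bin_edges
            ]
        )
        if not keep.any() and on_empty != "allow":
            raise ValueError("exclusion regions cover every bin")
        out = obj.select_bins(keep)
        out.excluded_regions = list(obj.excluded_regions) + regions
        for key in ("truth_bins", "bin_signs", "null_bins", "mixed_bins"):
            if key in out.metadata:
                out.metadata[key] = np.asarray(out.metadata[key])[keep]
        return out
    spectra = list(obj)
    if not regions:
        return spectra
    ppm = spectra[0].ppm
    keep = np.ones(ppm.size, dtype=bool)
    for lo, hi in regions:
        keep &= ~((ppm >= lo) & (ppm <= hi))
    if not keep.any() and on_empty != "allow":
        raise ValueError("exclusion regions cover the whole axis")
    return [Spectrum(s.ppm[keep], s.intensity[keep], s.sample_id) for s in spectra]
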