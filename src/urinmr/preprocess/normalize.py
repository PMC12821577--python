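"""Normalization and scaling of binned matrices; group mean spectra.

Probabilistic quotient normalization (PQN) removes per-sample dilution:
each sample is divided by the median of its bin-wise quotients against a
reference profile (default: the median spectrum over samples).  For a pure
dilution series the quotient median recovers the dilution factor exactly,
up to one global constant.
"""

from __future__ import annotations

import numpy as np

from ..datatypes import BinnedMatrix, Spectrum, stack_spectra

__all__ = ["normalize_quotient", "normalize_integral", "log_autoscale", "mean_spectrum"]


def _reference_profile(values: np.ndarray, reference) -> np.ndarray:
    if isinstance(reference, str):
        if reference == "median":
            return np.median(values, axis=0)
        if reference == "mean":
            return values.mean(axis=0)
        raise ValueError(f"unknown reference {reference!r}")
    if np.isscalar(reference):
        return values[int(reference)]
    return np.asarray(reference, dtype=float)


def normalize_quotient(
    matrix: BinnedMatrix,
    reference="median",
    reference_mass: float = 1.0,
    quotient_band: tuple | None = None,
) -> BinnedMatrix:
    """Probabilistic quotient normalization of a samples × bins matrix.

    ``reference`` is ``"median"`` (default), ``"mean"``, a sample index, or
    an explicit profile.  Two optional restrictions control which bins vote
    in the quotient median:

    * ``reference_mass < 1`` keeps only the strongest reference bins
      jointly holding that fraction of total reference intensity — use when
      the matrix contains signal-free floor bins, which do not scale with
      dilution and drag the median toward 1;
    * ``quotient_band=(lo_pct, hi_pct)`` keeps bins whose reference
      intensity lies between those percentiles of the positive bins — the
      mid-intensity "spectral background".  The strongest bins belong to a
      handful of dominant metabolites; when those are treatment-affected,
      letting them vote leaks part of the group effect into the
      normalization factors.  The background band is the part of the
      spectrum least likely to carry coherent treatment effects.

    The recovered per-sample factors (proportional to dilution for
    dilution-dominated data) are stored in ``metadata["pqn_factors"]``.
    """
    values = matrix.values
    if np.any(values.sum(axis=1) == 0):
        raise ValueError("all-zero sample cannot be quotient-normalized")
    ref = _reference_profile(values, reference)
    use = ref > 0
    if not use.any():
        raise ValueError("reference profile has no strictly positive bins")
    if reference_mass < 1.0:
        order = np.argsort(ref)[::-1]
        cum = np.cumsum(ref[order])
        keep_n = int(np.searchsorted(cum, reference_mass * cum[-1])) + 1
        mask = np.zeros(ref.size, dtype=bool)
        mask[order[:keep_n]] = True
        use &= mask
    if quotient_band is not None:
        lo_pct, hi_pct = quotient_band
        qlo, qhi = np.percentile(ref[ref > 0], [lo_pct, hi_pct])
        use &= (ref >= qlo) & (ref <= qhi)
        if not use.any():
            raise ValueError("quotient_band leaves no usable bins")
    q = values[:, use] / ref[use]
    factors = np.median(q, axis=1)
    if np.any(factors <= 0):
        raise ValueError("non-positive quotient median; check input positivity")
    return matrix.with_values(
        values / factors[:, None], pqn_factors=factors, normalization="pqn"
    )


def normalize_integral(matrix: BinnedMatrix) -> BinnedMatrix:
    """Total-area normalization (flagged alternative to PQN): each sample is
    divided by its summed intensity; rows then share a common total."""
    totals = matrix.values.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("non-positive sample total")
    factors = totals / totals.mean()
    return matrix.with_values(
        matrix.values / factors[:, None], integral_factors=factors,
        normalization="integral",
    )


def log_autoscale(
    matrix: BinnedMatrix, offset: float | None = None, constant_policy: str = "zero"
) -> BinnedMatrix:
    """Element-wise log then per-column standardisation (mean 0, SD 1).

    ``offset`` is added before the log; the default is half the smallest
    positive value in the matrix, which admits zero bins.  Constant columns
    become all-zero under ``constant_policy="zero"`` or raise under
    ``"error"``.
    """
    values = matrix.values
    if offset is None:
        positive = values[values > 0]
        if positive.size == 0:
            raise ValueError("matrix has no positive entries")
        offset = float(positive.min()) / 2.0
    shifted = values + offset
    if np.any(shifted <= 0):
        raise ValueError("non-positive entries remain after offset")
    logged = np.log(shifted)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    # near-constant columns: dividing rounding error by a ~eps SD explodes
    constant = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if constant.any() and constant_policy == "error":
        raise ValueError(f"{int(constant.sum())} constant columns")
    sd_safe = np.where(constant, 1.0, sd)
    scaled = (logged - mean) / sd_safe
    scaled[:, constant] = 0.0
    scaled -= scaled.mean(axis=0)  # remove residual rounding error exactly
    return matrix.with_values(scaled, log_offset=offset, scaling="log_autoscale")


def mean_spectrum(spectra, group_labels=None):
    """Point-wise mean spectrum, overall or per group.

    Returns a single :class:`Spectrum` when ``group_labels`` is None, else a
    ``{group: Spectrum}`` dict (a representative overview of each group's
    metabolic profile)."""
    ppm, mat, _ = stack_spectra(spectra)
    if group_labels is None:
        return Spectrum(ppm.copy(), mat.mean(axis=0), sample_id="mean")
    group_labels = np.asarray(group_labels)
    if group_labels.size != mat.shape[0]:
        raise ValueError("one label per spectrum required")
    out = {}
    for g in np.unique(group_labels):
        rows = mat[group_labels == g]
        if rows.size == 0:
            raise ValueError(f"empty group {g!r}")
        out[g] = Spectrum(ppm.copy(), rows.mean(axis=0), sample_id=f"mean_{g}")
    return out
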