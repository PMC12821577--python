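"""Self-contained validation studies on synthetic cohorts.

Each function runs a complete experiment against the generator's ground
truth and returns summary numbers: null calibration of the rdCV metrics and
their permutation test, sign-recovery of the planted discriminant panel,
dilution recovery by quotient normalization, URF cluster separation, the
type-I error of the confounder screen, and exact small-scale oracles.  The
acceptance script and the acceptance test suite both drive these.

Study-size choices (documented in the methods note): the null calibration
uses single-repetition rdCV with a five-component search per fit, equal for
the observed and permuted runs so the permutation p-value is exactly
exchangeable; the recovery study uses two outer folds so that sign
stability is judged over disjoint half-sample submodels, and a
mid-intensity quotient band so the discriminant-dominated strong bins do
not leak group signal into the normalization factors.
"""

from __future__ import annotations

import numpy as np

from . import preprocess, synth
from .plslda import RdCVConfig, fit_pls, permutation_test, rdcv, select_variables
from .urf import DissimilarityMatrix, URFConfig, confounder_screen, pcoa, urf_dissimilarity

__all__ = [
    "null_calibration_study",
    "recovery_study",
    "dilution_recovery_study",
    "urf_cluster_study",
    "screen_calibration_study",
    "oracle_checks",
]

#: signal-free high-field edge trimmed before normalization in studies
EDGE_TRIM = [(9.3, 10.0)]


def null_calibration_study(
    n_sims: int = 500,
    n_permutations: int = 99,
    n_bins: int = 200,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict:
    """Null calibration: rdCV accuracy at chance, permutation test at level.

    Each simulation draws a no-effect cohort (null panel, default cohort
    sizes 64+78, ``n_bins`` bins), preprocesses it (PQN, log, auto-scale)
    and runs the permutation test with the observed and permuted rdCV at
    identical settings (1 repetition, 7/6 folds, 5-component search), so
    the p-value is exchangeable by construction.
    """
    ss = np.random.SeedSequence(seed if seed is not None else None)
    panel = synth.build_default_panel(effect_size=0.0)
    span = 9.8 - 0.2
    bin_width = span / n_bins
    accs = np.empty(n_sims)
    rejected = 0
    for i, child in enumerate(ss.spawn(n_sims)):
        rs = np.random.default_rng(child)
        design = synth.CohortDesign(panel=panel, seed=int(rs.integers(2**31)))
        bm = synth.cohort_to_binned(design, bin_width, noise_sd=0.01)
        scaled = preprocess.log_autoscale(preprocess.normalize_quotient(bm))
        y = (np.asarray(bm.metadata["labels"]) == "worker").astype(np.int64)
        cfg = RdCVConfig(
            n_repetitions=1,
            max_components=5,
            n_permutations=n_permutations,
            permutation_repetitions=1,
            seed=int(rs.integers(2**31)),
        )
        pt = permutation_test(scaled.values, y, cfg)
        accs[i] = pt.observed["accuracy"]
        if pt.p_values["accuracy"] <= alpha:
            rejected += 1
    return {
        "mean_accuracy_pct": float(accs.mean()),
        "rejection_rate_pct": 100.0 * rejected / n_sims,
        "n_sims": n_sims,
        "n_permutations": n_permutations,
    }


def _preprocess_for_recovery(cohort, bin_width: float):
    """Spectra → scaled matrix for the recovery study (full pipeline with
    fixed-width bins for a deterministic bin ↔ truth mapping)."""
    spectra = [preprocess.correct_baseline(s) for s in cohort.spectra]
    spectra = preprocess.align_spectra(spectra)
    bm = preprocess.uniform_binning(spectra, bin_width)
    bm = preprocess.exclude_regions(
        bm, preprocess.DEFAULT_EXCLUDED_REGIONS + EDGE_TRIM
    )
    bm.values[bm.values < 0] = 0.0
    norm = preprocess.normalize_quotient(bm, quotient_band=(10, 60))
    return bm, preprocess.log_autoscale(norm)


def recovery_study(
    n_seeds: int = 20,
    effect_size: float = synth.DEFAULT_EFFECT_SIZE,
    bin_width: float = 0.04,
    n_repetitions: int = 200,
    seed: int | None = None,
) -> dict:
    """Sign-recovery of the 27-metabolite panel through the full pipeline.

    Per seed: simulate a default cohort, preprocess (baseline, alignment,
    binning, exclusion, band-quotient normalization, log + auto-scale), run
    rdCV with two outer folds (disjoint half-sample submodels for sign
    stability) and select variables.  Recovery counts planted bins flagged
    significant with the planted sign; false positives count flagged bins
    among the content-null bins.
    """
    ss = np.random.SeedSequence(seed if seed is not None else None)
    panel = synth.build_default_panel(effect_size=effect_size)
    recoveries, fps, accs = [], [], []
    for child in ss.spawn(n_seeds):
        rs = np.random.default_rng(child)
        design = synth.CohortDesign(panel=panel, seed=int(rs.integers(2**31)))
        cohort = synth.simulate_cohort(design)
        bm, scaled = _preprocess_for_recovery(cohort, bin_width)
        flags = synth.flag_truth_bins(design, bm.bin_edges)
        y = (cohort.labels == "worker").astype(np.int64)
        cfg = RdCVConfig(
            n_outer_folds=2,
            n_repetitions=n_repetitions,
            seed=int(rs.integers(2**31)),
        )
        res = rdcv(scaled.values, y, cfg)
        sel = select_variables(res)
        sig = sel.frame["significant"].to_numpy()
        mean_w = sel.frame["mean_weight"].to_numpy()
        signs = flags["bin_signs"]
        planted = signs != 0
        nulls = flags["null_bins"]
        recoveries.append((sig & (np.sign(mean_w) == signs))[planted].mean())
        fps.append(sig[nulls].mean())
        accs.append(res.metric_means["accuracy"])
    return {
        "recovery_rate_pct": 100.0 * float(np.mean(recoveries)),
        "false_positive_rate_pct": 100.0 * float(np.mean(fps)),
        "mean_accuracy_pct": float(np.mean(accs)),
        "n_seeds": n_seeds,
        "effect_size": effect_size,
    }


def dilution_recovery_study(n_seeds: int = 5, seed: int | None = None) -> dict:
    """Correlation between PQN factors and the planted dilution factors on
    default noisy cohorts (fast binned path)."""
    ss = np.random.SeedSequence(seed if seed is not None else None)
    rs_list = [np.random.default_rng(c) for c in ss.spawn(n_seeds)]
    r_values = []
    for rs in rs_list:
        design = synth.CohortDesign(seed=int(rs.integers(2**31)))
        bm = synth.cohort_to_binned(design, 0.04, noise_sd=0.01)
        bm = preprocess.exclude_regions(bm, EDGE_TRIM)
        norm = preprocess.normalize_quotient(bm)
        r = np.corrcoef(norm.metadata["pqn_factors"], bm.metadata["dilution"])[0, 1]
        r_values.append(r)
    return {"pearson_r": float(np.mean(r_values)), "n_seeds": n_seeds}


def urf_cluster_study(
    n_seeds: int = 20,
    n_per_cluster: int = 15,
    n_vars: int = 20,
    shift: float = 2.5,
    seed: int | None = None,
) -> dict:
    """Within- vs between-cluster URF dissimilarity on planted two-cluster
    cohorts; reports the fraction of seeds with within < between."""
    ss = np.random.SeedSequence(seed if seed is not None else None)
    cfg_template = dict(n_iterations=3, n_trees=100, min_leaf=2)
    successes = 0
    ratios = []
    n = n_per_cluster
    iu = np.triu_indices(n, 1)
    for child in ss.spawn(n_seeds):
        rs = np.random.default_rng(child)
        X = np.vstack(
            [rs.normal(0, 1, (n, n_vars)), rs.normal(shift, 1, (n, n_vars))]
        )
        cfg = URFConfig(seed=int(rs.integers(2**31)), **cfg_template)
        v = urf_dissimilarity(X, cfg).values
        within = np.r_[v[:n, :n][iu], v[n:, n:][iu]].mean()
        between = v[:n, n:].mean()
        ratios.append(within / between)
        if within < between:
            successes += 1
    return {
        "success_fraction": successes / n_seeds,
        "mean_within_between_ratio": float(np.mean(ratios)),
        "n_seeds": n_seeds,
    }


def screen_calibration_study(
    n_sims: int = 1000,
    n_samples: int = 20,
    n_perm: int = 99,
    alpha: float = 0.05,
    seed: int | None = None,
) -> dict:
    """Type-I error of the confounder screen for a covariate independent of
    the dissimilarities."""
    import pandas as pd
    from scipy.spatial.distance import pdist, squareform

    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        pts = rng.normal(size=(n_samples, 4))
        d = squareform(pdist(pts))
        D = DissimilarityMatrix(d / d.max(), [str(i) for i in range(n_samples)])
        cov = pd.DataFrame({"x": rng.normal(size=n_samples)})
        p = confounder_screen(
            D, cov, n_perm=n_perm, seed=int(rng.integers(2**31))
        )["p_value"].iloc[0]
        if p <= alpha:
            rejections += 1
    return {"type_one_error_pct": 100.0 * rejections / n_sims, "n_sims": n_sims}


def oracle_checks(seed: int | None = None) -> dict:
    """Exact small-scale oracles.

    * classical scaling reproduces Euclidean toy distances;
    * the first NIPALS weight vector equals X'y/||X'y|| on a 5 × 3 fixture;
    * recursive AI binning agrees with exhaustive split search on short axes.
    """
    from scipy.spatial.distance import pdist, squareform

    from .preprocess.binning import _split_bin, bin_value, noise_sigma, noise_threshold

    rng = np.random.default_rng(seed)

    pcoa_err = 0.0
    for _ in range(5):
        pts = rng.normal(size=(9, 3))
        d = squareform(pdist(pts))
        d /= d.max()
        res = pcoa(DissimilarityMatrix(d, [str(i) for i in range(9)]), k=8)
        rec = squareform(pdist(res.coordinates))
        pcoa_err = max(pcoa_err, float(np.abs(rec - d).max()))

    X = rng.normal(size=(5, 3))
    X -= X.mean(axis=0)
    y = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
    W, *_ = fit_pls(X, y, 1)
    yc = y - y.mean()
    expected = X.T @ yc
    expected /= np.linalg.norm(expected)
    nipals_err = float(np.abs(W[:, 0] - expected).max())

    def brute(mat, s, e, r, sigma, safety, min_pts):
        if e - s + 1 < 2 * min_pts:
            return [(s, e)]
        parent = bin_value(mat, s, e, r)
        best, best_j = -np.inf, None
        for j in range(s + min_pts - 1, e - min_pts):
            val = bin_value(mat, s, j, r) + bin_value(mat, j + 1, e, r)
            if val > best:
                best, best_j = val, j
        bl = bin_value(mat, s, best_j, r)
        br = bin_value(mat, best_j + 1, e, r)
        ok = (
            bl + br > parent
            and bl > noise_threshold(mat.shape[0], best_j - s + 1, sigma, r, safety)
            and br > noise_threshold(mat.shape[0], e - best_j, sigma, r, safety)
        )
        if not ok:
            return [(s, e)]
        return brute(mat, s, best_j, r, sigma, safety, min_pts) + brute(
            mat, best_j + 1, e, r, sigma, safety, min_pts
        )

    agree = 0
    n_cases = 20
    x = np.linspace(0, 1, 64)
    for _ in range(n_cases):
        mat = np.vstack(
            [
                0.02 / np.pi / ((x - 0.3) ** 2 + 0.02**2)
                + rng.uniform(0.5, 2) * 0.02 / np.pi / ((x - 0.7) ** 2 + 0.02**2)
                + rng.normal(0, 0.05, 64)
                for _ in range(3)
            ]
        )
        sigma = noise_sigma(mat[:, :10])
        out: list = []
        _split_bin(mat, 0, 63, 0.5, sigma, 4.0, 4, out)
        if sorted(out) == sorted(brute(mat, 0, 63, 0.5, sigma, 4.0, 4)):
            agree += 1

    return {
        "pcoa_reconstruction_max_error": pcoa_err,
        "nipals_first_weight_max_error": nipals_err,
        "ai_binning_oracle_agreement": agree / n_cases,
    }
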