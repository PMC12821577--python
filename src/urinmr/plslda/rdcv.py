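"""Repeated double cross-validation (rdCV) for PLS-LDA.

The outer loop estimates classification performance on samples never used
for any modelling decision; the inner loop, run on each outer-training set
only, selects the number of PLS components.  Repeating the whole procedure
over many random splits yields mean ± SD validation metrics, a per-sample
record of how often each sample is classified correctly, and one CV1 weight
profile per repetition — the basis for sign-stable variable selection.

Metrics (all in percent; class 1 = "workers" side = ``positive_class``):

* sensitivity  — correctly classified class-1 samples / class-1 samples
* specificity  — correctly classified class-0 samples / class-0 samples
* accuracy     — balanced accuracy, (sensitivity + specificity) / 2
* ccr          — correct classification rate, total correct / n

Significance of each metric is assessed by a permutation test: class labels
are shuffled, the (reduced-repetition) rdCV is re-run, and the p-value is
the add-one estimator ``(1 + #{null >= observed}) / (1 + n_permutations)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels as K

__all__ = [
    "RdCVConfig",
    "RdCVResults",
    "rdcv",
    "permutation_test",
    "PermutationTestResult",
    "select_variables",
    "VariableSelectionResult",
    "sample_stability",
]

METRICS = ("accuracy", "sensitivity", "specificity", "ccr")


@dataclass
class RdCVConfig:
    """Tuning parameters of the repeated double cross-validation."""

    n_outer_folds: int = 7
    n_inner_folds: int = 6
    n_repetitions: int = 50
    max_components: int = 10
    n_permutations: int = 1000
    alpha: float = 0.05
    #: repetitions used inside each permutation re-run (kept small for cost)
    permutation_repetitions: int = 5
    one_se_rule: bool = True
    ridge: float = 1e-8
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")


def _stratified_folds(y01: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment (0..k-1) balancing both classes across folds."""
    fold = np.empty(y01.shape[0], dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(y01 == cls)
        if idx.size < k:
            raise ValueError(f"class {cls} has {idx.size} samples < {k} folds")
        idx = rng.permutation(idx)
        fold[idx] = np.arange(idx.size) % k
    return fold


def _choose_components(fold_err: np.ndarray, one_se: bool) -> int:
    """Pick the component count from inner-CV fold error rates (folds × A).

    Minimum mean misclassification, with an optional 1-SE parsimony
    tie-break toward fewer components.
    """
    mean_err = fold_err.mean(axis=0)
    best = int(np.argmin(mean_err))
    if not one_se or fold_err.shape[0] < 2:
        return best + 1
    se = fold_err[:, best].std(ddof=1) / np.sqrt(fold_err.shape[0])
    ok = np.flatnonzero(mean_err <= mean_err[best] + se)
    return int(ok[0]) + 1


def _one_repetition(X, y01, cfg: RdCVConfig, rng: np.random.Generator):
    """One full outer/inner cycle.

    Returns (per-sample 0/1 predictions, chosen components per outer fold,
    mean CV1 weight vector over outer-fold refits).
    """
    n, p = X.shape
    preds = np.zeros(n, dtype=np.uint8)
    chosen = np.zeros(cfg.n_outer_folds, dtype=np.int64)
    fold_w = np.zeros((cfg.n_outer_folds, p))
    outer = _stratified_folds(y01, cfg.n_outer_folds, rng)
    amax = cfg.max_components
    for f in range(cfg.n_outer_folds):
        tr = np.flatnonzero(outer != f)
        te = np.flatnonzero(outer == f)
        Xtr = np.ascontiguousarray(X[tr])
        ytr = y01[tr]
        inner = _stratified_folds(ytr, cfg.n_inner_folds, rng)
        fold_err = np.empty((cfg.n_inner_folds, amax))
        for g in range(cfg.n_inner_folds):
            itr = np.flatnonzero(inner != g)
            ite = np.flatnonzero(inner == g)
            pmat = K.train_predict_nested(
                np.ascontiguousarray(Xtr[itr]), ytr[itr],
                np.ascontiguousarray(Xtr[ite]), amax, cfg.ridge,
            )
            fold_err[g] = (pmat != ytr[ite][:, None]).mean(axis=0)
        a_sel = _choose_components(fold_err, cfg.one_se_rule)
        chosen[f] = a_sel
        xmean, W, P, T, R, direction, threshold, cv1_w, used = K.train_full(
            Xtr, ytr, a_sel, cfg.ridge
        )
        fold_w[f] = cv1_w
        preds[te] = K.predict_full(
            np.ascontiguousarray(X[te]), xmean, W, P, direction, threshold, used
        )
    return preds, chosen, fold_w


def _metrics_from_preds(preds: np.ndarray, y01: np.ndarray) -> dict:
    correct = preds == y01
    n1 = int(y01.sum())
    n0 = y01.size - n1
    sens = correct[y01 == 1].sum() / n1
    spec = correct[y01 == 0].sum() / n0
    return {
        "accuracy": 100.0 * (sens + spec) / 2.0,
        "sensitivity": 100.0 * sens,
        "specificity": 100.0 * spec,
        "ccr": 100.0 * correct.mean(),
    }


def rdcv(X, y, config: Optional[RdCVConfig] = None, model=None, seed=None) -> "RdCVResults":
    """Run repeated double cross-validation of a PLS-LDA classifier.

    ``y`` may be 0/1 or any two-level labels (class 1 = lexicographically
    last, matching :class:`~urinmr.plslda.PLSLDA`).
    """
    cfg = config or RdCVConfig(seed=seed)
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y)
    if y.dtype.kind in "ifub" and set(np.unique(y)) <= {0, 1}:
        y01 = y.astype(np.int64)
    else:
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("need exactly two classes")
        y01 = (y == classes[-1]).astype(np.int64)
    n1 = int(y01.sum())
    if min(n1, y01.size - n1) < cfg.n_outer_folds:
        raise ValueError("each class must have at least n_outer_folds samples")
    ss = np.random.SeedSequence(cfg.seed if cfg.seed is not None else None)
    reps = ss.spawn(cfg.n_repetitions)
    n, p = X.shape
    metrics = np.empty((cfg.n_repetitions, len(METRICS)))
    fold_weights = np.empty((cfg.n_repetitions, cfg.n_outer_folds, p))
    predictions = np.empty((cfg.n_repetitions, n), dtype=np.uint8)
    components = np.empty((cfg.n_repetitions, cfg.n_outer_folds), dtype=np.int64)
    for r, child in enumerate(reps):
        rng = np.random.default_rng(child)
        preds, chosen, fw = _one_repetition(X, y01, cfg, rng)
        predictions[r] = preds
        components[r] = chosen
        fold_weights[r] = fw
        m = _metrics_from_preds(preds, y01)
        metrics[r] = [m[k] for k in METRICS]
    return RdCVResults(
        metrics=pd.DataFrame(metrics, columns=list(METRICS)),
        weights=fold_weights.mean(axis=1),
        fold_weights=fold_weights,
        predictions=predictions,
        components=components,
        y01=y01,
        config=cfg,
        model=model,
    )


@dataclass
class RdCVResults:
    """Outcome of repeated double cross-validation.

    Attributes
    ----------
    metrics : DataFrame (repetitions × 4), percent scale.
    weights : (repetitions × variables) CV1 weight profiles, one per
        repetition (mean over that repetition's outer-fold refits).
    fold_weights : (repetitions × outer folds × variables) CV1 weights of
        every individual outer-training submodel — the population over
        which sign stability is judged.
    predictions : (repetitions × samples) outer-loop 0/1 predictions; every
        sample is predicted exactly once per repetition.
    components : (repetitions × outer folds) chosen component counts.
    """

    metrics: pd.DataFrame
    weights: np.ndarray
    predictions: np.ndarray
    components: np.ndarray
    y01: np.ndarray
    config: RdCVConfig
    fold_weights: np.ndarray = None
    model: object = None
    permutation_pvalues: dict = field(default_factory=dict)

    @property
    def metric_means(self) -> pd.Series:
        return self.metrics.mean()

    @property
    def metric_sds(self) -> pd.Series:
        return self.metrics.std(ddof=1)

    def select_variables(self, alpha: float | None = None) -> "VariableSelectionResult":
        return select_variables(self, alpha if alpha is not None else self.config.alpha)

    def sample_stability(self) -> pd.Series:
        return sample_stability(self)

    def summary(self) -> str:
        mu, sd = self.metric_means, self.metric_sds
        lines = [
            "PLS-LDA repeated double cross-validation",
            "========================================",
            f"repetitions: {self.config.n_repetitions}   "
            f"outer/inner folds: {self.config.n_outer_folds}/{self.config.n_inner_folds}   "
            f"max components: {self.config.max_components}",
            "",
        ]
        for k in METRICS:
            line = f"{k:<12s} {mu[k]:5.1f} +/- {sd[k]:4.1f} %"
            if k in self.permutation_pvalues:
                line += f"   (permutation p = {self.permutation_pvalues[k]:.4g})"
            lines.append(line)
        comps = np.bincount(self.components.ravel())
        lines.append("")
        lines.append(
            "components chosen (outer folds): "
            + ", ".join(f"{a}:{c}" for a, c in enumerate(comps) if c > 0)
        )
        stab = self.sample_stability()
        counts = stab.value_counts()
        lines.append(
            "sample stability: "
            + ", ".join(f"{k}={counts.get(k, 0)}" for k in ("always-correct", "unstable", "always-wrong"))
        )
        return "\n".join(lines)


@dataclass
class PermutationTestResult:
    """Permutation-based significance of each rdCV metric."""

    p_values: dict
    observed: pd.Series
    null_distribution: pd.DataFrame  # permutations × metrics

    def summary(self) -> str:
        lines = ["Permutation test", "================"]
        for k in METRICS:
            lines.append(
                f"{k:<12s} observed {self.observed[k]:5.1f} %   p = {self.p_values[k]:.4g}"
            )
        return "\n".join(lines)


def permutation_test(
    X,
    y,
    config: Optional[RdCVConfig] = None,
    observed: Optional[RdCVResults] = None,
    model=None,
    seed=None,
) -> PermutationTestResult:
    """Label-permutation significance test for the rdCV metrics.

    Each of ``config.n_permutations`` shuffles re-runs a reduced-repetition
    rdCV (``config.permutation_repetitions`` repetitions) on the permuted
    labels; p-values use the add-one estimator, hence always in (0, 1].
    """
    cfg = config or RdCVConfig(seed=seed)
    ss = np.random.SeedSequence(cfg.seed if cfg.seed is not None else None)
    obs_seed, perm_seed = ss.spawn(2)
    if observed is None:
        obs_cfg = _replace_seed(cfg, obs_seed.generate_state(1)[0] % (2**31))
        observed = rdcv(X, y, obs_cfg, model=model)
    obs = observed.metric_means
    null_cfg = _replace_seed(cfg, None)
    null_cfg.n_repetitions = cfg.permutation_repetitions
    rng = np.random.default_rng(perm_seed)
    y = np.asarray(y)
    nulls = np.empty((cfg.n_permutations, len(METRICS)))
    for b in range(cfg.n_permutations):
        yb = rng.permutation(y)
        null_cfg.seed = int(rng.integers(2**31))
        res = rdcv(X, yb, null_cfg)
        nulls[b] = res.metric_means[list(METRICS)].to_numpy()
    null_frame = pd.DataFrame(nulls, columns=list(METRICS))
    p = {
        k: float((1 + int((null_frame[k].to_numpy() >= obs[k]).sum())) / (1 + cfg.n_permutations))
        for k in METRICS
    }
    observed.permutation_pvalues = p
    return PermutationTestResult(p_values=p, observed=obs, null_distribution=null_frame)


def _replace_seed(cfg: RdCVConfig, seed) -> RdCVConfig:
    out = RdCVConfig(**{f: getattr(cfg, f) for f in cfg.__dataclass_fields__})
    out.seed = seed
    return out


@dataclass
class VariableSelectionResult:
    """Sign-stable CV1-weight variable selection.

    A variable is *significant* when its CV1 weight kept the same sign in
    every repetition AND its 95% percentile confidence interval across
    repetitions excludes 0.  Positive weights associate with the positive
    class ("workers"), negative with the other group.
    """

    frame: pd.DataFrame
    ci_level: float

    @property
    def significant(self) -> pd.Index:
        return self.frame.index[self.frame["significant"]]

    def summary(self) -> str:
        sig = self.frame[self.frame["significant"]]
        lines = [
            "Sign-stable CV1 variable selection",
            "==================================",
            f"significant: {len(sig)} / {len(self.frame)} variables",
        ]
        for name, row in sig.reindex(
            sig["mean_weight"].abs().sort_values(ascending=False).index
        ).iterrows():
            lines.append(
                f"  {str(name):<28s} {row.mean_weight:+.4f} "
                f"[{row.ci_lo:+.4f}, {row.ci_hi:+.4f}]  -> {row.associated_group}"
            )
        return "\n".join(lines)


def select_variables(
    result: RdCVResults, alpha: float = 0.05, ci_level: float = 0.95,
    var_names=None, group_names=("residents", "workers"),
) -> VariableSelectionResult:
    """Select discriminant variables from the validation-cycle CV1 weights.

    Sign stability and the percentile CI are judged over every individual
    outer-training submodel (repetitions × outer folds of them).  Judging
    them on repetition-averaged weights instead would shrink the
    cross-validation jitter ~√(n_folds)-fold and let the chance correlation
    any variable has with the class labels in a finite sample (SE ≈ 1/√n)
    pass as "stable"; the submodel population is the honest yardstick.
    """
    if result.fold_weights is not None:
        Wm = result.fold_weights.reshape(-1, result.fold_weights.shape[-1])
    else:
        Wm = result.weights
    if Wm.shape[0] < 2:
        raise ValueError("need >= 2 repetitions for sign stability")
    lo_q = 100 * (1 - ci_level) / 2
    mean_w = Wm.mean(axis=0)
    ci_lo = np.percentile(Wm, lo_q, axis=0)
    ci_hi = np.percentile(Wm, 100 - lo_q, axis=0)
    signs = np.sign(Wm)
    sign_stable = (np.abs(signs.sum(axis=0)) == Wm.shape[0]) & (np.abs(Wm) > 0).all(axis=0)
    excludes0 = (ci_lo > 0) | (ci_hi < 0)
    significant = sign_stable & excludes0
    if var_names is None:
        var_names = (
            result.model.var_names
            if result.model is not None and hasattr(result.model, "var_names")
            else [f"var{j}" for j in range(Wm.shape[1])]
        )
    neg_name, pos_name = group_names
    if result.model is not None and hasattr(result.model, "positive_class"):
        pos_name = str(result.model.positive_class)
        others = [c for c in result.model.classes_ if c != result.model.positive_class]
        neg_name = str(others[0])
    frame = pd.DataFrame(
        {
            "mean_weight": mean_w,
            "ci_lo": ci_lo,
            "ci_hi": ci_hi,
            "sign_stable": sign_stable,
            "significant": significant,
            "associated_group": np.where(mean_w > 0, pos_name, neg_name),
        },
        index=pd.Index(var_names, name="variable"),
    )
    return VariableSelectionResult(frame=frame, ci_level=ci_level)


def sample_stability(result: RdCVResults) -> pd.Series:
    """Categorise samples by their outer-loop classification record.

    ``always-correct`` / ``always-wrong`` / ``unstable`` across repetitions —
    the categories partition the cohort.
    """
    correct = result.predictions == result.y01[None, :]
    frac = correct.mean(axis=0)
    cats = np.where(frac == 1.0, "always-correct", np.where(frac == 0.0, "always-wrong", "unstable"))
    ids = (
        result.model.sample_ids
        if result.model is not None and hasattr(result.model, "sample_ids")
        else range(result.y01.size)
    )
    return pd.Series(cats, index=pd.Index(ids, name="sample"), name="stability")
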