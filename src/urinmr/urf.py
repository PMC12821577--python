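"""Unsupervised Random Forest (URF) dissimilarity, PCoA and confounder screen.

URF turns a random forest into an unsupervised dissimilarity: the real
samples (class 1) are discriminated from a synthetic copy (class 2) drawn
from the product of the marginals — each column permuted independently, so
single-bin distributions are preserved but all covariance is destroyed.
The proximity of two real samples is the fraction of trees in which they
share a terminal node; dissimilarity is 1 − proximity, averaged over
re-randomized iterations (a square-root variant is available).

The embedding of the dissimilarity matrix uses classical scaling (PCoA,
via scikit-bio), and a distance-based pseudo-F permutation test
(McArdle–Anderson decomposition, PERMANOVA-style) screens covariates for
association with the sample dissimilarities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .datatypes import BinnedMatrix

__all__ = [
    "URFConfig",
    "DissimilarityMatrix",
    "PCoAResult",
    "URF",
    "URFResults",
    "synth_null",
    "urf_dissimilarity",
    "pcoa",
    "confounder_screen",
]


@dataclass
class URFConfig:
    """URF tuning parameters (defaults: 50 iterations, 1500 trees, final
    leaves of 8 samples)."""

    n_iterations: int = 50
    n_trees: int = 1500
    min_leaf: int = 8
    mtry: object = "sqrt"  # features per split
    dissimilarity: str = "one_minus"  # or "sqrt": d = sqrt(1 - proximity)
    oob_only: bool = False
    seed: Optional[int] = None

    def __post_init__(self):
        if min(self.n_iterations, self.n_trees, self.min_leaf) < 1:
            raise ValueError("counts must be >= 1")
        if self.dissimilarity not in ("one_minus", "sqrt"):
            raise ValueError("dissimilarity must be 'one_minus' or 'sqrt'")


@dataclass
class DissimilarityMatrix:
    """Symmetric zero-diagonal sample dissimilarities in [0, 1]."""

    values: np.ndarray
    sample_ids: list

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("entries must lie in [0, 1]")
        v = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(v, 0.0)
        self.values = v
        if len(self.sample_ids) != v.shape[0]:
            raise ValueError("one sample_id per row required")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_skbio(self) -> DistanceMatrix:
        return DistanceMatrix(self.values, ids=[str(i) for i in self.sample_ids])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DissimilarityMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame.to_numpy(float), [str(i) for i in frame.index])


@dataclass
class PCoAResult:
    """Classical-scaling embedding of a dissimilarity matrix."""

    coordinates: np.ndarray  # n × k
    explained_pct: np.ndarray  # per retained axis, of the positive inertia
    eigenvalues: np.ndarray
    sample_ids: list

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def synth_null(matrix, seed=None):
    """Synthetic URF class: every column permuted independently across
    samples — marginals intact, covariance destroyed."""
    rng = np.random.default_rng(seed)
    if isinstance(matrix, BinnedMatrix):
        return matrix.with_values(synth_null(matrix.values, rng), synthetic_class=True)
    if isinstance(seed, np.random.Generator):
        rng = seed
    X = np.asarray(matrix, dtype=np.float64)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[:, j] = rng.permutation(X[:, j])
    return out


def _proximity_from_leaves(leaves: np.ndarray, counts: np.ndarray, prox: np.ndarray,
                           valid: np.ndarray | None = None, chunk: int = 64) -> None:
    """Accumulate co-leaf counts (and, with an OOB validity mask, the number
    of trees where both samples were countable) into ``prox``/``counts``."""
    n, T = leaves.shape
    for s in range(0, T, chunk):
        L = leaves[:, s : s + chunk]
        eq = L[:, None, :] == L[None, :, :]
        if valid is not None:
            V = valid[:, s : s + chunk]
            both = V[:, None, :] & V[None, :, :]
            eq &= both
            counts += both.sum(axis=2)
        else:
            counts += L.shape[1]
        prox += eq.sum(axis=2)


def urf_dissimilarity(matrix, config: URFConfig | None = None, seed=None) -> DissimilarityMatrix:
    """URF dissimilarity of a samples × bins matrix.

    Per iteration a fresh synthetic class and a freshly seeded forest are
    drawn; proximities are averaged over iterations and transformed to
    dissimilarities.
    """
    cfg = config or URFConfig(seed=seed)
    if isinstance(matrix, BinnedMatrix):
        X, ids = matrix.values, list(matrix.sample_ids)
    else:
        X = np.asarray(matrix, dtype=np.float64)
        ids = [f"s{i}" for i in range(X.shape[0])]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    ss = np.random.SeedSequence(cfg.seed if cfg.seed is not None else None)
    prox_sum = np.zeros((n, n))
    for child in ss.spawn(cfg.n_iterations):
        rng = np.random.default_rng(child)
        Xa = np.vstack([X, synth_null(X, rng)])
        ya = np.repeat([1, 0], n)
        prox = np.zeros((n, n), dtype=np.int64)
        counts = np.zeros((n, n), dtype=np.int64)
        if not cfg.oob_only:
            forest = RandomForestClassifier(
                n_estimators=cfg.n_trees,
                min_samples_leaf=cfg.min_leaf,
                max_features=cfg.mtry,
                bootstrap=True,
                n_jobs=1,
                random_state=int(rng.integers(2**31)),
            )
            forest.fit(Xa, ya)
            _proximity_from_leaves(forest.apply(X).astype(np.int64), counts, prox)
        else:
            valid = np.empty((n, cfg.n_trees), dtype=bool)
            leaves = np.empty((n, cfg.n_trees), dtype=np.int64)
            for t in range(cfg.n_trees):
                boot = rng.integers(0, 2 * n, size=2 * n)
                tree = DecisionTreeClassifier(
                    min_samples_leaf=cfg.min_leaf,
                    max_features=cfg.mtry,
                    random_state=int(rng.integers(2**31)),
                )
                tree.fit(Xa[boot], ya[boot])
                leaves[:, t] = tree.apply(X)
                in_bag = np.zeros(2 * n, dtype=bool)
                in_bag[np.unique(boot)] = True
                valid[:, t] = ~in_bag[:n]
            _proximity_from_leaves(leaves, counts, prox, valid=valid)
        with np.errstate(invalid="ignore"):
            p = np.where(counts > 0, prox / np.maximum(counts, 1), 0.0)
        prox_sum += p
    proximity = prox_sum / cfg.n_iterations
    d = 1.0 - proximity
    if cfg.dissimilarity == "sqrt":
        d = np.sqrt(np.clip(d, 0.0, None))
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DissimilarityMatrix(d, ids)


def pcoa(D: DissimilarityMatrix, k: int = 4) -> PCoAResult:
    """Classical scaling of a dissimilarity matrix to ``k`` axes.

    Keeps the top-k non-negative eigenpairs; explained percentages are
    relative to the sum of positive eigenvalues; each axis is oriented so
    its largest-magnitude coordinate is positive.
    """
    if not isinstance(D, DissimilarityMatrix):
        D = DissimilarityMatrix(np.asarray(D, float), [f"s{i}" for i in range(len(D))])
    if k >= D.n:
        raise ValueError("k must be smaller than the number of samples")
    res = _skbio_pcoa(
        D.to_skbio(), method="eigh", number_of_dimensions=max(k, 2), inplace=False
    )
    eig = res.eigvals.to_numpy()
    pos = eig > 1e-12 * max(eig.max(), 1.0)
    total = eig[pos].sum()
    kk = min(k, int(pos.sum())) or 1
    coords = res.samples.to_numpy()[:, :kk].copy()
    eigk = eig[:kk].copy()
    for j in range(kk):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    explained = 100.0 * eigk / total if total > 0 else np.zeros(kk)
    return PCoAResult(coords, explained, eigk, list(D.sample_ids))


def _design_matrix(x: pd.Series) -> np.ndarray:
    """Centered design columns for one covariate (dummies for categoricals)."""
    if x.dtype.kind in "ifu" and x.nunique() > 2:
        Z = x.to_numpy(float)[:, None]
    else:
        dummies = pd.get_dummies(x.astype("category"), drop_first=True)
        if dummies.shape[1] == 0:
            raise ValueError(f"constant covariate {x.name!r}")
        Z = dummies.to_numpy(float)
    Z = Z - Z.mean(axis=0)
    if np.allclose(Z, 0):
        raise ValueError(f"constant covariate {x.name!r}")
    return Z


def _pseudo_f(G: np.ndarray, Z: np.ndarray) -> float:
    """McArdle–Anderson pseudo-F of a centered design against the Gower
    matrix G = -1/2 J D^2 J."""
    n = G.shape[0]
    Q, _ = np.linalg.qr(Z)
    m = Q.shape[1]
    ss_expl = float(np.einsum("ij,ij->", Q, G @ Q))
    ss_tot = float(np.trace(G))
    ss_res = ss_tot - ss_expl
    denom_df = n - m - 1
    return (ss_expl / m) / (ss_res / denom_df)


def confounder_screen(
    D: DissimilarityMatrix,
    covariates: pd.DataFrame,
    n_perm: int = 999,
    seed=None,
    columns=None,
) -> pd.DataFrame:
    """Distance-based pseudo-F permutation test per covariate.

    For each covariate (e.g. age, sex, smoking, alcohol, BMI, exposure
    group) the between/within decomposition of the squared dissimilarities
    gives a pseudo-F; its p-value comes from ``n_perm`` random permutations
    of the covariate (add-one estimator).  Returns a DataFrame indexed by
    covariate with ``statistic`` and ``p_value`` columns.
    """
    if not isinstance(D, DissimilarityMatrix):
        D = DissimilarityMatrix(np.asarray(D, float), [f"s{i}" for i in range(len(D))])
    if len(covariates) != D.n:
        raise ValueError("covariates must cover every sample")
    if covariates.isna().any().any():
        raise ValueError("covariates must be complete (no missing values)")
    rng = np.random.default_rng(seed)
    n = D.n
    d2 = D.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ d2 @ J
    cols = list(columns) if columns is not None else list(covariates.columns)
    rows = []
    for col in cols:
        Z = _design_matrix(covariates[col])
        f_obs = _pseudo_f(G, Z)
        hits = 0
        for _ in range(n_perm):
            f_null = _pseudo_f(G, Z[rng.permutation(n)])
            if f_null >= f_obs:
                hits += 1
        rows.append(
            {"covariate": col, "statistic": f_obs, "p_value": (1 + hits) / (1 + n_perm)}
        )
    return pd.DataFrame(rows).set_index("covariate")


class URF:
    """Unsupervised Random Forest model over a binned-intensity matrix."""

    def __init__(self, matrix, config: URFConfig | None = None):
        self.matrix = matrix
        self.config = config or URFConfig()

    def fit(self, seed=None) -> "URFResults":
        cfg = self.config
        if seed is not None:
            cfg = URFConfig(**{f: getattr(cfg, f) for f in cfg.__dataclass_fields__})
            cfg.seed = seed
        return URFResults(self, urf_dissimilarity(self.matrix, cfg), cfg)


@dataclass
class URFResults:
    """Fitted URF: the dissimilarity matrix plus embedding / screening."""

    model: URF
    dissimilarity: DissimilarityMatrix
    config: URFConfig
    _pcoa_cache: dict = field(default_factory=dict, repr=False)

    def pcoa(self, k: int = 4) -> PCoAResult:
        if k not in self._pcoa_cache:
            self._pcoa_cache[k] = pcoa(self.dissimilarity, k)
        return self._pcoa_cache[k]

    def confounder_screen(self, covariates: pd.DataFrame, n_perm: int = 999,
                          seed=None, columns=None) -> pd.DataFrame:
        return confounder_screen(self.dissimilarity, covariates, n_perm, seed, columns)

    def summary(self) -> str:
        d = self.dissimilarity.values
        off = d[~np.eye(d.shape[0], dtype=bool)]
        emb = self.pcoa(min(4, self.dissimilarity.n - 1))
        lines = [
            "Unsupervised Random Forest",
            "==========================",
            f"samples: {self.dissimilarity.n}   iterations: {self.config.n_iterations}   "
            f"trees: {self.config.n_trees}   min leaf: {self.config.min_leaf}",
            f"dissimilarity range: [{off.min():.3f}, {off.max():.3f}]  mean {off.mean():.3f}",
            "PCoA explained variance: "
            + ", ".join(f"PCo{i + 1} {p:.1f}%" for i, p in enumerate(emb.explained_pct)),
        ]
        return "\n".join(lines)
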