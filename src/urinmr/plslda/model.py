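"""PLS-LDA discriminant model (statsmodels-style Model / Results pair).

The model reduces the binned-intensity matrix to a small number of PLS
latent scores computed against the class indicator, then fits a two-class
linear discriminant in score space.  The discriminant direction pulled back
to variable space — the weights along the first canonical variate (CV1) —
is the quantity used for variable selection: its sign says in which group a
variable is elevated.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels as K

__all__ = ["PLSLDA", "PLSLDAResults", "fit_pls", "fit_plslda"]


def fit_pls(X: np.ndarray, y_dummy: np.ndarray, n_components: int):
    """NIPALS PLS1 of a (column-centered) matrix against a class indicator.

    Parameters
    ----------
    X : (n, p) array, column-centered.
    y_dummy : (n,) class indicator (any two-level coding); centered internally.
    n_components : number of latent components to extract.

    Returns
    -------
    W, P, T, q : weights (p, A), loadings (p, A), scores (n, A) and inner
        regression coefficients (A,).  ``T`` equals ``X @ W @ inv(P'W)``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y_dummy, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y_dummy have incompatible shapes")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("zero-variance X")
    Xc = X.copy()
    yc = y - y.mean()
    W, P, T, q, used = K._nipals_pls1(Xc, yc, int(n_components))
    if used < n_components:
        W, P, T, q = W[:, :used], P[:, :used], T[:, :used], q[:used]
    return W, P, T, q


class PLSLDA:
    """Two-class PLS-LDA model for a samples × variables matrix.

    Parameters
    ----------
    X : (n, p) matrix (typically log-transformed, auto-scaled bin intensities).
    y : per-sample labels; exactly two distinct values.
    positive_class : the label treated as class 1 ("workers" side — positive
        CV1 weights associate with it).  Defaults to the lexicographically
        last label.
    var_names, sample_ids : optional identifiers carried into results.
    ridge : relative ridge added to the within-class scatter when (near-)
        singular; logged on results when it was needed.
    """

    def __init__(
        self,
        X,
        y,
        positive_class=None,
        var_names: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
        ridge: float = 1e-8,
    ):
        X = np.ascontiguousarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"need exactly two classes, got {classes.size}")
        if positive_class is None:
            positive_class = classes[-1]
        elif positive_class not in classes:
            raise ValueError(f"positive_class {positive_class!r} not in labels")
        self.X = X
        self.y = y
        self.classes_ = classes
        self.positive_class = positive_class
        self.y01 = (y == positive_class).astype(np.int64)
        self.var_names = (
            list(var_names) if var_names is not None else [f"var{j}" for j in range(X.shape[1])]
        )
        self.sample_ids = (
            list(sample_ids) if sample_ids is not None else [f"s{i}" for i in range(X.shape[0])]
        )
        self.ridge = float(ridge)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, labels, **kwargs):
        """Build from a samples × variables DataFrame; index becomes sample ids."""
        labels = np.asarray(labels)
        return cls(
            frame.to_numpy(dtype=np.float64),
            labels,
            var_names=[str(c) for c in frame.columns],
            sample_ids=[str(i) for i in frame.index],
            **kwargs,
        )

    def fit(self, n_components: int = 2) -> "PLSLDAResults":
        """Fit with a fixed number of PLS components."""
        a = int(n_components)
        if a < 1:
            raise ValueError("n_components must be >= 1")
        out = K.train_full(self.X, self.y01, a, self.ridge)
        xmean, W, P, T, R, direction, threshold, cv1_w, used = out
        if used == 0:
            raise ValueError("zero-variance X: no PLS component extractable")
        return PLSLDAResults(self, xmean, W[:, :used], P[:, :used], T[:, :used],
                             R, direction, float(threshold), cv1_w, used)

    def rdcv(self, config=None, seed=None):
        """Repeated double cross-validation; see :func:`urinmr.plslda.rdcv`."""
        from .rdcv import rdcv as _rdcv, RdCVConfig

        return _rdcv(self.X, self.y01, config or RdCVConfig(seed=seed), model=self)

    def permutation_test(self, config=None, seed=None, n_jobs=None):
        from .rdcv import permutation_test as _pt, RdCVConfig

        return _pt(self.X, self.y01, config or RdCVConfig(seed=seed), model=self)


class PLSLDAResults:
    """Fitted PLS-LDA model: scores, CV1 weights and a classifier."""

    def __init__(self, model, xmean, W, P, T, R, direction, threshold, cv1_weights, n_components):
        self.model = model
        self.xmean = xmean
        self.weights = W
        self.loadings = P
        self.scores = T
        self.rotations = R
        self.lda_direction = direction
        self.lda_threshold = threshold
        self.cv1_weights = cv1_weights
        self.n_components = n_components

    @property
    def canonical_scores(self) -> np.ndarray:
        """Projection of each training sample on the first canonical variate."""
        return self.scores @ self.lda_direction

    def predict(self, Xnew=None):
        """Predicted class labels (original label values)."""
        X = self.model.X if Xnew is None else np.ascontiguousarray(Xnew, dtype=np.float64)
        pred01 = K.predict_full(
            X, self.xmean, self.weights, self.loadings,
            self.lda_direction, self.lda_threshold, self.n_components,
        )
        neg = [c for c in self.model.classes_ if c != self.model.positive_class][0]
        return np.where(pred01 == 1, self.model.positive_class, neg)

    def training_accuracy(self) -> float:
        return float(np.mean(self.predict() == self.model.y))

    def cv1_weight_frame(self) -> pd.DataFrame:
        pos = self.model.positive_class
        neg = [c for c in self.model.classes_ if c != pos][0]
        return pd.DataFrame(
            {
                "cv1_weight": self.cv1_weights,
                "sign": np.sign(self.cv1_weights).astype(int),
                "associated_group": np.where(self.cv1_weights > 0, str(pos), str(neg)),
            },
            index=self.model.var_names,
        )

    def summary(self) -> str:
        lines = [
            "PLS-LDA Results",
            "===============",
            f"samples:              {self.model.X.shape[0]}",
            f"variables:            {self.model.X.shape[1]}",
            f"components:           {self.n_components}",
            f"positive class:       {self.model.positive_class}",
            f"training accuracy:    {100 * self.training_accuracy():.1f}%",
            "",
            "top |CV1| weights:",
        ]
        frame = self.cv1_weight_frame()
        top = frame.reindex(frame["cv1_weight"].abs().sort_values(ascending=False).index).head(10)
        for name, row in top.iterrows():
            lines.append(f"  {name:<28s} {row.cv1_weight:+.4f}  -> {row.associated_group}")
        return "\n".join(lines)


def fit_plslda(X, y, n_components: int, **kwargs) -> PLSLDAResults:
    """Functional form of ``PLSLDA(X, y).fit(n_components)``."""
    return PLSLDA(X, y, **kwargs).fit(n_components)
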