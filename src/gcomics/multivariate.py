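"""Multivariate stage modelling: PCA, ANOVA-simultaneous component analysis
(ASCA), PLS regression on developmental stage with VIP scores, hierarchical
(Ward) clustering with purity, the 2-means early/late partition, and the
sample Pearson correlation matrix.

ASCA and the PLS stage model follow a Model/Results idiom: construct the
model from a matrix plus metadata, call :meth:`fit`, and read estimates and
diagnostics off the returned results object (``summary()`` gives a text
table). Thin functional wrappers (:func:`asca`, :func:`pls_stage_model`)
exist for pipeline use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.cross_decomposition import PLSRegression

from .containers import AbundanceMatrix
from .exceptions import ConfigurationError, DataError

__all__ = [
    "pca", "PcaResult",
    "ASCA", "AscaResults", "asca",
    "PLSStageModel", "PLSStageResults", "pls_stage_model",
    "hierarchical_cluster", "kmeans_split", "ClusterResult",
    "sample_correlation_matrix",
]


def _samples_by_features(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Transpose to the samples x features orientation used throughout."""
    return matrix.values.T


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # features x components
    explained_variance_ratio: np.ndarray

    def summary(self) -> str:
        lines = ["PCA", "---"]
        for i, r in enumerate(self.explained_variance_ratio, 1):
            lines.append(f"PC{i}: {100 * r:.2f}% of variance")
        return "\n".join(lines)


def pca(matrix: AbundanceMatrix, n_components: int = 2) -> PcaResult:
    """SVD-based PCA of samples with a deterministic sign convention.

    The input should be autoscaled (or at least centered); samples are rows
    of the decomposed array. Each component is oriented so its
    largest-magnitude loading is positive, making results reproducible
    across SVD implementations.
    """
    X = _samples_by_features(matrix)
    if n_components > min(X.shape):
        raise ConfigurationError("n_components exceeds matrix dimensions")
    sd = X.to_numpy().std(axis=0)
    if (sd == 0).any():
        bad = X.columns[sd == 0].tolist()
        raise DataError(
            f"constant feature(s) {bad[:5]}: remove before PCA (zero variance)"
        )
    Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry positive per component
    for a in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[a]))
        if Vt[a, j] < 0:
            Vt[a] *= -1
            U[:, a] *= -1
    var = S**2
    ratio = var / var.sum()
    comps = [f"PC{i}" for i in range(1, n_components + 1)]
    return PcaResult(
        scores=pd.DataFrame((U * S)[:, :n_components], index=X.index, columns=comps),
        loadings=pd.DataFrame(Vt[:n_components].T, index=X.columns, columns=comps),
        explained_variance_ratio=ratio[:n_components],
    )


# ---------------------------------------------------------------------------
# ASCA
# ---------------------------------------------------------------------------

@dataclass
class AscaResults:
    """ASCA decomposition of a centered samples x features matrix.

    ``effects`` maps factor name (and ``"factor1:factor2"`` for the
    interaction) to its effect matrix; ``residual`` is the remainder, so
    centered data = sum(effects) + residual holds by construction.
    ``ss_share`` gives each term's share of the total sum of squares and
    ``effect_pca_ratio`` the PCA variance ratios *within* each effect
    matrix (the per-effect principal-component shares).
    """

    effects: dict
    residual: pd.DataFrame
    ss_share: dict
    effect_pca_ratio: dict
    centered: pd.DataFrame

    def summary(self) -> str:
        lines = ["ANOVA-simultaneous component analysis", "-" * 38]
        for name, share in self.ss_share.items():
            pc1 = self.effect_pca_ratio.get(name, [np.nan])[0]
            lines.append(
                f"{name:<20s} SS share {100 * share:6.2f}%"
                + ("" if np.isnan(pc1) else f"   effect-PC1 {100 * pc1:6.2f}%")
            )
        return "\n".join(lines)


class ASCA:
    """ANOVA-simultaneous component analysis.

    Partitions the column-centered data into per-factor effect matrices
    (level-mean deviations broadcast to samples), an optional interaction
    term (cell means minus main effects) and a residual, then runs PCA on
    each effect matrix. On a balanced design the effect matrices are
    pairwise orthogonal and the sum-of-squares decomposition is exact.
    """

    def __init__(self, matrix: AbundanceMatrix, meta: pd.DataFrame,
                 factors=("fraction", "stage"), with_interaction: bool = True):
        self.X = _samples_by_features(matrix)
        if list(self.X.index) != list(meta.index):
            meta = meta.loc[self.X.index]
        self.meta = meta
        self.factors = list(factors)
        self.with_interaction = with_interaction and len(self.factors) == 2
        for f in self.factors:
            if f not in meta.columns:
                raise DataError(f"factor {f!r} missing from metadata")
            levels = meta[f].value_counts()
            if len(levels) < 2:
                raise DataError(f"factor {f!r} has a single level")

    def fit(self) -> AscaResults:
        X = self.X.to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        centered = pd.DataFrame(Xc, index=self.X.index, columns=self.X.columns)
        effects: dict[str, pd.DataFrame] = {}
        for f in self.factors:
            lv = self.meta[f]
            E = np.zeros_like(Xc)
            for level, idx in lv.groupby(lv).groups.items():
                rows = self.X.index.get_indexer(idx)
                E[rows] = Xc[rows].mean(axis=0)
            effects[f] = pd.DataFrame(E, index=self.X.index, columns=self.X.columns)
        if self.with_interaction:
            f1, f2 = self.factors
            cells = self.meta[f1].astype(str) + "\x00" + self.meta[f2].astype(str)
            E = np.zeros_like(Xc)
            for _, idx in cells.groupby(cells).groups.items():
                rows = self.X.index.get_indexer(idx)
                E[rows] = Xc[rows].mean(axis=0)
            inter = E - effects[f1].to_numpy() - effects[f2].to_numpy()
            effects[f"{f1}:{f2}"] = pd.DataFrame(
                inter, index=self.X.index, columns=self.X.columns
            )
        resid = Xc - sum(e.to_numpy() for e in effects.values())
        total_ss = float((Xc**2).sum())
        denom = total_ss if total_ss > 0 else 1.0   # all-constant input
        ss_share = {
            name: float((E.to_numpy() ** 2).sum()) / denom
            for name, E in effects.items()
        }
        ss_share["residual"] = float((resid**2).sum()) / denom
        ratios = {}
        for name, E in effects.items():
            s = np.linalg.svd(E.to_numpy(), compute_uv=False)
            ss = s**2
            ratios[name] = ss / ss.sum() if ss.sum() > 0 else ss
        return AscaResults(
            effects=effects,
            residual=pd.DataFrame(resid, index=self.X.index, columns=self.X.columns),
            ss_share=ss_share,
            effect_pca_ratio=ratios,
            centered=centered,
        )


def asca(matrix, meta, factors=("fraction", "stage"), with_interaction=True):
    return ASCA(matrix, meta, factors, with_interaction).fit()


# ---------------------------------------------------------------------------
# PLS stage regression with VIP
# ---------------------------------------------------------------------------

@dataclass
class PLSStageResults:
    """Fitted PLS stage-regression model.

    ``r2`` is the fitted variance explained of the (centered) stage
    response, ``q2 = 1 - PRESS/TSS`` from stratified k-fold cross-validation
    with in-fold re-autoscaling, and ``accuracy`` the fraction of samples
    whose continuous prediction rounds to the true stage ordinal. ``vip``
    holds variable-importance-in-projection scores normalized so that
    sum(VIP^2) equals the number of features.
    """

    n_components: int
    r2: float
    q2: float
    accuracy: float
    vip: pd.Series
    weights: pd.DataFrame
    scores: pd.DataFrame
    y_pred: pd.Series

    def summary(self) -> str:
        return "\n".join(
            [
                "PLS stage regression",
                "--------------------",
                f"components: {self.n_components}",
                f"R2  = {self.r2:.4f}",
                f"Q2  = {self.q2:.4f}",
                f"accuracy = {self.accuracy:.4f}",
                f"features with VIP > 2: {(self.vip > 2).sum()}",
            ]
        )


def _autoscale_train_apply(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _vip(pls: PLSRegression) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a)."""
    W = pls.x_weights_                      # p x A
    T = pls.x_scores_                       # n x A
    Q = pls.y_loadings_                     # 1 x A
    p, A = W.shape
    ssy = np.array([(T[:, a] @ T[:, a]) * Q[0, a] ** 2 for a in range(A)])
    wnorm2 = (W**2).sum(axis=0)
    contrib = (W**2 / wnorm2) @ ssy
    return np.sqrt(p * contrib / ssy.sum())


class PLSStageModel:
    """PLS regression of autoscaled features on the centered stage ordinal.

    The core NIPALS fit is delegated to scikit-learn's ``PLSRegression``;
    VIP scores, cross-validated Q2 (with re-autoscaling inside every
    training fold) and rounded-prediction accuracy are computed here.
    """

    def __init__(self, matrix: AbundanceMatrix, stage_ordinal):
        self.X = _samples_by_features(matrix)
        self.y = pd.Series(stage_ordinal).loc[self.X.index].astype(float)
        if self.y.isna().any():
            raise DataError("stage ordinal missing for some samples")

    def fit(self, n_components: int = 2, cv_folds: int = 7,
            seed: int = 0) -> PLSStageResults:
        X = self.X.to_numpy(dtype=float)
        y = self.y.to_numpy()
        n, p = X.shape
        if n_components < 1:
            raise ConfigurationError("n_components must be >= 1")
        if n_components > min(n - 1, p):
            raise ConfigurationError("n_components exceeds matrix rank bound")
        Xs, _ = _autoscale_train_apply(X, X)
        yc = y - y.mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls = PLSRegression(n_components=n_components, scale=False)
            pls.fit(Xs, yc)
        y_fit = pls.predict(Xs).ravel() + y.mean()
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(((y - y_fit) ** 2).sum()) / tss
        vip = _vip(pls)

        # cross-validated Q2, folds stratified by stage
        rng = np.random.default_rng(seed)
        folds = [[] for _ in range(cv_folds)]
        for stage in np.unique(y):
            idx = np.flatnonzero(y == stage)
            idx = idx[rng.permutation(len(idx))]
            for k, i in enumerate(idx):
                folds[k % cv_folds].append(i)
        press = 0.0
        for fold in folds:
            if not fold:
                continue
            test = np.array(sorted(fold))
            train = np.setdiff1d(np.arange(n), test)
            Xtr, Xte = _autoscale_train_apply(X[train], X[test])
            ytr = y[train]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = PLSRegression(n_components=n_components, scale=False)
                m.fit(Xtr, ytr - ytr.mean())
            pred = m.predict(Xte).ravel() + ytr.mean()
            press += float(((y[test] - pred) ** 2).sum())
        q2 = 1.0 - press / tss

        rounded = np.clip(np.round(y_fit), y.min(), y.max())
        accuracy = float((rounded == y).mean())
        comps = [f"LV{i}" for i in range(1, n_components + 1)]
        return PLSStageResults(
            n_components=n_components,
            r2=r2,
            q2=q2,
            accuracy=accuracy,
            vip=pd.Series(vip, index=self.X.columns, name="VIP"),
            weights=pd.DataFrame(pls.x_weights_, index=self.X.columns, columns=comps),
            scores=pd.DataFrame(pls.x_scores_, index=self.X.index, columns=comps),
            y_pred=pd.Series(y_fit, index=self.X.index, name="stage_pred"),
        )


def pls_stage_model(matrix, stage_ordinal, n_components=2, cv_folds=7, seed=0):
    return PLSStageModel(matrix, stage_ordinal).fit(n_components, cv_folds, seed)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    assignments: pd.Series          # sample -> cluster id (or label)
    method: str
    k: int
    purity: float | None = None     # percent, vs supplied labels
    warnings: list = field(default_factory=list)

    def summary(self) -> str:
        out = [f"{self.method} clustering, k={self.k}"]
        if self.purity is not None:
            out.append(f"purity vs labels: {self.purity:.1f}%")
        out += self.warnings
        return "\n".join(out)


def _purity(assign: pd.Series, labels: pd.Series) -> float:
    """Percent of samples in clusters whose majority label matches their own."""
    labels = labels.loc[assign.index]
    correct = 0
    for _, idx in assign.groupby(assign).groups.items():
        majority = labels.loc[idx].mode().iloc[0]
        correct += int((labels.loc[idx] == majority).sum())
    return 100.0 * correct / len(assign)


def hierarchical_cluster(matrix: AbundanceMatrix, k: int,
                         labels=None, method: str = "ward") -> ClusterResult:
    """Agglomerative Ward/Euclidean clustering of samples cut into k groups."""
    X = _samples_by_features(matrix)
    n = len(X)
    if not 2 <= k <= n:
        raise ConfigurationError(f"k={k} out of range [2, {n}]")
    Z = linkage(X.to_numpy(), method=method, metric="euclidean")
    assign = pd.Series(fcluster(Z, t=k, criterion="maxclust"), index=X.index)
    purity = None
    if labels is not None:
        purity = _purity(assign, pd.Series(labels))
    return ClusterResult(assign, f"{method}/euclidean", k, purity)


def kmeans_split(matrix: AbundanceMatrix, stage_ordinal, seed: int = 0,
                 n_restarts: int = 50) -> ClusterResult:
    """2-means partition of samples labelled early/late by mean stage.

    The cluster whose samples have the lower mean stage ordinal is named
    ``early``, the other ``late``. Degenerate inputs (all points identical)
    collapse to a single cluster with a warning rather than failing.
    """
    X = _samples_by_features(matrix)
    if len(X) < 2:
        raise DataError("k-means split needs at least 2 samples")
    arr = X.to_numpy(dtype=float)
    if np.allclose(arr, arr[0]):
        assign = pd.Series(["early"] * len(X), index=X.index)
        return ClusterResult(assign, "kmeans", 2,
                             warnings=["degenerate input: single cluster"])
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(arr)
    ords = pd.Series(stage_ordinal).loc[X.index].astype(float)
    mean0 = ords[raw == 0].mean()
    mean1 = ords[raw == 1].mean()
    early_id = 0 if mean0 <= mean1 else 1
    assign = pd.Series(np.where(raw == early_id, "early", "late"), index=X.index)
    return ClusterResult(assign, "kmeans", 2)


# ---------------------------------------------------------------------------
# Sample correlation matrix
# ---------------------------------------------------------------------------

def sample_correlation_matrix(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Samples x samples Pearson matrix; constant profiles give NaN rows."""
    if matrix.n_features < 2:
        raise DataError("need at least 2 features for sample correlations")
    X = matrix.values.to_numpy(dtype=float)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    if (sd == 0).any():
        warnings.warn("constant sample profile(s): undefined correlations set NaN")
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=matrix.sample_ids, columns=matrix.sample_ids)
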