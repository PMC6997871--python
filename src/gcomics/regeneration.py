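"""Regeneration-arm analysis: empirical-Bayes batch correction, ROC-based
lipid marker ranking, and intersection of significant ontology terms with
the developmental signature.

The batch correction is the parametric empirical-Bayes location/scale
model: per-feature standardization against the batch-size-weighted grand
mean and pooled within-batch variance, normal/inverse-gamma priors on the
per-batch location (gamma) and scale (delta^2) parameters with
method-of-moments hyperparameters, and iterated posterior updates to
convergence. As a package design choice the adjusted matrix is re-centred
per feature to its original grand mean, so the correction is exactly
mean-preserving (the EB shrinkage otherwise leaves a residual offset of
order the shrinkage bias).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix
from .exceptions import DataError

__all__ = ["combat_adjust", "BatchAdjustment", "CombatModel",
           "roc_rank", "roc_single", "common_signatures"]


# ---------------------------------------------------------------------------
# ComBat
# ---------------------------------------------------------------------------

@dataclass
class BatchAdjustment:
    """Posterior batch-effect estimates from the EB correction.

    ``gamma_star`` / ``delta_star`` are features x batches location and
    scale posteriors on the standardized scale; ``grand_mean`` and
    ``pooled_sd`` are the per-feature standardization parameters.
    """

    batches: list
    gamma_star: pd.DataFrame
    delta_star: pd.DataFrame
    grand_mean: pd.Series
    pooled_sd: pd.Series
    n_iterations: dict
    converged: dict


class CombatModel:
    """Empirical-Bayes location/scale batch-correction model.

    ``CombatModel(matrix, batch_labels).fit()`` returns the adjusted matrix
    and a :class:`BatchAdjustment`. A single-batch input is returned
    unchanged (identity adjustment).
    """

    def __init__(self, matrix: AbundanceMatrix, batch_labels):
        if matrix.space != "log2":
            raise DataError("batch correction expects a log2-space matrix")
        self.matrix = matrix
        labels = pd.Series(batch_labels)
        missing = [s for s in matrix.sample_ids if s not in labels.index]
        if missing:
            raise DataError(f"samples without batch label: {missing[:5]}")
        self.labels = labels.loc[matrix.sample_ids]
        counts = self.labels.value_counts()
        small = counts[counts < 2].index.tolist()
        if small:
            raise DataError(f"batch(es) with < 2 samples: {small}")
        self.batches = sorted(counts.index)

    def fit(self, tol: float = 1e-4, max_iter: int = 100):
        X = self.matrix.values.to_numpy(dtype=float)
        features = self.matrix.feature_ids
        n_feat, n_samp = X.shape
        batch_idx = {b: np.flatnonzero((self.labels == b).to_numpy())
                     for b in self.batches}
        n_b = {b: len(ix) for b, ix in batch_idx.items()}

        if len(self.batches) == 1:
            b = self.batches[0]
            adj = BatchAdjustment(
                batches=list(self.batches),
                gamma_star=pd.DataFrame(0.0, index=features, columns=self.batches),
                delta_star=pd.DataFrame(1.0, index=features, columns=self.batches),
                grand_mean=pd.Series(X.mean(axis=1), index=features),
                pooled_sd=pd.Series(X.std(axis=1), index=features),
                n_iterations={b: 0},
                converged={b: True},
            )
            return AbundanceMatrix(self.matrix.values.copy(), "log2"), adj

        # standardization: weighted grand mean, pooled within-batch variance
        M = np.column_stack([X[:, ix].mean(axis=1) for ix in batch_idx.values()])
        weights = np.array([n_b[b] / n_samp for b in self.batches])
        grand = M @ weights
        resid = X.copy()
        for j, b in enumerate(self.batches):
            resid[:, batch_idx[b]] -= M[:, [j]]
        var_pooled = (resid**2).mean(axis=1)
        if (var_pooled <= 0).any():
            bad = [features[i] for i in np.flatnonzero(var_pooled <= 0)]
            raise DataError(f"zero pooled variance for feature(s) {bad[:5]}")
        sd_pooled = np.sqrt(var_pooled)
        Z = (X - grand[:, None]) / sd_pooled[:, None]

        gamma_star = np.zeros((n_feat, len(self.batches)))
        delta_star = np.ones((n_feat, len(self.batches)))
        n_iters, converged = {}, {}
        for j, b in enumerate(self.batches):
            Zb = Z[:, batch_idx[b]]
            n_i = n_b[b]
            g_hat = Zb.mean(axis=1)
            d_hat = Zb.var(axis=1, ddof=1)
            g_bar = g_hat.mean()
            t2 = g_hat.var(ddof=1)
            d_mean = d_hat.mean()
            d_var = d_hat.var(ddof=1)
            if d_var <= 0 or t2 <= 0:
                # degenerate priors (e.g. all features identical): no shrinkage
                gamma_star[:, j] = g_hat
                delta_star[:, j] = d_hat
                n_iters[b] = 0
                converged[b] = True
                continue
            a_prior = (2 * d_var + d_mean**2) / d_var
            b_prior = (d_mean * d_var + d_mean**3) / d_var
            g_old = g_hat.copy()
            d_old = d_hat.copy()
            it = 0
            ok = False
            while it < max_iter:
                it += 1
                g_new = (n_i * t2 * g_hat + d_old * g_bar) / (n_i * t2 + d_old)
                sse = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (b_prior + 0.5 * sse) / (n_i / 2 + a_prior - 1)
                change = max(
                    np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                    np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
                )
                g_old, d_old = g_new, d_new
                if change < tol:
                    ok = True
                    break
            gamma_star[:, j] = g_old
            delta_star[:, j] = d_old
            n_iters[b] = it
            converged[b] = ok

        Zadj = Z.copy()
        for j, b in enumerate(self.batches):
            ix = batch_idx[b]
            Zadj[:, ix] = (Z[:, ix] - gamma_star[:, [j]]) / np.sqrt(delta_star[:, [j]])
        Xadj = Zadj * sd_pooled[:, None] + grand[:, None]
        # exact grand-mean restoration (see module docstring)
        Xadj += (X.mean(axis=1) - Xadj.mean(axis=1))[:, None]

        adj = BatchAdjustment(
            batches=list(self.batches),
            gamma_star=pd.DataFrame(gamma_star, index=features, columns=self.batches),
            delta_star=pd.DataFrame(delta_star, index=features, columns=self.batches),
            grand_mean=pd.Series(grand, index=features),
            pooled_sd=pd.Series(sd_pooled, index=features),
            n_iterations=n_iters,
            converged=converged,
        )
        out = AbundanceMatrix(
            pd.DataFrame(Xadj, index=features, columns=self.matrix.sample_ids), "log2"
        )
        return out, adj


def combat_adjust(matrix: AbundanceMatrix, batch_labels,
                  tol: float = 1e-4, max_iter: int = 100):
    """Functional wrapper: ``(adjusted_matrix, BatchAdjustment)``."""
    return CombatModel(matrix, batch_labels).fit(tol=tol, max_iter=max_iter)


# ---------------------------------------------------------------------------
# ROC ranking
# ---------------------------------------------------------------------------

def _auc_midrank(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    from scipy.stats import rankdata

    vals = np.concatenate([pos, neg])
    ranks = rankdata(vals)
    n1, n2 = len(pos), len(neg)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n2))


def _best_threshold_accuracy(pos: np.ndarray, neg: np.ndarray) -> float:
    """Accuracy at the best cut point (Youden-optimal for balanced cost).

    Both orientations of the decision rule are considered; candidate
    thresholds are midpoints between consecutive distinct pooled values
    (plus the trivial all-one-class rules).
    """
    vals = np.unique(np.concatenate([pos, neg]))
    cuts = np.concatenate([[vals[0] - 1.0], (vals[:-1] + vals[1:]) / 2,
                           [vals[-1] + 1.0]])
    n = len(pos) + len(neg)
    best = 0.0
    for c in cuts:
        acc_hi = ((pos > c).sum() + (neg <= c).sum()) / n
        acc_lo = ((pos <= c).sum() + (neg > c).sum()) / n
        best = max(best, acc_hi, acc_lo)
    return float(best)


def roc_single(values, labels, positive_label: str) -> dict:
    """AUC, orientation and best-threshold accuracy for one feature."""
    values = pd.Series(values)
    labels = pd.Series(labels).loc[values.index]
    pos = values[labels == positive_label].to_numpy(dtype=float)
    neg = values[labels != positive_label].to_numpy(dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("both groups must be non-empty for ROC")
    auc = _auc_midrank(pos, neg)
    direction = "up" if auc >= 0.5 else "down"
    return {
        "auc": max(auc, 1.0 - auc),
        "auc_raw": auc,
        "direction": direction,
        "accuracy": _best_threshold_accuracy(pos, neg),
        "n_pos": len(pos),
        "n_neg": len(neg),
    }


def roc_rank(matrix: AbundanceMatrix, labels, positive_label: str = "regeneration",
             ) -> pd.DataFrame:
    """Rank every species by orientation-corrected ROC AUC.

    ``labels`` maps sample id to a group; samples labelled
    ``positive_label`` are the positive class, all others negative. Both
    classes need >= 2 samples. Sorted by AUC descending (ties broken by
    feature id for determinism).
    """
    labels = pd.Series(labels).loc[matrix.sample_ids]
    n_pos = int((labels == positive_label).sum())
    n_neg = int((labels != positive_label).sum())
    if n_pos < 2 or n_neg < 2:
        raise DataError(f"need >= 2 samples per class (got {n_pos} vs {n_neg})")
    rows = []
    for fid in matrix.feature_ids:
        res = roc_single(matrix.values.loc[fid], labels, positive_label)
        res["species_id"] = fid
        rows.append(res)
    out = pd.DataFrame(rows).set_index("species_id")
    return out.sort_values(["auc", "accuracy", "species_id"],
                           ascending=[False, False, True], kind="stable")


# ---------------------------------------------------------------------------
# Development / regeneration signature intersection
# ---------------------------------------------------------------------------

def common_signatures(dev_enrichment: pd.DataFrame,
                      regen_enrichment: pd.DataFrame,
                      q_thr: float = 0.05,
                      feature_sets: dict | None = None,
                      terms=None) -> pd.DataFrame:
    """Terms significantly enriched (q < q_thr) in both analysis arms.

    Both inputs are :func:`~gcomics.enrichment.fisher_enrich` tables
    computed on compatible term universes (their ``term_id`` sets must
    overlap). When ``feature_sets`` and ``terms`` are supplied, per-arm
    annotation counts are attached via ``term_annotation_counts``.
    """
    dev_terms = set(dev_enrichment["term_id"])
    regen_terms = set(regen_enrichment["term_id"])
    if not dev_terms & regen_terms:
        raise DataError("disjoint term universes between arms")
    dev_sig = set(dev_enrichment.loc[dev_enrichment["q"] < q_thr, "term_id"])
    regen_sig = set(regen_enrichment.loc[regen_enrichment["q"] < q_thr, "term_id"])
    shared = sorted(dev_sig & regen_sig)
    out = pd.DataFrame({"term_id": shared})
    if shared:
        dq = dev_enrichment.set_index("term_id")["q"]
        rq = regen_enrichment.set_index("term_id")["q"]
        out["q_development"] = out["term_id"].map(dq)
        out["q_regeneration"] = out["term_id"].map(rq)
    else:
        out["q_development"] = np.array([], dtype=float)
        out["q_regeneration"] = np.array([], dtype=float)
    if feature_sets is not None and terms is not None and shared:
        from .enrichment import term_annotation_counts

        counts = term_annotation_counts(feature_sets, terms, shared)
        out = out.merge(counts, left_on="term_id", right_index=True, how="left")
    return out
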