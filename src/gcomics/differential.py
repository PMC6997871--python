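"""Two-group volcano statistics, linear stage-trend filtering, and per-class
treatment/timepoint tests.

Conventions: Welch (unequal-variance) t-tests throughout; log2 fold change
is the difference of group means in log2 space (group A minus group B);
Benjamini-Hochberg correction is applied within each analysis family. The
volcano gate is (q < q_thr) AND (|log2FC| > log2(fc_thr)); the trend gate is
(p < p_thr) AND (|r| > r_thr) with the raw p, the BH q being reported
alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix
from .exceptions import DataError

__all__ = ["two_group_diff", "stage_trend", "class_timepoint_tests"]


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def two_group_diff(
    matrix: AbundanceMatrix,
    labels,
    group_a: str,
    group_b: str,
    fc_thr: float = 2.0,
    q_thr: float = 0.05,
) -> pd.DataFrame:
    """Per-feature Welch t-test between two sample groups on log2 values.

    Returns a DataFrame indexed by feature with ``log2FC`` (A minus B),
    ``t``, ``p``, ``q`` and the ``significant`` volcano gate.
    """
    if matrix.space != "log2":
        raise DataError("two_group_diff expects a log2-space matrix")
    labels = pd.Series(labels)
    a_ids = [s for s in matrix.sample_ids if labels.get(s) == group_a]
    b_ids = [s for s in matrix.sample_ids if labels.get(s) == group_b]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise DataError(
            f"each group needs >= 2 samples (got {len(a_ids)} {group_a!r}, "
            f"{len(b_ids)} {group_b!r})"
        )
    A = matrix.values[a_ids].to_numpy(dtype=float)
    B = matrix.values[b_ids].to_numpy(dtype=float)
    t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    q = _bh(p)
    out = pd.DataFrame(
        {"log2FC": log2fc, "t": t, "p": p, "q": q},
        index=matrix.feature_ids,
    )
    out["significant"] = (out["q"] < q_thr) & (out["log2FC"].abs() > np.log2(fc_thr))
    out.index.name = "feature_id"
    return out


def stage_trend(
    matrix: AbundanceMatrix,
    stage_ordinal,
    r_thr: float = 0.7,
    p_thr: float = 0.01,
) -> pd.DataFrame:
    """Pearson correlation of every feature with the stage ordinal.

    Two-sided p from the t-distribution with n-2 df; BH q reported. The
    ``direction`` column is ``increasing``/``decreasing`` under the joint
    gate (p < p_thr) AND (|r| > r_thr), else ``none``. Constant features
    are excluded with reason ``zero variance``.
    """
    if matrix.space not in ("log2", "autoscaled"):
        raise DataError("stage_trend expects log2 (or autoscaled) values")
    y = pd.Series(stage_ordinal).loc[matrix.sample_ids].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise DataError("all samples share one stage: trend undefined")
    X = matrix.values.to_numpy(dtype=float)
    n = X.shape[1]
    yc = y - y.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    constant = sx == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(p)] = 0.0 if n > 2 else 1.0   # |r| == 1 exactly
    out = pd.DataFrame({"r": r, "p": p}, index=matrix.feature_ids)
    out.loc[constant, ["r", "p"]] = np.nan
    ok = ~constant
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok] = _bh(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    gate = ok & (out["p"] < p_thr) & (out["r"].abs() > r_thr)
    out["direction"] = "none"
    out.loc[gate & (out["r"] > 0), "direction"] = "increasing"
    out.loc[gate & (out["r"] < 0), "direction"] = "decreasing"
    out["excluded_reason"] = ""
    out.loc[constant, "excluded_reason"] = "zero variance"
    out.index.name = "feature_id"
    return out


def class_timepoint_tests(
    class_matrix: AbundanceMatrix,
    meta: pd.DataFrame,
    contrasts,
    control_treatment: str = "control",
) -> pd.DataFrame:
    """Per-class Welch t-tests of (treatment, day) groups against control.

    ``contrasts`` is an iterable of (treatment, day) pairs. Significance
    tiers: ``*`` at p < 0.05, ``***`` at p < 0.001. The mean difference is
    reported in the matrix's own space (log2 recommended).
    """
    ctrl_ids = meta.index[meta["treatment"] == control_treatment].tolist()
    if len(ctrl_ids) < 2:
        raise DataError(f"control group {control_treatment!r} missing or too small")
    C = class_matrix.values[ctrl_ids].to_numpy(dtype=float)
    rows = []
    for treatment, day in contrasts:
        sel = meta["treatment"] == treatment
        if day is not None:
            sel &= meta["day"] == day
        ids = meta.index[sel].tolist()
        if len(ids) < 2:
            raise DataError(f"contrast group ({treatment!r}, day {day}) missing")
        G = class_matrix.values[ids].to_numpy(dtype=float)
        t, p = stats.ttest_ind(G, C, axis=1, equal_var=False)
        diff = G.mean(axis=1) - C.mean(axis=1)
        for cls, d, tv, pv in zip(class_matrix.feature_ids, diff, t, p):
            tier = "***" if pv < 0.001 else ("*" if pv < 0.05 else "")
            rows.append(
                {
                    "class_code": cls,
                    "treatment": treatment,
                    "day": day,
                    "mean_diff": d,
                    "t": tv,
                    "p": pv,
                    "tier": tier,
                }
            )
    return pd.DataFrame(rows)
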