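"""Protein-lipid correlation integration.

Four steps build the correlation network: (1) a full Pearson matrix between
lipid species (or classes) and proteins over matched samples; (2) filtering
of literature protein-protein edges by a dual requirement — both endpoints
detected in the proteome, and their abundance profiles significantly
correlated with each other across development; (3) combination of a
protein's per-species correlations within a lipid class by Fisher's
r-to-Z-to-r transform (average on the atanh scale, back-transform with
tanh); (4) annotation of curated protein complexes with per-member stage
correlations and an r-to-Z-to-r complex summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix
from .exceptions import DataError

__all__ = [
    "pl_correlation", "PlCorrelation",
    "filter_pp_edges", "fisher_combine",
    "combine_by_class", "annotate_complexes",
]

_R_CLIP = 1.0 - 1e-6


class PlCorrelation:
    """Lipid x protein Pearson matrix with companion p-values."""

    def __init__(self, r: pd.DataFrame, p: pd.DataFrame, n_samples: int,
                 constant_lipids=(), constant_proteins=()):
        self.r = r
        self.p = p
        self.n_samples = n_samples
        self.constant_lipids = list(constant_lipids)
        self.constant_proteins = list(constant_proteins)


def pl_correlation(protein_matrix: AbundanceMatrix,
                   lipid_matrix: AbundanceMatrix) -> PlCorrelation:
    """Pearson r and p for every (lipid, protein) pair over shared samples.

    Sample ids are intersected (order of the protein matrix); at least 3
    shared samples are required. Constant rows yield NaN and are flagged.
    """
    shared = [s for s in protein_matrix.sample_ids if s in set(lipid_matrix.sample_ids)]
    if not shared:
        raise DataError("no shared samples between protein and lipid matrices")
    if len(shared) < 3:
        raise DataError(f"only {len(shared)} shared samples; need >= 3")
    P = protein_matrix.values[shared].to_numpy(dtype=float)
    L = lipid_matrix.values[shared].to_numpy(dtype=float)
    n = len(shared)

    def _standardize(X):
        Xc = X - X.mean(axis=1, keepdims=True)
        s = np.sqrt((Xc**2).sum(axis=1))
        const = s == 0
        s[const] = 1.0
        return Xc / s[:, None], const

    Zp, const_p = _standardize(P)
    Zl, const_l = _standardize(L)
    R = Zl @ Zp.T
    R = np.clip(R, -1.0, 1.0)
    R[const_l, :] = np.nan
    R[:, const_p] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = R * np.sqrt(n - 2) / np.sqrt(1.0 - R**2)
        pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pvals[np.abs(R) >= 1.0] = 0.0
    r_df = pd.DataFrame(R, index=lipid_matrix.feature_ids,
                        columns=protein_matrix.feature_ids)
    p_df = pd.DataFrame(pvals, index=lipid_matrix.feature_ids,
                        columns=protein_matrix.feature_ids)
    return PlCorrelation(
        r_df, p_df, n,
        constant_lipids=[f for f, c in zip(lipid_matrix.feature_ids, const_l) if c],
        constant_proteins=[f for f, c in zip(protein_matrix.feature_ids, const_p) if c],
    )


def filter_pp_edges(edges: pd.DataFrame, matrix: AbundanceMatrix,
                    detected_proteins=None, p_thr: float = 0.01,
                    strict: bool = False) -> pd.DataFrame:
    """Dual-requirement filter of a literature protein-protein edge list.

    An edge survives iff (1) both endpoints are in ``detected_proteins``
    (default: the matrix's features) and (2) the two endpoints' abundance
    profiles are significantly Pearson-correlated with each other across
    the matrix's samples (p < p_thr, either sign). Edges naming unknown
    proteins raise in strict mode, otherwise they are dropped and counted.

    Returns the edge table with canonical endpoint ordering and columns
    ``r``, ``p``, ``retained``.
    """
    if detected_proteins is None:
        detected_proteins = matrix.feature_ids
    detected = set(detected_proteins) & set(matrix.feature_ids)
    out = edges.copy()
    a = out["protein_a"].to_numpy()
    b = out["protein_b"].to_numpy()
    swap = a > b
    out["protein_a"] = np.where(swap, b, a)
    out["protein_b"] = np.where(swap, a, b)
    if (out["protein_a"] == out["protein_b"]).any():
        raise DataError("self-edge in protein-protein edge list")
    rs, ps, keep = [], [], []
    X = matrix.values
    for pa, pb in zip(out["protein_a"], out["protein_b"]):
        if pa not in detected or pb not in detected:
            if strict and (pa not in set(matrix.feature_ids)
                           or pb not in set(matrix.feature_ids)):
                raise DataError(f"edge references unknown protein: {pa!r}-{pb!r}")
            rs.append(np.nan)
            ps.append(np.nan)
            keep.append(False)
            continue
        r, p = stats.pearsonr(X.loc[pa], X.loc[pb])
        rs.append(float(r))
        ps.append(float(p))
        keep.append(bool(p < p_thr))
    out["r"] = rs
    out["p"] = ps
    out["retained"] = keep
    return out


def fisher_combine(r_values) -> float:
    """Combine correlations by averaging Fisher Z values and back-transforming.

    Values are clipped to +/-(1 - 1e-6) so the transform stays finite;
    the result is order-invariant, bounded in (-1, 1), the identity on a
    single value, and monotone in every argument.
    """
    r = np.asarray(list(r_values), dtype=float)
    if r.size == 0:
        raise DataError("fisher_combine requires at least one correlation")
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    return float(np.tanh(np.arctanh(r).mean()))


def combine_by_class(plc: PlCorrelation, species_class: dict,
                     proteins=None) -> pd.DataFrame:
    """Per-protein combined correlation with every lipid class.

    For each protein the Pearson correlations with all species of a class
    are merged by :func:`fisher_combine`, yielding the class-level combined
    coefficients attached to network edges.
    """
    proteins = list(proteins) if proteins is not None else list(plc.r.columns)
    classes = sorted(set(species_class.values()))
    rows = {}
    for cls in classes:
        members = [s for s, c in species_class.items() if c == cls and s in plc.r.index]
        if not members:
            continue
        sub = plc.r.loc[members, proteins]
        rows[cls] = {
            prot: fisher_combine(col.dropna()) if col.notna().any() else np.nan
            for prot, col in sub.items()
        }
    out = pd.DataFrame(rows)
    out.index.name = "protein_id"
    return out


def annotate_complexes(complexes, trend_results: pd.DataFrame) -> pd.DataFrame:
    """Attach per-member stage correlations and a combined summary to
    curated protein complexes.

    ``trend_results`` is the stage-trend table (indexed by feature with an
    ``r`` column); members absent from it are counted as undetected.
    Complexes with fewer than two detected members are flagged rather than
    dropped, and get no summary.
    """
    rows = []
    detected = set(trend_results.index)
    for cpx in complexes:
        members = sorted(cpx.members)
        present = [m for m in members if m in detected]
        rs = trend_results.loc[present, "r"].dropna()
        summary = fisher_combine(rs) if len(rs) >= 2 else np.nan
        rows.append(
            {
                "complex_id": cpx.term_id,
                "description": cpx.description,
                "n_members": len(members),
                "n_detected": len(present),
                "member_r": ";".join(f"{m}={trend_results.loc[m, 'r']:.3f}"
                                     for m in present),
                "combined_r": summary,
                "flagged": len(rs) < 2,
            }
        )
    return pd.DataFrame(rows)
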