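"""Term-annotation over-representation analysis (Fisher exact + BH) and
per-term annotation counting.

This is the generic set-enrichment formulation standing behind the
ontology-style analyses (cellular compartments, lipid biophysical terms):
for every term the overlap of a selected feature set with the term's
members inside a detection-conditioned background is scored with the
one-sided upper-tail hypergeometric probability, then Benjamini-Hochberg
corrected across terms. Depletion is available through the complementary
tail.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError

__all__ = ["fisher_enrich", "term_annotation_counts"]


def fisher_enrich(selected, background, terms, q_thr: float = 0.05,
                  alternative: str = "enrichment") -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` within ``terms``.

    Parameters
    ----------
    selected, background : iterable of feature ids
        ``selected`` must be a subset of ``background``; terms are
        intersected with the background before testing (terms that vanish
        are dropped).
    alternative : "enrichment" | "depletion"
        Upper tail P(X >= k) or lower tail P(X <= k).

    Returns a DataFrame with one row per surviving term: overlap ``k``,
    selection size ``n``, term size ``K``, background ``N``, odds ratio,
    ``p``, BH ``q`` and the ``enriched`` flag at q < q_thr.
    """
    selected = set(selected)
    background = set(background)
    if not selected:
        raise DataError("empty selection")
    stray = selected - background
    if stray:
        raise DataError(f"selected features outside background: {sorted(stray)[:5]}")
    N = len(background)
    n = len(selected)
    rows = []
    for term in terms:
        members = set(term.members) & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & selected)
        if alternative == "enrichment":
            p = float(hypergeom.sf(k - 1, N, K, n))
        elif alternative == "depletion":
            p = float(hypergeom.cdf(k, N, K, n))
        else:
            raise DataError(f"unknown alternative {alternative!r}")
        # odds ratio of the 2x2 table (selected x in-term), Haldane corrected
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        rows.append(
            {"term_id": term.term_id, "description": term.description,
             "k": k, "n": n, "K": K, "N": N, "odds_ratio": orat, "p": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out["enriched"] = out["q"] < q_thr
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        out["q"] = np.array([], dtype=float)
        out["enriched"] = np.array([], dtype=bool)
    return out


def term_annotation_counts(feature_sets: dict, terms, significant_terms) -> pd.DataFrame:
    """Annotation counts per significant term for each labelled feature set.

    ``feature_sets`` maps a label (e.g. ``early development``,
    ``regeneration``) to a feature-id set; the returned table has one row
    per significant term and one column per label, holding the number of
    that set's members annotated to the term — the per-term bar quantities
    of the early-vs-late and development-vs-regeneration comparisons.
    """
    by_id = {t.term_id: t for t in terms}
    unknown = [t for t in significant_terms if t not in by_id]
    if unknown:
        raise DataError(f"unknown term id(s): {unknown[:5]}")
    data = {}
    for label, feats in feature_sets.items():
        feats = set(feats)
        data[label] = {
            tid: len(set(by_id[tid].members) & feats) for tid in significant_terms
        }
    out = pd.DataFrame(data)
    out.index.name = "term_id"
    return out
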