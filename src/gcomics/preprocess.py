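"""Normalization, QC (coefficients of variation), lipid-name parsing and
species-to-class aggregation.

The lipid shorthand grammar accepted by :func:`parse_lipid_name` is
``CLASS(chain[/chain...])`` where each chain is ``[d|t]C:D`` — carbons,
double bonds, with an optional sphingoid hydroxylation prefix (d = di-, t =
tri-hydroxy base). Examples: ``Cer(d18:1/24:0)``, ``TG(16:0/18:1/18:2)``,
``LPC(16:0)``. Unknown class codes pass through verbatim (flagged via
``known_class``) rather than failing, so novel classes survive the pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix
from .exceptions import DataError

# Lipid class codes with an expected chain count; anything else still parses
# but is flagged as unknown.
KNOWN_CLASS_CHAINS = {
    "PC": 2, "PE": 2, "PS": 2, "PI": 2, "PG": 2, "PA": 2, "CL": 4,
    "TG": 3, "DG": 2, "MG": 1, "ChE": 1, "ZyE": 1,
    "Cer": 2, "SM": 2, "CerG1": 2, "So": 1,
    "LPC": 1, "LPE": 1, "LPS": 1, "LPG": 1,
}

_NAME_RE = re.compile(r"^([A-Za-z0-9]+)\(([^()]+)\)$")
_CHAIN_RE = re.compile(r"^([dt]?)(\d+):(\d+)$")


@dataclass(frozen=True)
class LipidAnnotation:
    """Parsed lipid species name."""

    species_id: str
    class_code: str
    chains: tuple  # of (carbons, double_bonds, prefix) with prefix in {"", "d", "t"}
    known_class: bool

    @property
    def total_carbons(self) -> int:
        return sum(c for c, _, _ in self.chains)

    @property
    def total_double_bonds(self) -> int:
        return sum(d for _, d, _ in self.chains)


def parse_lipid_name(name: str) -> LipidAnnotation:
    """Parse a shorthand lipid species name into class and acyl chains."""
    m = _NAME_RE.match(name.strip())
    if not m:
        raise DataError(f"unparseable lipid name: {name!r}")
    cls, body = m.group(1), m.group(2)
    chains = []
    for part in body.split("/"):
        cm = _CHAIN_RE.match(part.strip())
        if not cm:
            raise DataError(f"unparseable chain {part!r} in lipid name {name!r}")
        chains.append((int(cm.group(2)), int(cm.group(3)), cm.group(1)))
    return LipidAnnotation(
        species_id=name.strip(),
        class_code=cls,
        chains=tuple(chains),
        known_class=cls in KNOWN_CLASS_CHAINS,
    )


def format_lipid_name(ann: LipidAnnotation) -> str:
    """Inverse of :func:`parse_lipid_name` (identity on parsed names)."""
    body = "/".join(f"{p}{c}:{d}" for c, d, p in ann.chains)
    return f"{ann.class_code}({body})"


def annotate_species(species_ids) -> pd.DataFrame:
    """Annotation table (class, chain totals) for a list of species names."""
    rows = []
    for sid in species_ids:
        ann = parse_lipid_name(sid)
        rows.append(
            {
                "species_id": sid,
                "class_code": ann.class_code,
                "n_chains": len(ann.chains),
                "total_carbons": ann.total_carbons,
                "total_double_bonds": ann.total_double_bonds,
                "known_class": ann.known_class,
            }
        )
    return pd.DataFrame(rows).set_index("species_id")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(
    matrix: AbundanceMatrix,
    method: str = "total_intensity",
    to_log2: bool = False,
    pseudocount: float = 1.0,
) -> AbundanceMatrix:
    """Column (sample) normalization, optionally followed by log2.

    ``total_intensity`` rescales every sample so its column sum equals the
    mean column sum; ``median`` equalizes column medians; ``autoscale``
    standardizes every feature to zero mean and unit (n-1) variance across
    samples. log2(x + pseudocount) is applied after scaling when requested.
    """
    X = matrix.values
    if method in ("total_intensity", "median"):
        if matrix.space != "raw":
            raise DataError(f"{method} normalization expects a raw-space matrix")
        stat = X.sum(axis=0) if method == "total_intensity" else X.median(axis=0)
        bad = stat.index[stat <= 0].tolist()
        if bad:
            raise DataError(
                f"zero column {'sum' if method == 'total_intensity' else 'median'} "
                f"in sample(s) {bad[:5]}"
            )
        scaled = X * (stat.mean() / stat)
        out = AbundanceMatrix(scaled, "raw")
        if to_log2:
            out = out.to_log2(pseudocount)
        return out
    if method == "autoscale":
        mu = X.mean(axis=1)
        sd = X.std(axis=1, ddof=1)
        bad = sd.index[~(sd > 0)].tolist()
        if bad:
            raise DataError(f"constant feature(s) cannot be autoscaled: {bad[:5]}")
        return AbundanceMatrix(X.sub(mu, axis=0).div(sd, axis=0), "autoscaled")
    raise DataError(f"unknown normalization method {method!r}")


# ---------------------------------------------------------------------------
# Coefficients of variation
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Per-feature per-group CVs plus within/between dispersion summary.

    ``per_feature`` is a features x groups DataFrame of CV = SD/mean (n-1
    SD, raw intensities). ``group_medians`` is the median CV per group,
    ``median_within`` the overall median within-group CV and
    ``median_between`` the median across features of the CV of group means —
    the intra- vs inter-group comparison reported for replicate QC.
    """

    per_feature: pd.DataFrame
    group_medians: pd.Series
    median_within: float
    median_between: float

    def summary(self) -> str:
        lines = ["Coefficient-of-variation report", "-" * 33]
        for g, v in self.group_medians.items():
            lines.append(f"median CV [{g}]: {v:.4f}")
        lines.append(f"median within-group CV : {self.median_within:.4f}")
        lines.append(f"median between-group CV: {self.median_between:.4f}")
        return "\n".join(lines)


def compute_cv(matrix: AbundanceMatrix, grouping) -> CvReport:
    """Within-group coefficients of variation on raw intensities.

    Parameters
    ----------
    matrix : AbundanceMatrix
        Raw-space matrix (CV is undefined on log2 values).
    grouping : mapping or Series
        sample id -> group label; every group needs >= 2 samples.
    """
    if matrix.space != "raw":
        raise DataError("compute_cv requires raw-space intensities, not log2")
    grouping = pd.Series(grouping)
    missing = [s for s in matrix.sample_ids if s not in grouping.index]
    if missing:
        raise DataError(f"samples without a group: {missing[:5]}")
    groups = grouping.loc[matrix.sample_ids]
    X = matrix.values
    cvs = {}
    means = {}
    for g, idx in groups.groupby(groups).groups.items():
        if len(idx) < 2:
            raise DataError(f"group {g!r} has fewer than 2 samples")
        sub = X.loc[:, list(idx)]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        cvs[g] = sd / mu
        means[g] = mu
    per_feature = pd.DataFrame(cvs)
    group_means = pd.DataFrame(means)
    if group_means.shape[1] >= 2:
        between = group_means.std(axis=1, ddof=1) / group_means.mean(axis=1)
        median_between = float(between.median())
    else:
        median_between = float("nan")   # between-group dispersion undefined
    return CvReport(
        per_feature=per_feature,
        group_medians=per_feature.median(axis=0),
        median_within=float(per_feature.stack().median()),
        median_between=median_between,
    )


# ---------------------------------------------------------------------------
# Class aggregation
# ---------------------------------------------------------------------------

def aggregate_lipid_classes(matrix: AbundanceMatrix, annotations=None) -> AbundanceMatrix:
    """Sum species intensities into lipid-class abundances per sample.

    ``annotations`` maps species id -> class code; by default class codes
    are parsed from the species names. Aggregation conserves per-sample
    total intensity exactly (it is a partition of the rows).
    """
    if matrix.space != "raw":
        raise DataError("class aggregation expects raw-space species intensities")
    if annotations is None:
        annotations = {s: parse_lipid_name(s).class_code for s in matrix.feature_ids}
    else:
        annotations = dict(annotations)
    missing = [s for s in matrix.feature_ids if s not in annotations]
    if missing:
        raise DataError(f"unannotated species: {missing[:5]}")
    classes = pd.Series({s: annotations[s] for s in matrix.feature_ids})
    agg = matrix.values.groupby(classes).sum()
    agg = agg.sort_index()
    return AbundanceMatrix(agg, "raw")
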