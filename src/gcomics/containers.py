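"""Core in-memory containers: abundance matrices, sample metadata, term sets.

An :class:`AbundanceMatrix` is a thin wrapper around a features x samples
:class:`pandas.DataFrame` that also tracks which *space* the values live in:

``raw``
    non-negative ion intensities, the space in which coefficients of
    variation and class aggregation are defined;
``log2``
    log2-transformed intensities, the space of fold changes, trend
    correlations and batch correction;
``autoscaled``
    per-feature zero-mean / unit-variance values used by PCA, PLS and
    clustering.

Sample metadata is a plain DataFrame indexed by sample id with the factor
columns ``fraction``, ``stage``, ``replicate``, ``treatment``, ``day`` and
``batch``; helpers here validate it and map developmental stages onto the
ordinal scale E18=0 ... P9=4 used by every trend analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError

#: Developmental stages in chronological order; index = stage ordinal.
STAGE_ORDER = ("E18", "P0", "P3", "P6", "P9")
STAGE_ORDINAL = {s: i for i, s in enumerate(STAGE_ORDER)}

VALID_SPACES = ("raw", "log2", "autoscaled")


@dataclass
class AbundanceMatrix:
    """Features x samples intensity table with a space flag.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are feature ids (proteins, lipid species or lipid classes),
        columns are sample ids. Both must be unique.
    space : str
        One of ``raw``, ``log2`` or ``autoscaled``. Raw-space values must be
        non-negative.
    """

    values: pd.DataFrame
    space: str = "raw"

    def __post_init__(self) -> None:
        if self.space not in VALID_SPACES:
            raise DataError(f"unknown matrix space {self.space!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise DataError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise DataError(f"duplicate sample ids: {dups[:5]}")
        if self.space == "raw" and (self.values.to_numpy() < 0).any():
            raise DataError("raw-space matrix contains negative values")

    # -- convenience -----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "AbundanceMatrix":
        """Matrix restricted to ``sample_ids`` (order preserved as given)."""
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise DataError(f"unknown sample ids: {missing[:5]}")
        return AbundanceMatrix(self.values.loc[:, list(sample_ids)].copy(), self.space)

    def subset_features(self, feature_ids) -> "AbundanceMatrix":
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise DataError(f"unknown feature ids: {missing[:5]}")
        return AbundanceMatrix(self.values.loc[list(feature_ids)].copy(), self.space)

    def to_log2(self, pseudocount: float = 1.0) -> "AbundanceMatrix":
        """log2(x + pseudocount) transform of a raw matrix."""
        if self.space != "raw":
            raise DataError("to_log2 expects a raw-space matrix")
        return AbundanceMatrix(np.log2(self.values + pseudocount), "log2")

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, path, provenance: str | None = None) -> None:
        """Write as TSV with a ``feature_id`` first column.

        An optional provenance string is embedded as a ``#`` comment line so
        every serialized table records where it came from; readers skip it.
        """
        with open(path, "w", newline="\n") as fh:
            if provenance:
                fh.write(f"# {provenance}\n")
            df = self.values.copy()
            df.index.name = "feature_id"
            df.to_csv(fh, sep="\t", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path, space: str = "raw") -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, space)


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table and return it indexed by sample id."""
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    if meta.index.has_duplicates:
        raise DataError("duplicate sample ids in metadata")
    if "stage" in meta.columns:
        bad = set(meta["stage"].dropna()) - set(STAGE_ORDER)
        if bad:
            raise DataError(f"unknown stages in metadata: {sorted(bad)}")
    return meta


def stage_ordinal(meta: pd.DataFrame) -> pd.Series:
    """Stage ordinals (E18=0 ... P9=4) for every sample carrying a stage."""
    if "stage" not in meta.columns:
        raise DataError("metadata has no 'stage' column")
    return meta["stage"].map(STAGE_ORDINAL)


def read_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#")
    return validate_meta(meta)


def write_meta(meta: pd.DataFrame, path, provenance: str | None = None) -> None:
    with open(path, "w", newline="\n") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        out = meta.copy()
        out.index.name = "sample_id"
        out.to_csv(fh, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# Term sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermSet:
    """A named annotation term with its member feature ids."""

    term_id: str
    description: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.members:
            raise DataError(f"term {self.term_id!r} has no members")


def read_gmt(path) -> list[TermSet]:
    """Read a GMT file (name TAB description TAB member...)."""
    terms = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"malformed GMT line: {line[:60]!r}")
            term_id, desc, members = parts[0], parts[1], parts[2:]
            if term_id in seen:
                raise DataError(f"duplicate term id {term_id!r}")
            seen.add(term_id)
            terms.append(TermSet(term_id, desc, frozenset(m for m in members if m)))
    return terms


def write_gmt(terms, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.description, *sorted(t.members)]) + "\n")
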