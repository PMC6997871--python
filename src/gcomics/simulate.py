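"""Synthetic multi-omic growth-cone and optic-nerve regeneration data.

The generators plant the statistical structure every downstream stage is
designed to recover, so the whole pipeline is testable without any raw
LC-MS/MS data:

* a growth-cone (GC) arm: proteins and lipid species measured in two
  subcellular fractions (growth cone membrane GCM, growth cone particulate
  GCP) across five developmental stages (E18, P0, P3, P6, P9) with ~6
  biological replicates per cell (GCM/E18 and GCP/P9 reduced to 5, i.e.
  29 + 29 = 58 proteome samples);
* a regeneration arm: an adult optic-nerve lipidome with uninjured controls,
  crush + saline, and two regeneration-inducing treatments (Wnt3a, Zymosan)
  measured at 3/7/15 days post injection, with per-experiment batch offsets
  and one lipid species planted to separate regenerating from control
  samples essentially perfectly.

Measurement noise is multiplicative lognormal: intensities are built in
log2 space as baseline + planted effects + Normal(0, sigma) with
``sigma = sqrt(ln(1 + CV^2)) / ln 2`` so the within-group coefficient of
variation on the raw scale is targetable directly.

Planted effects (all multiplicative, i.e. additive in log2):

* protein stage trends, linear in the stage ordinal (E18=0 ... P9=4),
  slope expressed in noise-SD units per stage;
* a fraction (GCM vs GCP) shift on a subset of proteins and lipid species;
* lipid-class "switching": species of early classes (sterols,
  acylglycerols, sphingosine) are elevated at E18-P0 and low afterwards,
  late classes (lysolipids, monohexosylceramide) the reverse — a step
  profile, matching the early/late partition the class analysis recovers;
* protein-lipid co-trends: a few trend proteins share the stage profile of
  an early or late lipid class, giving recoverable P:L correlations and
  correlated protein-protein edges;
* regeneration effects: a marker species elevated by several SD in
  Wnt3a/Zymosan samples, class-level day-7/day-15 shifts, crush-depleted
  species, and additive per-batch offsets.

Every generator is deterministic given (config, seed).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, STAGE_ORDER, TermSet
from .exceptions import ConfigurationError, DataError

__all__ = [
    "GcConfig",
    "RegenConfig",
    "SyntheticTruth",
    "GcBundle",
    "RegenBundle",
    "generate_gc_multiomic",
    "generate_regen_lipidome",
    "generate_knowledge_tables",
    "lipid_term_sets",
    "CLASS_TERMS",
]

# ---------------------------------------------------------------------------
# Static knowledge: lipid classes, chain grammar, biophysical term map
# ---------------------------------------------------------------------------

#: classes used by the generators (20), with chain counts and sphingoid flag
GENERATOR_CLASSES = (
    "PC", "PE", "PS", "PI", "PG", "PA", "CL",
    "TG", "DG", "MG", "ChE", "ZyE",
    "Cer", "SM", "CerG1", "So",
    "LPC", "LPE", "LPS", "LPG",
)
_CLASS_CHAINS = {
    "PC": 2, "PE": 2, "PS": 2, "PI": 2, "PG": 2, "PA": 2, "CL": 4,
    "TG": 3, "DG": 2, "MG": 1, "ChE": 1, "ZyE": 1,
    "Cer": 2, "SM": 2, "CerG1": 2, "So": 1,
    "LPC": 1, "LPE": 1, "LPS": 1, "LPG": 1,
}
_SPHINGOID = {"Cer", "SM", "CerG1", "So"}

#: Static lipid-class -> biophysical/chemical ontology term map. This is the
#: packaged stand-in knowledge table from which GMT term sets are expanded to
#: species membership. Terms mirror the vocabulary of lipid ontologies
#: (storage, membrane, headgroup charge, bilayer biophysics).
CLASS_TERMS = {
    "TG": ["triacylglycerol", "glycerolipid", "lipid storage", "lipid droplet",
           "headgroup with neutral charge"],
    "DG": ["glycerolipid", "lipid storage", "lipid droplet",
           "headgroup with neutral charge"],
    "MG": ["glycerolipid", "lipid storage", "lipid droplet",
           "headgroup with neutral charge"],
    "ChE": ["sterol lipid", "lipid storage", "lipid droplet",
            "headgroup with neutral charge", "high bilayer thickness"],
    "ZyE": ["sterol lipid", "lipid storage", "lipid droplet",
            "high bilayer thickness"],
    "So": ["sphingolipid", "headgroup with neutral charge",
           "above average transition temperature"],
    "Cer": ["sphingolipid", "membrane", "above average transition temperature",
            "high bilayer thickness"],
    "SM": ["sphingolipid", "membrane", "headgroup with neutral charge",
           "above average transition temperature"],
    "CerG1": ["sphingolipid", "glycosphingolipid", "membrane",
              "high lateral diffusion"],
    "PC": ["glycerophospholipid", "membrane", "headgroup with neutral charge",
           "low lateral diffusion"],
    "PE": ["glycerophospholipid", "membrane", "negative intrinsic curvature"],
    "PS": ["glycerophospholipid", "membrane", "headgroup with negative charge"],
    "PI": ["glycerophospholipid", "membrane", "headgroup with negative charge"],
    "PG": ["glycerophospholipid", "membrane", "headgroup with negative charge"],
    "PA": ["glycerophospholipid", "headgroup with negative charge",
           "negative intrinsic curvature"],
    "CL": ["glycerophospholipid", "mitochondrion", "headgroup with negative charge",
           "negative intrinsic curvature"],
    "LPC": ["lysolipid", "membrane", "positive intrinsic curvature",
            "high lateral diffusion", "below average bilayer thickness"],
    "LPE": ["lysolipid", "membrane", "positive intrinsic curvature",
            "high lateral diffusion", "below average bilayer thickness"],
    "LPS": ["lysolipid", "positive intrinsic curvature",
            "high lateral diffusion", "below average bilayer thickness"],
    "LPG": ["lysolipid", "positive intrinsic curvature",
            "high lateral diffusion", "below average bilayer thickness"],
}


def noise_sigma_log2(cv: float) -> float:
    """Log2-space noise SD that yields a raw-scale CV of ``cv``."""
    return float(np.sqrt(np.log1p(cv**2)) / np.log(2))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class GcConfig:
    """Generator settings for the growth-cone multi-omic bundle.

    Effect sizes are expressed in units of the log2 noise SD unless the
    field name says log2. Defaults encode the study design: 2 fractions x
    5 stages x 6 replicates with the GCM/E18 and GCP/P9 cells at n=5.
    """

    n_proteins: int = 600
    n_lipid_species: int = 200
    n_replicates: int = 6
    #: (fraction, stage) cells with a reduced replicate count
    reduced_cells: dict = field(
        default_factory=lambda: {("GCM", "E18"): 5, ("GCP", "P9"): 5}
    )
    noise_cv: float = 0.08
    # protein effects
    n_trend_pos: int = 60
    n_trend_neg: int = 60
    trend_slope_sd: float = 1.0          #: log2 slope per stage, in noise-SD units
    coupled_slope_sd: float = 1.5        #: slope for P:L-coupled proteins
    n_fraction_effect: int = 200
    fraction_shift_log2: float = 2.0     #: GCM-vs-GCP shift, log2 units
    # lipid effects
    early_classes: tuple = ("TG", "DG", "MG", "ChE", "ZyE", "So")
    late_classes: tuple = ("CerG1", "LPC", "LPS", "LPG")
    class_switch_sd: float = 3.0         #: early/late step amplitude, noise-SD units
    n_lipid_fraction_effect: int = 40
    lipid_fraction_shift_log2: float = 1.5
    n_coupled_per_class: int = 8         #: proteins co-trending with TG / CerG1
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0

    def validate(self) -> None:
        for name in ("n_proteins", "n_lipid_species", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.noise_cv <= 0:
            raise ConfigurationError("noise_cv must be positive")
        if set(self.early_classes) & set(self.late_classes):
            raise ConfigurationError("early and late class sets overlap")
        n_effects = self.n_trend_pos + self.n_trend_neg + self.n_fraction_effect
        if n_effects > self.n_proteins:
            raise ConfigurationError("more planted protein effects than proteins")
        if self.n_coupled_per_class > min(self.n_trend_pos, self.n_trend_neg):
            raise ConfigurationError("coupled proteins exceed trend protein pool")


@dataclass
class RegenConfig:
    """Generator settings for the optic-nerve regeneration lipidome.

    Group sizes default to the study design: uninjured control n=21, crush +
    saline n=16, crush + Wnt3a n=6, crush + Zymosan n=10 (53 samples), with
    treated samples spread over 3/7/15 days post injection and the two
    regeneration experiments carrying distinct batch offsets.
    """

    n_species: int = 208
    n_control: int = 21
    n_crush_saline: int = 16
    n_wnt3a: int = 6
    n_zymosan: int = 10
    noise_cv: float = 0.08
    marker_species: str = "Cer(d18:1/24:0)"
    marker_sep_sd: float = 8.0           #: regeneration-vs-control shift of the marker
    n_crush_depleted: int = 9            #: 8 PC + 1 PE species down after crush
    crush_depletion_log2: float = 1.5
    #: class-level regeneration effects in noise-SD units, keyed by class:
    #: (day-7 shift, day-15 shift); positive = up in regenerating samples
    class_effects: dict = field(
        default_factory=lambda: {
            "TG": (1.5, 4.0),
            "CerG1": (-1.5, -4.0),
            "MG": (0.0, 4.0),
            "PG": (0.0, 4.0),
        }
    )
    #: additive log2 offsets per batch; the control/crush reference batch is 0
    batch_shifts: dict = field(
        default_factory=lambda: {
            "reference": 0.0,
            "wnt3a_batch": 0.6,
            "zymosan_batch": -0.4,
        }
    )
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0

    def validate(self) -> None:
        for name in ("n_control", "n_crush_saline", "n_wnt3a", "n_zymosan"):
            if getattr(self, name) < 2:
                raise ConfigurationError(f"{name} must be at least 2")
        if self.n_species <= 0:
            raise ConfigurationError("n_species must be positive")
        if self.noise_cv <= 0:
            raise ConfigurationError("noise_cv must be positive")


# ---------------------------------------------------------------------------
# Truth record and bundles
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Record of every planted parameter, for parameter-recovery tests."""

    noise_cv: float = 0.08
    trend_proteins_pos: list = field(default_factory=list)
    trend_proteins_neg: list = field(default_factory=list)
    fraction_effect_features: list = field(default_factory=list)
    early_classes: list = field(default_factory=list)
    late_classes: list = field(default_factory=list)
    pl_coupled_pairs: list = field(default_factory=list)   # (protein_id, class_code)
    planted_edges: list = field(default_factory=list)      # (protein_a, protein_b)
    planted_complexes: dict = field(default_factory=dict)  # name -> [members]
    marker_species: str | None = None
    crush_depleted_species: list = field(default_factory=list)
    batch_shifts: dict = field(default_factory=dict)
    protein_ids: list = field(default_factory=list)
    species_class: dict = field(default_factory=dict)      # species -> class code
    lipid_fraction_effect_species: list = field(default_factory=list)

    def validate(self) -> None:
        if set(self.early_classes) & set(self.late_classes):
            raise DataError("early and late class sets overlap in truth")
        if self.noise_cv <= 0:
            raise DataError("noise_cv must be positive")
        universe = set(self.protein_ids) | set(self.species_class)
        for name in ("trend_proteins_pos", "trend_proteins_neg",
                     "fraction_effect_features", "crush_depleted_species"):
            unknown = set(getattr(self, name)) - universe
            if unknown:
                raise DataError(f"{name} references unknown ids: {sorted(unknown)[:5]}")

    def to_json(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=list)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["pl_coupled_pairs"] = [tuple(x) for x in d.get("pl_coupled_pairs", [])]
        d["planted_edges"] = [tuple(x) for x in d.get("planted_edges", [])]
        return cls(**d)


@dataclass
class GcBundle:
    """Growth-cone proteome + lipidome with shared samples and truth."""

    protein_matrix: AbundanceMatrix
    lipid_matrix: AbundanceMatrix
    meta: pd.DataFrame
    truth: SyntheticTruth

    def __post_init__(self):
        if self.protein_matrix.sample_ids != self.lipid_matrix.sample_ids:
            raise DataError("protein and lipid matrices have different samples")
        if self.protein_matrix.sample_ids != list(self.meta.index):
            raise DataError("metadata samples do not match matrices")


@dataclass
class RegenBundle:
    """Optic-nerve regeneration lipidome with metadata and truth."""

    lipid_matrix: AbundanceMatrix
    meta: pd.DataFrame
    truth: SyntheticTruth

    def __post_init__(self):
        if self.lipid_matrix.sample_ids != list(self.meta.index):
            raise DataError("metadata samples do not match matrix")
        valid = {"control", "crush_saline", "wnt3a", "zymosan"}
        bad = set(self.meta["treatment"]) - valid
        if bad:
            raise DataError(f"unknown treatments: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Species-name generation
# ---------------------------------------------------------------------------

_CARBONS = (14, 16, 18, 20, 22, 24)
_SPH_BASES = ((16, 0), (16, 1), (18, 0), (18, 1), (18, 2), (20, 1))


def _class_species_pool(cls: str) -> list[str]:
    """Deterministic enumeration of plausible species names for a class."""
    n_chains = _CLASS_CHAINS[cls]
    names = []
    if cls in _SPHINGOID:
        if n_chains == 1:  # sphingoid backbones: di- and tri-hydroxy bases
            for p in ("d", "t"):
                for c, d in _SPH_BASES:
                    names.append(f"{cls}({p}{c}:{d})")
            return names
        for (bc, bd), c in itertools.product(_SPH_BASES, _CARBONS):
            for d in range(0, min(6, c // 3) + 1):
                names.append(f"{cls}(d{bc}:{bd}/{c}:{d})")
        return names
    # glycero / sterol species: combinations (sorted chains, no repeats of
    # the same name) spanning double-bond counts 0-6
    chain_pool = [
        (c, d) for c in _CARBONS for d in range(0, min(6, c // 3) + 1)
    ]
    for combo in itertools.combinations_with_replacement(chain_pool, n_chains):
        body = "/".join(f"{c}:{d}" for c, d in combo)
        names.append(f"{cls}({body})")
    return names


def _draw_species(rng: np.random.Generator, n_species: int,
                  force: tuple = ()) -> dict:
    """Draw ``n_species`` unique species names across the 20 generator
    classes (class membership uniform: sizes differ by at most one).
    Returns species -> class. ``force`` species are always included."""
    n_classes = len(GENERATOR_CLASSES)
    base, extra = divmod(n_species, n_classes)
    species = {}
    for i, cls in enumerate(GENERATOR_CLASSES):
        want = base + (1 if i < extra else 0)
        pool = _class_species_pool(cls)
        forced = [s for s in force if s.startswith(f"{cls}(")]
        picked = list(dict.fromkeys(forced))[:want]
        remaining = [s for s in pool if s not in picked]
        k = want - len(picked)
        if k > len(remaining):
            raise ConfigurationError(f"class {cls} pool too small for {want} species")
        if k > 0:
            picked += list(rng.choice(remaining, size=k, replace=False))
        for s in picked:
            species[s] = cls
    return species


# ---------------------------------------------------------------------------
# Growth-cone generator
# ---------------------------------------------------------------------------

def _gc_samples(config: GcConfig) -> pd.DataFrame:
    rows = []
    for fraction in ("GCM", "GCP"):
        for stage in STAGE_ORDER:
            n = config.reduced_cells.get((fraction, stage), config.n_replicates)
            for rep in range(1, n + 1):
                rows.append(
                    {
                        "sample_id": f"{fraction}_{stage}_r{rep}",
                        "fraction": fraction,
                        "stage": stage,
                        "replicate": rep,
                    }
                )
    meta = pd.DataFrame(rows).set_index("sample_id")
    meta["stage_ordinal"] = [STAGE_ORDER.index(s) for s in meta["stage"]]
    return meta


def generate_gc_multiomic(config: GcConfig | None = None, seed: int = 1) -> GcBundle:
    """Generate the growth-cone proteome + lipidome bundle.

    Deterministic given (config, seed). See the module docstring for the
    planted structure; all ids planted with effects are recorded in
    ``bundle.truth``.
    """
    config = config or GcConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    meta = _gc_samples(config)
    n_samples = len(meta)
    sigma = noise_sigma_log2(config.noise_cv)
    stage = meta["stage_ordinal"].to_numpy()           # 0..4
    frac_sign = np.where(meta["fraction"].to_numpy() == "GCM", 1.0, -1.0)

    # ---- proteins -------------------------------------------------------
    prot_ids = [f"PROT{i:04d}" for i in range(1, config.n_proteins + 1)]
    order = rng.permutation(config.n_proteins)
    pos = [prot_ids[i] for i in order[: config.n_trend_pos]]
    neg = [prot_ids[i] for i in order[config.n_trend_pos:
                                      config.n_trend_pos + config.n_trend_neg]]
    fr_start = config.n_trend_pos + config.n_trend_neg
    frac_feats = [prot_ids[i] for i in order[fr_start: fr_start + config.n_fraction_effect]]

    # P:L-coupled proteins: first members of each trend set, with the
    # stronger coupled slope. Decreasing proteins co-trend with the early
    # class TG, increasing ones with the late class CerG1.
    k = config.n_coupled_per_class
    coupled_neg = neg[:k]      # track TG (high early -> decreasing)
    coupled_pos = pos[:k]      # track CerG1 (late -> increasing)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          config.n_proteins)
    slopes = np.zeros(config.n_proteins)
    idx = {p: i for i, p in enumerate(prot_ids)}
    for p in pos:
        slopes[idx[p]] = config.trend_slope_sd * sigma
    for p in neg:
        slopes[idx[p]] = -config.trend_slope_sd * sigma
    for p in coupled_pos:
        slopes[idx[p]] = config.coupled_slope_sd * sigma
    for p in coupled_neg:
        slopes[idx[p]] = -config.coupled_slope_sd * sigma
    frac_shift = np.zeros(config.n_proteins)
    for j, p in enumerate(frac_feats):
        # half enriched in GCM, half in GCP
        frac_shift[idx[p]] = config.fraction_shift_log2 / 2 * (1 if j % 2 == 0 else -1)

    log2P = (
        baseline[:, None]
        + slopes[:, None] * (stage - 2.0)[None, :]
        + frac_shift[:, None] * frac_sign[None, :]
        + rng.normal(0.0, sigma, (config.n_proteins, n_samples))
    )
    protein_matrix = AbundanceMatrix(
        pd.DataFrame(2.0 ** log2P, index=prot_ids, columns=meta.index), "raw"
    )

    # ---- lipid species --------------------------------------------------
    species_class = _draw_species(rng, config.n_lipid_species)
    species = list(species_class)
    cls_arr = np.array([species_class[s] for s in species])
    early = set(config.early_classes)
    late = set(config.late_classes)
    step = config.class_switch_sd * sigma
    # step profile: +step/2 in E18-P0, -step/2 in P3-P9 for early classes
    early_profile = np.where(stage <= 1, step / 2, -step / 2)
    switch = np.zeros((len(species), n_samples))
    for i, c in enumerate(cls_arr):
        if c in early:
            switch[i] = early_profile
        elif c in late:
            switch[i] = -early_profile
    # lipid fraction effects on species of non-switching classes
    neutral_species = [s for s, c in species_class.items()
                       if c not in early and c not in late]
    n_lf = min(config.n_lipid_fraction_effect, len(neutral_species))
    lf_species = [neutral_species[i]
                  for i in rng.permutation(len(neutral_species))[:n_lf]]
    sidx = {s: i for i, s in enumerate(species)}
    lfrac = np.zeros(len(species))
    for j, s in enumerate(lf_species):
        lfrac[sidx[s]] = config.lipid_fraction_shift_log2 / 2 * (1 if j % 2 == 0 else -1)

    lbaseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                           len(species))
    log2L = (
        lbaseline[:, None]
        + switch
        + lfrac[:, None] * frac_sign[None, :]
        + rng.normal(0.0, sigma, (len(species), n_samples))
    )
    lipid_matrix = AbundanceMatrix(
        pd.DataFrame(2.0 ** log2L, index=species, columns=meta.index), "raw"
    )

    # ---- truth ----------------------------------------------------------
    pl_pairs = [(p, "TG") for p in coupled_neg] + [(p, "CerG1") for p in coupled_pos]
    edges = [tuple(sorted(e)) for grp in (coupled_neg, coupled_pos)
             for e in itertools.combinations(grp, 2)]
    complexes = {
        "PLANTED_CPX_8": list(coupled_neg),
        "PLANTED_CPX_2": list(coupled_pos[:2]),
    }
    truth = SyntheticTruth(
        noise_cv=config.noise_cv,
        trend_proteins_pos=pos,
        trend_proteins_neg=neg,
        fraction_effect_features=frac_feats,
        early_classes=list(config.early_classes),
        late_classes=list(config.late_classes),
        pl_coupled_pairs=pl_pairs,
        planted_edges=edges,
        planted_complexes=complexes,
        batch_shifts={},
        protein_ids=prot_ids,
        species_class=species_class,
        lipid_fraction_effect_species=lf_species,
    )
    truth.validate()
    return GcBundle(protein_matrix, lipid_matrix, meta, truth)


# ---------------------------------------------------------------------------
# Regeneration generator
# ---------------------------------------------------------------------------

def _regen_samples(config: RegenConfig) -> pd.DataFrame:
    def spread_days(n):
        """Deterministic near-even allocation over days 7 and 15 (and 3 for
        the saline arm, which is sampled at all three timepoints)."""
        return [7] * (n // 2) + [15] * (n - n // 2)

    rows = []
    for i in range(1, config.n_control + 1):
        rows.append(("CTRL_r%02d" % i, "control", pd.NA, "reference"))
    saline_days = ([3] * (config.n_crush_saline - 2 * (config.n_crush_saline // 3))
                   + [7] * (config.n_crush_saline // 3)
                   + [15] * (config.n_crush_saline // 3))
    for i, d in enumerate(saline_days, 1):
        rows.append(("CRUSH_r%02d" % i, "crush_saline", d, "reference"))
    for i, d in enumerate(spread_days(config.n_wnt3a), 1):
        rows.append(("WNT3A_r%02d" % i, "wnt3a", d, "wnt3a_batch"))
    for i, d in enumerate(spread_days(config.n_zymosan), 1):
        rows.append(("ZYM_r%02d" % i, "zymosan", d, "zymosan_batch"))
    meta = pd.DataFrame(rows, columns=["sample_id", "treatment", "day", "batch"])
    return meta.set_index("sample_id")


def generate_regen_lipidome(config: RegenConfig | None = None,
                            seed: int = 42) -> RegenBundle:
    """Generate the optic-nerve regeneration lipidome bundle."""
    config = config or RegenConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    meta = _regen_samples(config)
    sigma = noise_sigma_log2(config.noise_cv)
    n_samples = len(meta)

    species_class = _draw_species(rng, config.n_species,
                                  force=(config.marker_species,))
    if config.marker_species not in species_class:
        raise ConfigurationError(
            f"marker species {config.marker_species!r} not representable")
    species = list(species_class)
    sidx = {s: i for i, s in enumerate(species)}

    treatment = meta["treatment"].to_numpy()
    day = meta["day"].to_numpy(dtype=object)
    regen_mask = np.isin(treatment, ("wnt3a", "zymosan"))
    crushed_mask = np.isin(treatment, ("crush_saline", "wnt3a", "zymosan"))

    effects = np.zeros((len(species), n_samples))

    # marker separation (regenerating vs everything else)
    effects[sidx[config.marker_species], regen_mask] += config.marker_sep_sd * sigma

    # class-level day effects in regenerating samples
    for cls, (d7, d15) in config.class_effects.items():
        members = [sidx[s] for s, c in species_class.items() if c == cls]
        for j in range(n_samples):
            if not regen_mask[j]:
                continue
            shift = d7 if day[j] == 7 else (d15 if day[j] == 15 else 0.0)
            effects[members, j] += shift * sigma

    # crush-depleted species: 8 PC + 1 PE, down in every crushed eye
    pc = sorted(s for s, c in species_class.items() if c == "PC")
    pe = sorted(s for s, c in species_class.items() if c == "PE")
    n_pc = min(8, config.n_crush_depleted, len(pc))
    depleted = pc[:n_pc] + pe[: max(0, config.n_crush_depleted - n_pc)]
    for s in depleted:
        effects[sidx[s], crushed_mask] -= config.crush_depletion_log2

    # batch offsets
    batch_offset = meta["batch"].map(config.batch_shifts).fillna(0.0).to_numpy()

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          len(species))
    log2X = (
        baseline[:, None]
        + effects
        + batch_offset[None, :]
        + rng.normal(0.0, sigma, (len(species), n_samples))
    )
    lipid_matrix = AbundanceMatrix(
        pd.DataFrame(2.0 ** log2X, index=species, columns=meta.index), "raw"
    )
    truth = SyntheticTruth(
        noise_cv=config.noise_cv,
        early_classes=[],
        late_classes=[],
        marker_species=config.marker_species,
        crush_depleted_species=depleted,
        batch_shifts=dict(config.batch_shifts),
        species_class=species_class,
    )
    truth.validate()
    return RegenBundle(lipid_matrix, meta, truth)


# ---------------------------------------------------------------------------
# Knowledge tables
# ---------------------------------------------------------------------------

def lipid_term_sets(species_class: dict) -> list[TermSet]:
    """Expand the static class->term map to species-level term sets.

    This is the ontology-annotation step for whichever lipidome was
    measured: every species inherits the biophysical/chemical terms of its
    class, so term ids are shared across datasets while memberships follow
    each dataset's species.
    """
    term_members: dict[str, set] = {}
    for s, cls in species_class.items():
        for term in CLASS_TERMS.get(cls, ()):
            term_members.setdefault(term, set()).add(s)
    return [
        TermSet(term, "lipid biophysical/chemical property", frozenset(m))
        for term, m in sorted(term_members.items())
    ]


def generate_knowledge_tables(truth: SyntheticTruth, seed: int = 1,
                              decoy_factor: int = 5):
    """Build STRING/CORUM/ontology-style stand-in tables from planted truth.

    Returns ``(edges, complexes, terms)``: an interaction edge list
    (DataFrame protein_a / protein_b / score) containing every planted
    co-trending pair plus ``decoy_factor`` x as many decoy edges among
    effect-free proteins; the two planted complexes as :class:`TermSet`
    objects; and lipid-ontology term sets expanded from the static
    class->term map to species membership.
    """
    if not truth.pl_coupled_pairs or not truth.planted_edges:
        raise DataError("truth carries no planted coupled pairs")
    rng = np.random.default_rng(seed)
    planted = [tuple(sorted(e)) for e in truth.planted_edges]
    planted_set = set(planted)
    trendy = set(truth.trend_proteins_pos) | set(truth.trend_proteins_neg)
    with_fraction = set(truth.fraction_effect_features)
    decoy_pool = [p for p in truth.protein_ids
                  if p not in trendy and p not in with_fraction]
    n_decoys = decoy_factor * len(planted)
    decoys = set()
    while len(decoys) < n_decoys:
        a, b = rng.choice(len(decoy_pool), size=2, replace=False)
        e = tuple(sorted((decoy_pool[a], decoy_pool[b])))
        if e not in planted_set:
            decoys.add(e)
    all_edges = planted + sorted(decoys)
    edges = pd.DataFrame(all_edges, columns=["protein_a", "protein_b"])
    edges["score"] = rng.uniform(0.4, 0.999, len(edges)).round(3)

    complexes = [
        TermSet(name, "planted protein complex", frozenset(members))
        for name, members in truth.planted_complexes.items()
    ]

    terms = lipid_term_sets(truth.species_class)
    return edges, complexes, terms
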