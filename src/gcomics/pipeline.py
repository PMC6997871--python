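"""Configuration-driven orchestration of the two analysis pipelines.

``run_gc_pipeline`` executes the growth-cone development analysis
(preprocess -> multivariate -> differential -> enrichment -> network) and
``run_regen_pipeline`` the optic-nerve regeneration analysis (preprocess ->
batch correction -> differential/class tests -> ROC -> enrichment ->
signature intersection). Both read their inputs either from TSV paths or
from a simulate block, write result tables with a provenance header, and
serialize a run report (config echo, seeds, per-stage row counts,
warnings) that makes reruns bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, enrichment, multivariate, network, preprocess, regeneration
from .containers import (AbundanceMatrix, read_gmt, read_meta, stage_ordinal,
                         write_gmt, write_meta)
from .exceptions import ConfigurationError
from .simulate import (GcConfig, RegenConfig, generate_gc_multiomic,
                       generate_knowledge_tables, generate_regen_lipidome,
                       lipid_term_sets)

__all__ = ["RunConfig", "run_gc_pipeline", "run_regen_pipeline", "simulate_to_dir"]


@dataclass
class RunConfig:
    """Pipeline settings: one of (input paths | simulate) plus thresholds."""

    outdir: str = "gcomics_out"
    simulate: bool = True
    seed: int = 1
    # input paths (used when simulate is False)
    protein_tsv: str | None = None
    lipid_tsv: str | None = None
    meta_tsv: str | None = None
    edges_tsv: str | None = None
    complexes_gmt: str | None = None
    terms_gmt: str | None = None
    # thresholds (defaults are the analysis' quoted gates)
    fc_thr: float = 2.0
    q_thr: float = 0.05
    r_thr: float = 0.7
    p_thr: float = 0.01
    # method switches
    normalization: str = "total_intensity"
    pls_components: int = 2
    cv_folds: int = 7

    def validate(self) -> None:
        if not self.simulate:
            needed = [self.lipid_tsv, self.meta_tsv]
            if any(p is None for p in needed):
                raise ConfigurationError(
                    "non-simulate runs need lipid_tsv and meta_tsv paths")
        for name in ("fc_thr",):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("q_thr", "p_thr"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not 0 <= self.r_thr <= 1:
            raise ConfigurationError("r_thr must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Hash of the analysis-relevant settings (destination excluded, so
        the same analysis rerun into another directory is byte-identical)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return f"gcomics run config={config.digest()} seed={config.seed}"


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig,
                 index: bool = True) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# {_provenance(config)}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def simulate_to_dir(outdir, seed: int = 1) -> dict:
    """Generate both synthetic bundles plus knowledge tables into a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gc = generate_gc_multiomic(GcConfig(), seed=seed)
    regen = generate_regen_lipidome(RegenConfig(), seed=seed)
    edges, complexes, terms = generate_knowledge_tables(gc.truth, seed=seed)
    gc.protein_matrix.to_tsv(out / "gc_proteins.tsv")
    gc.lipid_matrix.to_tsv(out / "gc_lipids.tsv")
    write_meta(gc.meta, out / "gc_meta.tsv")
    regen.lipid_matrix.to_tsv(out / "regen_lipids.tsv")
    write_meta(regen.meta, out / "regen_meta.tsv")
    edges.to_csv(out / "edges.tsv", sep="\t", index=False, lineterminator="\n")
    write_gmt(complexes, out / "complexes.gmt")
    write_gmt(terms, out / "terms.gmt")
    gc.truth.to_json(out / "gc_truth.json")
    regen.truth.to_json(out / "regen_truth.json")
    return {"outdir": str(out), "n_gc_samples": gc.protein_matrix.n_samples,
            "n_regen_samples": regen.lipid_matrix.n_samples}


def _load_gc_inputs(config: RunConfig):
    if config.simulate:
        gc = generate_gc_multiomic(GcConfig(), seed=config.seed)
        edges, complexes, terms = generate_knowledge_tables(gc.truth, seed=config.seed)
        return gc.protein_matrix, gc.lipid_matrix, gc.meta, edges, complexes, terms
    proteins = AbundanceMatrix.from_tsv(config.protein_tsv, "raw")
    lipids = AbundanceMatrix.from_tsv(config.lipid_tsv, "raw")
    meta = read_meta(config.meta_tsv)
    edges = (pd.read_csv(config.edges_tsv, sep="\t", comment="#")
             if config.edges_tsv else None)
    complexes = read_gmt(config.complexes_gmt) if config.complexes_gmt else []
    terms = read_gmt(config.terms_gmt) if config.terms_gmt else []
    return proteins, lipids, meta, edges, complexes, terms


def run_gc_pipeline(config: RunConfig) -> dict:
    """Run the growth-cone development analysis end to end.

    Returns the run report (also written to ``<outdir>/report.json``).
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"pipeline": "gc", "config": dataclasses.asdict(config),
                    "config_digest": config.digest(), "seed": config.seed,
                    "stages": {}, "warnings": []}

    proteins, lipids, meta, edges, complexes, terms = _load_gc_inputs(config)
    report["stages"]["input"] = {
        "n_proteins": proteins.n_features,
        "n_lipid_species": lipids.n_features,
        "n_samples": proteins.n_samples,
    }

    # --- preprocess ------------------------------------------------------
    prot_norm = preprocess.normalize(proteins, config.normalization)
    lip_norm = preprocess.normalize(lipids, config.normalization)
    prot_log = prot_norm.to_log2()
    lip_log = lip_norm.to_log2()
    groups = meta["fraction"].astype(str) + "/" + meta["stage"].astype(str)
    cv_prot = preprocess.compute_cv(prot_norm, groups)
    cv_lip = preprocess.compute_cv(lip_norm, groups)
    report["stages"]["preprocess"] = {
        "median_cv_protein": cv_prot.median_within,
        "median_cv_lipid": cv_lip.median_within,
    }
    classes = preprocess.aggregate_lipid_classes(lip_norm)
    classes.to_tsv(out / "lipid_classes.tsv", _provenance(config))

    # --- multivariate ----------------------------------------------------
    prot_scaled = preprocess.normalize(prot_log, "autoscale")
    asca_res = multivariate.asca(prot_scaled, meta)
    pca_res = multivariate.pca(prot_scaled, n_components=3)
    pls = multivariate.pls_stage_model(
        prot_log, stage_ordinal(meta), config.pls_components, config.cv_folds)
    ward = multivariate.hierarchical_cluster(prot_scaled, k=2,
                                             labels=meta["fraction"])
    gcm_ids = meta.index[meta["fraction"] == "GCM"].tolist()
    lip_gcm = lip_log.subset_samples(gcm_ids)
    lip_gcm_scaled = preprocess.normalize(lip_gcm, "autoscale")
    km = multivariate.kmeans_split(lip_gcm_scaled,
                                   stage_ordinal(meta.loc[gcm_ids]),
                                   seed=config.seed)
    corr = multivariate.sample_correlation_matrix(prot_log)
    _write_table(corr, out / "sample_correlations.tsv", config)
    _write_table(pls.vip.to_frame(), out / "pls_vip.tsv", config)
    report["stages"]["multivariate"] = {
        "asca_ss_share": {k: float(v) for k, v in asca_res.ss_share.items()},
        "asca_fraction_pc1": float(asca_res.effect_pca_ratio["fraction"][0]),
        "pca_ratio": [float(r) for r in pca_res.explained_variance_ratio],
        "pls_r2": pls.r2, "pls_q2": pls.q2, "pls_accuracy": pls.accuracy,
        "ward_fraction_purity": ward.purity,
        "kmeans_early": sorted(km.assignments.index[km.assignments == "early"]),
    }

    # --- differential ----------------------------------------------------
    volcano = differential.two_group_diff(
        prot_log, meta["fraction"], "GCM", "GCP", config.fc_thr, config.q_thr)
    _write_table(volcano, out / "volcano_gcm_vs_gcp.tsv", config)
    trends = {}
    for frac in ("GCM", "GCP"):
        ids = meta.index[meta["fraction"] == frac].tolist()
        tr = differential.stage_trend(
            prot_log.subset_samples(ids), stage_ordinal(meta.loc[ids]),
            config.r_thr, config.p_thr)
        trends[frac] = tr
        _write_table(tr, out / f"stage_trend_{frac}.tsv", config)
    lip_trend_gcm = differential.stage_trend(
        lip_gcm, stage_ordinal(meta.loc[gcm_ids]), config.r_thr, config.p_thr)
    _write_table(lip_trend_gcm, out / "lipid_stage_trend_GCM.tsv", config)
    report["stages"]["differential"] = {
        "n_volcano_significant": int(volcano["significant"].sum()),
        "n_trend_gcm": int((trends["GCM"]["direction"] != "none").sum()),
        "n_trend_gcp": int((trends["GCP"]["direction"] != "none").sum()),
    }

    # --- enrichment ------------------------------------------------------
    if terms:
        early_species = lip_trend_gcm.index[
            lip_trend_gcm["direction"] == "decreasing"].tolist()
        if early_species:
            enr = enrichment.fisher_enrich(early_species, lip_gcm.feature_ids,
                                           terms, config.q_thr)
            _write_table(enr, out / "early_lipid_enrichment.tsv", config,
                         index=False)
            report["stages"]["enrichment"] = {
                "n_terms_tested": len(enr),
                "n_enriched": int(enr["enriched"].sum()) if len(enr) else 0,
            }

    # --- network ---------------------------------------------------------
    if edges is not None:
        prot_gcm = prot_log.subset_samples(gcm_ids)
        filt = network.filter_pp_edges(edges, prot_gcm, p_thr=config.p_thr)
        _write_table(filt, out / "pp_edges_filtered.tsv", config, index=False)
        plc = network.pl_correlation(prot_gcm, lip_gcm)
        species_class = {s: preprocess.parse_lipid_name(s).class_code
                         for s in lip_gcm.feature_ids}
        retained_prots = sorted(
            set(filt.loc[filt["retained"], "protein_a"])
            | set(filt.loc[filt["retained"], "protein_b"]))
        if retained_prots:
            combined = network.combine_by_class(plc, species_class, retained_prots)
            _write_table(combined, out / "pp_combined_class_r.tsv", config)
        if complexes:
            cpx = network.annotate_complexes(complexes, trends["GCM"])
            _write_table(cpx, out / "complex_summary.tsv", config, index=False)
        report["stages"]["network"] = {
            "n_edges_in": len(filt),
            "n_edges_retained": int(filt["retained"].sum()),
        }

    report["n_samples"] = proteins.n_samples
    with open(out / "report.json", "w", newline="\n") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def run_regen_pipeline(config: RunConfig, dev_enrichment: pd.DataFrame | None = None,
                       crush_only: bool = False) -> dict:
    """Run the optic-nerve regeneration analysis end to end."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"pipeline": "regen", "config": dataclasses.asdict(config),
                    "config_digest": config.digest(), "seed": config.seed,
                    "stages": {}, "warnings": []}

    if config.simulate:
        bundle = generate_regen_lipidome(RegenConfig(), seed=config.seed)
        lipids, meta = bundle.lipid_matrix, bundle.meta
        terms = lipid_term_sets(bundle.truth.species_class)
    else:
        lipids = AbundanceMatrix.from_tsv(config.lipid_tsv, "raw")
        meta = read_meta(config.meta_tsv)
        terms = read_gmt(config.terms_gmt) if config.terms_gmt else []
    if "batch" not in meta.columns:
        raise ConfigurationError("regeneration metadata needs a 'batch' column")

    lip_log = preprocess.normalize(lipids, config.normalization).to_log2()
    report["stages"]["input"] = {"n_species": lipids.n_features,
                                 "n_samples": lipids.n_samples}

    # crush-vs-control differential (no batch structure involved)
    crush_ids = meta.index[meta["treatment"].isin(["crush_saline", "control"])]
    crush_diff = differential.two_group_diff(
        lip_log.subset_samples(list(crush_ids)),
        meta.loc[crush_ids, "treatment"], "crush_saline", "control",
        config.fc_thr, config.q_thr)
    _write_table(crush_diff, out / "crush_vs_control.tsv", config)
    report["stages"]["crush_diff"] = {
        "n_significant": int(crush_diff["significant"].sum())}
    if crush_only:
        with open(out / "report.json", "w", newline="\n") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return report

    # batch correction across the regeneration experiments
    regen_ids = meta.index[meta["treatment"].isin(["wnt3a", "zymosan"])].tolist()
    batches = meta.loc[regen_ids, "batch"]
    corrected = lip_log.values.copy()
    if len(set(batches)) >= 1 and len(regen_ids) >= 4:
        sub = lip_log.subset_samples(regen_ids)
        adj, adjustment = regeneration.combat_adjust(sub, batches)
        corrected[regen_ids] = adj.values
        report["stages"]["combat"] = {
            "batches": adjustment.batches,
            "iterations": adjustment.n_iterations,
            "converged": adjustment.converged,
        }
    lip_adj = AbundanceMatrix(corrected, "log2")
    lip_adj.to_tsv(out / "lipids_batch_corrected.tsv", _provenance(config))

    # class-level timepoint tests (treatment arms vs control), on the
    # batch-corrected intensities so experiment offsets do not masquerade
    # as treatment effects
    adj_raw = AbundanceMatrix(2.0 ** lip_adj.values, "raw")
    classes = preprocess.aggregate_lipid_classes(adj_raw)
    class_log = classes.to_log2()
    contrasts = sorted(
        {(t, d) for t, d in zip(meta["treatment"], meta["day"])
         if t in ("wnt3a", "zymosan") and pd.notna(d)})
    class_tests = differential.class_timepoint_tests(class_log, meta, contrasts)
    _write_table(class_tests, out / "class_timepoint_tests.tsv", config,
                 index=False)

    # ROC ranking: regeneration (wnt3a + zymosan pooled) vs control
    roc_ids = regen_ids + meta.index[meta["treatment"] == "control"].tolist()
    roc_labels = pd.Series(
        np.where(meta.loc[roc_ids, "treatment"].isin(["wnt3a", "zymosan"]),
                 "regeneration", "control"), index=roc_ids)
    roc = regeneration.roc_rank(lip_adj.subset_samples(roc_ids), roc_labels)
    _write_table(roc, out / "roc_ranking.tsv", config)
    report["stages"]["roc"] = {
        "top_species": roc.index[0],
        "top_auc": float(roc["auc"].iloc[0]),
        "top_accuracy": float(roc["accuracy"].iloc[0]),
    }

    # enrichment of regeneration-elevated species + signature intersection
    if terms:
        regen_diff = differential.two_group_diff(
            lip_adj.subset_samples(roc_ids), roc_labels,
            "regeneration", "control", fc_thr=1.0, q_thr=config.q_thr)
        up = regen_diff.index[(regen_diff["q"] < config.q_thr)
                              & (regen_diff["log2FC"] > 0)].tolist()
        if up:
            regen_enr = enrichment.fisher_enrich(up, lip_adj.feature_ids, terms,
                                                 config.q_thr)
            _write_table(regen_enr, out / "regen_enrichment.tsv", config,
                         index=False)
            report["stages"]["enrichment"] = {
                "n_enriched": int(regen_enr["enriched"].sum())}
            if dev_enrichment is not None:
                shared = regeneration.common_signatures(
                    dev_enrichment, regen_enr, config.q_thr)
                _write_table(shared, out / "common_signatures.tsv", config,
                             index=False)
                report["stages"]["common_signatures"] = {
                    "terms": shared["term_id"].tolist()}

    with open(out / "report.json", "w", newline="\n") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
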