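"""Batch correction, ROC ranking and signature intersection."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gcomics import preprocess
from gcomics.containers import AbundanceMatrix
from gcomics.enrichment import fisher_enrich
from gcomics.exceptions import DataError
from gcomics.regeneration import (combat_adjust, common_signatures, roc_rank,
                                  roc_single)
from gcomics.simulate import lipid_term_sets

from conftest import small_matrix


def _two_batch_matrix(shift=1.0, noise=0.1, n_feat=60, n_per=12, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.normal(20, 2, (n_feat, 1))
    X = base + rng.normal(0, noise, (n_feat, 2 * n_per))
    X[:, n_per:] += shift
    samples = [f"s{j}" for j in range(2 * n_per)]
    batch = pd.Series(["A"] * n_per + ["B"] * n_per, index=samples)
    return small_matrix(X, space="log2", samples=samples), batch, X


class TestCombat:
    def test_single_batch_identity(self):
        m, batch, X = _two_batch_matrix()
        one = pd.Series("A", index=m.sample_ids)
        adj, a = combat_adjust(m, one)
        assert np.abs(adj.values.to_numpy() - X).max() < 1e-8
        assert (a.gamma_star.to_numpy() == 0).all()
        assert (a.delta_star.to_numpy() == 1).all()

    def test_planted_shift_removed(self):
        """Additive 1.0 log2 batch shift: median per-feature batch-mean gap
        reduced by >= 90% at the pipeline's noise scale."""
        m, batch, X = _two_batch_matrix(shift=1.0, noise=0.12)
        adj, _ = combat_adjust(m, batch)
        A = adj.values.to_numpy()
        before = np.abs(X[:, :12].mean(1) - X[:, 12:].mean(1))
        after = np.abs(A[:, :12].mean(1) - A[:, 12:].mean(1))
        assert np.median(after) <= 0.1 * np.median(before)

    def test_identical_batches_barely_changed(self):
        m, batch, X = _two_batch_matrix(shift=0.0, noise=0.12, seed=3)
        adj, _ = combat_adjust(m, batch)
        change = np.abs(adj.values.to_numpy() - X)
        assert np.median(change) < 0.12

    def test_grand_mean_preserved(self):
        m, batch, X = _two_batch_matrix(shift=0.7, noise=0.3, seed=4)
        adj, _ = combat_adjust(m, batch)
        A = adj.values.to_numpy()
        rel = np.abs(A.mean(1) - X.mean(1)) / np.abs(X.mean(1))
        assert rel.max() < 1e-6

    def test_small_batch_rejected(self):
        m, _, _ = _two_batch_matrix()
        bad = pd.Series(["A"] * 23 + ["B"], index=m.sample_ids)
        with pytest.raises(DataError, match="< 2 samples"):
            combat_adjust(m, bad)

    def test_agrees_with_reference_implementation(self, tmp_path):
        """Numerical agreement with sva::ComBat (R) on a two-batch matrix,
        after applying the same grand-mean restoration to its output."""
        m, batch, X = _two_batch_matrix(shift=0.8, noise=0.5, n_feat=40,
                                        n_per=8, seed=7)
        adj, _ = combat_adjust(m, batch)
        xp = tmp_path / "X.tsv"
        bp = tmp_path / "batch.tsv"
        op = tmp_path / "out.tsv"
        m.values.to_csv(xp, sep="\t")
        batch.to_csv(bp, sep="\t", header=["batch"])
        script = textwrap.dedent(f"""
            suppressMessages(library(sva))
            X <- as.matrix(read.delim("{xp}", row.names=1, check.names=FALSE))
            batch <- read.delim("{bp}", row.names=1)$batch
            out <- ComBat(dat=X, batch=batch)
            out <- out + (rowMeans(X) - rowMeans(out))
            write.table(out, "{op}", sep="\\t", quote=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True, timeout=300)
        ref = pd.read_csv(op, sep="\t", index_col=0).to_numpy()
        # same EB formulation; residual differences come from the 1e-4
        # convergence stop on ~20-magnitude values
        assert np.abs(ref - adj.values.to_numpy()).max() < 1e-3


def brute_force_auc(pos, neg):
    """Pair-counting oracle: wins + half-credit ties over all n1*n2 pairs."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def _series(self, pos, neg):
        vals = pd.Series(list(pos) + list(neg),
                         index=[f"s{i}" for i in range(len(pos) + len(neg))])
        labels = pd.Series(["r"] * len(pos) + ["c"] * len(neg),
                           index=vals.index)
        return vals, labels

    def test_complete_separation(self):
        vals, labels = self._series([10, 11, 12], [1, 2, 3])
        res = roc_single(vals, labels, "r")
        assert res["auc"] == 1.0
        assert res["accuracy"] == 1.0

    def test_identical_distributions(self):
        vals, labels = self._series([1, 2, 3], [1, 2, 3])
        res = roc_single(vals, labels, "r")
        assert res["auc_raw"] == pytest.approx(0.5)

    def test_hand_computed_example(self):
        # control [1,2,3] vs regeneration [2.5,4]: AUC = 5/6
        vals, labels = self._series([2.5, 4], [1, 2, 3])
        res = roc_single(vals, labels, "r")
        assert res["auc_raw"] == pytest.approx(5 / 6)

    @given(
        pos=st.lists(st.integers(0, 8), min_size=1, max_size=6),
        neg=st.lists(st.integers(0, 8), min_size=1, max_size=6),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_pair_counting_oracle(self, pos, neg):
        vals, labels = self._series(pos, neg)
        res = roc_single(vals, labels, "r")
        oracle = brute_force_auc(pos, neg)
        assert res["auc_raw"] == pytest.approx(oracle, abs=1e-12)
        # duality: flipping the sign of the score flips the AUC
        flipped = roc_single(-vals, labels, "r")
        assert res["auc_raw"] + flipped["auc_raw"] == pytest.approx(1.0)

    @given(pos=st.lists(st.integers(0, 1000), min_size=2, max_size=6, unique=True),
           neg=st.lists(st.integers(0, 1000), min_size=2, max_size=6, unique=True))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_invariant_under_monotone_transform(self, pos, neg):
        pos = [v / 100.0 for v in pos]
        neg = [v / 100.0 for v in neg]
        vals, labels = self._series(pos, neg)
        res = roc_single(vals, labels, "r")
        res2 = roc_single(np.exp(vals / 5.0), labels, "r")
        assert res["auc"] == pytest.approx(res2["auc"], abs=1e-12)

    def test_rank_matrix_sorted_and_sized(self, regen_bundle):
        meta = regen_bundle.meta
        log = preprocess.normalize(
            regen_bundle.lipid_matrix, "total_intensity").to_log2()
        ids = meta.index[meta.treatment.isin(
            ["wnt3a", "zymosan", "control"])].tolist()
        labels = pd.Series(
            np.where(meta.loc[ids].treatment == "control",
                     "control", "regeneration"), index=ids)
        out = roc_rank(log.subset_samples(ids), labels)
        assert (out.auc.diff().dropna() <= 1e-12).all()
        assert out.n_pos.iloc[0] == 16 and out.n_neg.iloc[0] == 21
        assert out.index[0] == regen_bundle.truth.marker_species

    def test_empty_group_rejected(self):
        vals, labels = self._series([1, 2], [])
        with pytest.raises(DataError):
            roc_single(vals, labels, "r")


class TestCommonSignatures:
    def _enr(self, gc_bundle):
        truth = gc_bundle.truth
        terms = lipid_term_sets(truth.species_class)
        early = [s for s, c in truth.species_class.items()
                 if c in truth.early_classes]
        return fisher_enrich(early, list(truth.species_class), terms)

    def test_identical_inputs_full_intersection(self, gc_bundle):
        enr = self._enr(gc_bundle)
        out = common_signatures(enr, enr)
        assert set(out.term_id) == set(enr.loc[enr.q < 0.05, "term_id"])

    def test_disjoint_significant_sets_empty(self, gc_bundle):
        enr = self._enr(gc_bundle)
        other = enr.copy()
        other["q"] = 1.0
        out = common_signatures(enr, other)
        assert len(out) == 0

    def test_disjoint_universes_rejected(self, gc_bundle):
        enr = self._enr(gc_bundle)
        other = enr.copy()
        other["term_id"] = other["term_id"] + "_x"
        with pytest.raises(DataError, match="disjoint"):
            common_signatures(enr, other)

    def test_planted_shared_terms_recovered(self, gc_bundle, regen_bundle):
        """Storage/droplet/glycerolipid terms are enriched in both early
        development and regeneration, and appear in the intersection."""
        dev_enr = self._enr(gc_bundle)
        rtruth = regen_bundle.truth
        rterms = lipid_term_sets(rtruth.species_class)
        up = [s for s, c in rtruth.species_class.items()
              if c in ("TG", "MG", "PG")]
        regen_enr = fisher_enrich(up, list(rtruth.species_class), rterms)
        out = common_signatures(dev_enr, regen_enr)
        assert {"lipid storage", "lipid droplet", "glycerolipid"} <= set(out.term_id)
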