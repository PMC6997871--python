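"""PCA, ASCA decomposition, PLS-VIP stage model and clustering behaviour."""

import numpy as np
import pandas as pd
import pytest

from gcomics import preprocess
from gcomics.containers import AbundanceMatrix
from gcomics.exceptions import ConfigurationError, DataError
from gcomics.multivariate import (asca, hierarchical_cluster, kmeans_split,
                                  pca, pls_stage_model,
                                  sample_correlation_matrix)
from gcomics.simulate import GcConfig, generate_gc_multiomic

from conftest import small_matrix


class TestPca:
    def test_rank_one_matrix_single_component(self):
        u = np.array([1.0, 2.0, 3.0])
        v = np.array([1.0, -1.0, 0.5, 2.0])
        m = small_matrix(np.outer(v, u) + 5, space="log2")
        res = pca(m, n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (10, 6))  # features x samples
        m = small_matrix(X, space="log2")
        res = pca(m, n_components=6)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        Xc = X.T - X.T.mean(axis=0)
        assert np.linalg.norm(recon - Xc) < 1e-8
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()

    def test_constant_feature_rejected(self):
        m = small_matrix([[1, 1, 1], [1, 2, 3]], space="log2")
        with pytest.raises(DataError, match="zero variance"):
            pca(m, 2)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (8, 5))
        r1 = pca(small_matrix(X, space="log2"), 3)
        r2 = pca(small_matrix(-X + 10, space="log2"), 3)
        for a in range(3):
            j = np.argmax(np.abs(r1.loadings.iloc[:, a]))
            assert r1.loadings.iloc[j, a] > 0
            j = np.argmax(np.abs(r2.loadings.iloc[:, a]))
            assert r2.loadings.iloc[j, a] > 0


def _balanced_design(n_feat=30, reps=4, seed=0):
    """Balanced 2-fraction x 5-stage design with planted effects."""
    cfg = GcConfig(n_proteins=n_feat, n_lipid_species=40, n_replicates=reps,
                   reduced_cells={}, n_trend_pos=5, n_trend_neg=5,
                   n_fraction_effect=10, n_coupled_per_class=2)
    return generate_gc_multiomic(cfg, seed=seed)


class TestAsca:
    def test_two_level_factor_effect_is_rank_one(self, gc_bundle, gc_protein_log):
        scaled = preprocess.normalize(gc_protein_log, "autoscale")
        res = asca(scaled, gc_bundle.meta)
        # two-level factor with equal group sizes: effect matrix rank 1
        assert res.effect_pca_ratio["fraction"][0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_effects_when_group_means_equal(self):
        X = np.tile([[1.0, 1.0, 1.0, 1.0]], (5, 1))
        m = small_matrix(X + np.arange(5)[:, None] * 0, space="log2")
        meta = pd.DataFrame(
            {"fraction": ["GCM", "GCM", "GCP", "GCP"],
             "stage": ["E18", "P0", "E18", "P0"]},
            index=[f"s{j}" for j in range(4)])
        res = asca(m, meta)
        for E in res.effects.values():
            assert np.linalg.norm(E.to_numpy()) < 1e-9

    def test_decomposition_identity_and_orthogonality_balanced(self):
        b = _balanced_design()
        log = b.protein_matrix.to_log2()
        res = asca(log, b.meta)
        total = res.centered.to_numpy()
        recon = sum(E.to_numpy() for E in res.effects.values()) + res.residual.to_numpy()
        assert np.linalg.norm(total - recon) / np.linalg.norm(total) < 1e-9
        mats = list(res.effects.values()) + [res.residual]
        for i in range(len(mats)):
            for j in range(i + 1, len(mats)):
                A, B = mats[i].to_numpy(), mats[j].to_numpy()
                denom = np.linalg.norm(A) * np.linalg.norm(B)
                if denom > 0:
                    assert abs((A * B).sum()) < 1e-9 * denom
        # sum of squares decomposes exactly
        assert sum(res.ss_share.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_level_factor_rejected(self):
        m = small_matrix(np.random.default_rng(0).normal(0, 1, (5, 4)),
                         space="log2")
        meta = pd.DataFrame({"fraction": ["GCM"] * 4, "stage": list("abcd")},
                            index=[f"s{j}" for j in range(4)])
        with pytest.raises(DataError, match="single level"):
            asca(m, meta, factors=("fraction",), with_interaction=False)


class TestPls:
    def test_vip_all_one_when_weights_equal(self):
        # features are identical noisy copies of the response: equal weights
        rng = np.random.default_rng(1)
        y = np.tile(np.arange(5.0), 4)
        X = np.tile(y, (6, 1)) + rng.normal(0, 1e-6, (6, 20))
        m = small_matrix(X, space="log2")
        res = pls_stage_model(m, pd.Series(y, index=m.sample_ids), 1, cv_folds=4)
        assert np.allclose(res.vip, 1.0, atol=1e-3)
        assert (res.vip**2).sum() == pytest.approx(len(res.vip))

    def test_perfect_predictor_feature(self):
        rng = np.random.default_rng(2)
        y = np.tile(np.arange(5.0), 4)
        X = np.tile(y, (3, 1))  # response copied as the features
        X += rng.normal(0, 1e-9, X.shape)
        m = small_matrix(X, space="log2")
        res = pls_stage_model(m, pd.Series(y, index=m.sample_ids), 1, cv_folds=4)
        assert res.r2 >= 0.999

    def test_vip_normalization_on_default_bundle(self, gc_bundle, gc_protein_log):
        res = pls_stage_model(gc_protein_log, gc_bundle.meta.stage_ordinal, 2)
        p = gc_protein_log.n_features
        assert (res.vip**2).sum() == pytest.approx(p, rel=1e-9)

    def test_recovery_r2_exceeds_q2_and_vip_hits_planted(self, gc_bundle,
                                                         gc_protein_log):
        res = pls_stage_model(gc_protein_log, gc_bundle.meta.stage_ordinal, 2)
        assert res.r2 > res.q2 > 0.8
        planted = set(gc_bundle.truth.trend_proteins_pos) \
            | set(gc_bundle.truth.trend_proteins_neg)
        vip_hot = set(res.vip.index[res.vip > 2])
        assert len(vip_hot) > 0
        assert len(vip_hot & planted) / len(vip_hot) >= 0.8

    def test_excessive_components_rejected(self):
        m = small_matrix(np.random.default_rng(0).normal(0, 1, (4, 5)),
                         space="log2")
        y = pd.Series([0, 1, 2, 3, 4.0], index=m.sample_ids)
        with pytest.raises(ConfigurationError):
            pls_stage_model(m, y, n_components=5)


class TestClustering:
    def test_two_blobs_pure(self):
        rng = np.random.default_rng(0)
        X = np.hstack([rng.normal(0, 0.1, (10, 6)), rng.normal(5, 0.1, (10, 6))])
        m = small_matrix(X, space="autoscaled")
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=m.sample_ids)
        res = hierarchical_cluster(m, 2, labels=labels)
        assert res.purity == 100.0

    def test_k_equals_n_trivially_pure(self):
        rng = np.random.default_rng(1)
        m = small_matrix(rng.normal(0, 1, (5, 6)), space="autoscaled")
        labels = pd.Series(list("aabbcc"), index=m.sample_ids)
        res = hierarchical_cluster(m, 6, labels=labels)
        assert res.purity == 100.0

    def test_k_out_of_range(self):
        m = small_matrix(np.random.default_rng(2).normal(0, 1, (5, 4)),
                         space="autoscaled")
        with pytest.raises(ConfigurationError):
            hierarchical_cluster(m, 1)
        with pytest.raises(ConfigurationError):
            hierarchical_cluster(m, 5)

    def test_gc_proteome_splits_by_fraction(self, gc_bundle, gc_protein_log):
        scaled = preprocess.normalize(gc_protein_log, "autoscale")
        res = hierarchical_cluster(scaled, 2, labels=gc_bundle.meta.fraction)
        assert res.purity == 100.0

    def test_kmeans_planted_two_means(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 10), rng.normal(10, 1, 10)])
        m = small_matrix(x[None, :], space="autoscaled")
        ords = pd.Series([0] * 10 + [4] * 10, index=m.sample_ids)
        res = kmeans_split(m, ords, seed=0)
        assert (res.assignments.iloc[:10] == "early").all()
        assert (res.assignments.iloc[10:] == "late").all()

    def test_kmeans_gcm_lipids_early_late(self, gc_bundle, gc_lipid_log):
        meta = gc_bundle.meta
        gcm = meta.index[meta.fraction == "GCM"].tolist()
        scaled = preprocess.normalize(gc_lipid_log.subset_samples(gcm), "autoscale")
        res = kmeans_split(scaled, meta.loc[gcm].stage_ordinal, seed=0)
        early = set(res.assignments.index[res.assignments == "early"])
        expected = set(meta.loc[gcm].index[meta.loc[gcm].stage.isin(["E18", "P0"])])
        assert early == expected

    def test_kmeans_degenerate_input_warns(self):
        m = small_matrix(np.ones((3, 4)), space="autoscaled")
        res = kmeans_split(m, pd.Series([0, 1, 2, 3.0], index=m.sample_ids))
        assert res.warnings


class TestSampleCorrelation:
    def test_duplicate_and_negated_samples(self):
        x = np.array([1.0, 2.0, 4.0, 3.0])
        m = small_matrix(np.column_stack([x, x, -x]), space="log2")
        R = sample_correlation_matrix(m)
        assert R.iloc[0, 1] == pytest.approx(1.0)
        assert R.iloc[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(R), 1.0)
        assert np.allclose(R, R.T)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (30, 7))
        m = small_matrix(X, space="log2")
        R = sample_correlation_matrix(m).to_numpy()
        for i in range(7):
            for j in range(7):
                xi, xj = X[:, i], X[:, j]
                num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
                den = np.sqrt(((xi - xi.mean())**2).sum() * ((xj - xj.mean())**2).sum())
                assert R[i, j] == pytest.approx(num / den, abs=1e-12)
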