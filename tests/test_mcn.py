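import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mitoarray as ma
from mitoarray.mcn import GCWaveCorrector, MCNEstimator, PCConfounderAdjuster, _mean_impute

from conftest import make_markers, random_genotypes


def _lrr(values, markers=None, chromosome="1"):
    values = np.asarray(values, float)
    markers = markers if markers is not None else make_markers(values.shape[1], chromosome=chromosome)
    return ma.LRRMatrix([f"s{i}" for i in range(values.shape[0])], markers, values)


class TestComputeLrr:
    def test_constant_column_and_doubling(self):
        markers = make_markers(2)
        r = np.full((4, 2), 100.0)
        r[0, 1] = 200.0
        x = ma.IntensityMatrix([f"s{i}" for i in range(4)], markers, r)
        lrr = ma.compute_lrr(x)
        np.testing.assert_allclose(lrr.lrr[:, 0], 0.0)
        assert lrr.lrr[0, 1] == pytest.approx(1.0)

    def test_zero_intensity_is_missing(self):
        markers = make_markers(1)
        x = ma.IntensityMatrix(["a", "b", "c"], markers, np.array([[0.0], [50.0], [100.0]]))
        lrr = ma.compute_lrr(x)
        assert np.isnan(lrr.lrr[0, 0]) and np.isfinite(lrr.lrr[1:, 0]).all()

    def test_matches_per_column_brute_force(self):
        rng = np.random.default_rng(109)
        r = rng.uniform(10, 200, size=(30, 50))
        x = ma.IntensityMatrix([f"s{i}" for i in range(30)], make_markers(50), r)
        lrr = ma.compute_lrr(x)
        for j in range(50):
            np.testing.assert_allclose(
                lrr.lrr[:, j], np.log2(r[:, j] / np.median(r[:, j])), atol=1e-12
            )


class TestGcCorrect:
    def test_nothing_to_remove(self):
        rng = np.random.default_rng(113)
        vals = rng.normal(0, 0.05, size=(10, 500))
        lrr = _lrr(vals)
        corrected, model = ma.gc_correct(lrr)
        # fitted slopes are pure noise; correction is bounded by the fit noise
        assert np.abs(corrected.lrr - vals).max() < 0.05
        assert model.skipped == []

    def test_planted_linear_wave_removed(self):
        rng = np.random.default_rng(127)
        n, m = 20, 2000
        gc = rng.uniform(0.3, 0.7, size=m)
        markers = make_markers(m, gc=gc)
        wave = 0.5 * (gc - gc.mean())
        vals = wave[None, :] + rng.normal(0, 0.05, size=(n, m))
        corrected, _ = ma.gc_correct(_lrr(vals, markers))
        for i in range(n):
            assert abs(np.corrcoef(corrected.lrr[i], gc)[0, 1]) < 0.05
        # mean-preserving per sample
        np.testing.assert_allclose(corrected.lrr.mean(axis=1), vals.mean(axis=1), atol=1e-10)

    def test_recovers_planted_coefficients(self):
        rng = np.random.default_rng(131)
        m = 1000
        gc = rng.uniform(0.2, 0.8, size=m)
        markers = make_markers(m, gc=gc)
        b1, b2 = 0.8, -0.5
        vals = (b1 * gc + b2 * gc**2)[None, :] + np.zeros((3, m))
        _, model = ma.gc_correct(_lrr(vals, markers))
        np.testing.assert_allclose(
            model.coefficients.to_numpy(), [[b1, b2]] * 3, atol=1e-8
        )

    def test_mito_corrected_with_autosomal_fit(self):
        rng = np.random.default_rng(137)
        gc_a = rng.uniform(0.3, 0.7, 500)
        gc_m = rng.uniform(0.40, 0.48, 50)
        markers = pd.concat(
            [make_markers(500, chromosome="1", gc=gc_a),
             make_markers(50, chromosome="MT", gc=gc_m)],
            ignore_index=True,
        )
        markers["marker_id"] = [f"m{j}" for j in range(550)]
        gc = np.r_[gc_a, gc_m]
        slope = 0.6
        vals = slope * (gc - gc_a.mean())[None, :] + np.zeros((4, 550))
        corrected, _ = ma.gc_correct(_lrr(vals, ma.validate_markers(markers)))
        # the mitochondrial wave component is removed by the autosomal fit
        assert np.abs(corrected.lrr[:, 500:]).max() < 0.02

    def test_too_few_markers_skips_sample(self):
        vals = np.random.default_rng(1).normal(size=(3, 5))
        corrected, model = ma.gc_correct(_lrr(vals), min_markers=10)
        assert len(model.skipped) == 3
        np.testing.assert_allclose(corrected.lrr, vals)


class TestAutosomalPcs:
    def test_batch_separation(self):
        rng = np.random.default_rng(139)
        n, m = 40, 300
        shift = np.r_[np.zeros(20), np.full(20, 0.5)]
        vals = shift[:, None] + rng.normal(0, 1e-3, size=(n, m))
        scores, _ = ma.autosomal_pcs(_lrr(vals), n_pcs=5)
        r = abs(np.corrcoef(scores[:, 0], shift)[0, 1])
        assert r > 0.99

    def test_rank_bound(self):
        vals = np.random.default_rng(3).normal(size=(3, 10))
        with pytest.warns(UserWarning, match="rank bound"):
            scores, _ = ma.autosomal_pcs(_lrr(vals), n_pcs=80)
        assert scores.shape[1] == 2

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(149)
        vals = rng.normal(size=(12, 8))
        scores, pca = ma.autosomal_pcs(_lrr(vals), n_pcs=8)
        recon = scores @ pca.components_ + vals.mean(axis=0)
        np.testing.assert_allclose(recon, vals, atol=1e-8)

    def test_deterministic_sign(self):
        vals = np.random.default_rng(151).normal(size=(20, 10))
        s1, p1 = ma.autosomal_pcs(_lrr(vals), n_pcs=3)
        s2, p2 = ma.autosomal_pcs(_lrr(vals), n_pcs=3)
        np.testing.assert_array_equal(s1, s2)
        for k in range(3):
            j = np.argmax(np.abs(p1.components_[k]))
            assert p1.components_[k, j] > 0


class TestAdjustMitoLrr:
    def test_exact_linear_combination_gives_zero(self):
        rng = np.random.default_rng(157)
        n = 30
        pcs = rng.normal(size=(n, 4))
        beta = rng.normal(size=(4, 6))
        y = pcs @ beta + 1.5
        adj = ma.adjust_mito_lrr(_lrr(y, chromosome="MT"), pcs)
        np.testing.assert_allclose(adj.lrr, 0.0, atol=1e-10)

    def test_orthogonal_pcs_leave_centered_input(self):
        rng = np.random.default_rng(163)
        n = 50
        y = rng.normal(size=(n, 3))
        pcs = np.zeros((n, 2))  # degenerate: regression fits only the mean
        adj = ma.adjust_mito_lrr(_lrr(y, chromosome="MT"), pcs)
        np.testing.assert_allclose(adj.lrr, y - y.mean(axis=0), atol=1e-10)

    def test_batch_confounding_removed(self):
        cfg = ma.SimulationConfig(
            n_samples=200, n_auto_markers=400, n_mito_markers=50, n_chromosomes=2,
            batch_sd=0.4, noise_sd=0.05, mcn_log_sd=0.0, seed=167,
        )
        ds = ma.simulate_dataset(cfg)
        lrr = ma.compute_lrr(ds.intensity)
        lrr, _ = ma.gc_correct(lrr, markers=ds.markers)
        auto_ids = ds.markers.loc[ds.markers["chromosome"] != "MT", "marker_id"].tolist()
        mito_ids = ds.markers.loc[ds.markers["chromosome"] == "MT", "marker_id"].tolist()
        shift = ds.truth.batch_label.astype(float)
        mito = lrr.subset_markers(mito_ids)
        before = np.mean(
            [abs(np.corrcoef(mito.lrr[:, j], shift)[0, 1]) for j in range(len(mito_ids))]
        )
        pcs, _ = ma.autosomal_pcs(lrr.subset_markers(auto_ids), n_pcs=20)
        adj = ma.adjust_mito_lrr(mito, pcs)
        after = np.mean(
            [abs(np.corrcoef(adj.lrr[:, j], shift)[0, 1]) for j in range(len(mito_ids))]
        )
        assert before > 0.5 and after < 0.05

    def test_pc_count_reduced_with_warning(self):
        rng = np.random.default_rng(173)
        y = rng.normal(size=(5, 3))
        pcs = rng.normal(size=(5, 10))
        with pytest.warns(UserWarning, match="reducing adjustment PCs"):
            ma.adjust_mito_lrr(_lrr(y, chromosome="MT"), pcs)


class TestExtractMcn:
    def test_rank_preservation_of_shared_signal(self):
        rng = np.random.default_rng(179)
        s = rng.normal(size=40)
        vals = np.outer(s, np.ones(10)) + rng.normal(0, 1e-6, size=(40, 10))
        res = ma.extract_mcn(_lrr(vals, chromosome="MT"))
        assert stats.spearmanr(res.table["mcn"], s).statistic == pytest.approx(1.0)
        assert stats.spearmanr(res.table["raw_score"], res.table["mcn"]).statistic == 1.0

    def test_blom_quantiles_closed_form(self):
        vals = np.outer([3.0, 1.0, 5.0, 2.0, 4.0], np.ones(4))
        res = ma.extract_mcn(_lrr(vals, chromosome="MT"))
        ranks = stats.rankdata(res.table["raw_score"])
        expected = stats.norm.ppf((ranks - 0.375) / (5 + 0.25))
        np.testing.assert_allclose(res.table["mcn"], expected, atol=1e-12)

    def test_total_tie_maps_to_zero(self):
        vals = np.ones((5, 3))
        res = ma.extract_mcn(_lrr(vals, chromosome="MT"))
        np.testing.assert_allclose(res.table["mcn"], 0.0)

    def test_standardized_moments(self):
        rng = np.random.default_rng(181)
        vals = rng.normal(size=(200, 12))
        res = ma.extract_mcn(_lrr(vals, chromosome="MT"))
        z = res.table["mcn"].to_numpy()
        assert abs(z.mean()) < 1e-8
        assert abs(z.std(ddof=1) - 1) < 0.02


class TestWgsMcn:
    def test_arithmetic(self):
        assert ma.wgs_mcn(30.0, 30.0) == 2.0
        assert ma.wgs_mcn(30.0, 1500.0) == 100.0
        with pytest.raises(ValueError):
            ma.wgs_mcn(0.0, 10.0)

    def test_tracks_truth_on_simulated_depths(self):
        ds = ma.simulate_dataset(ma.SimulationConfig(n_samples=300, n_auto_markers=50,
                                                     n_mito_markers=5, seed=191))
        est = ma.wgs_mcn(ds.depths["autosomal_depth"].to_numpy(),
                         ds.depths["mito_depth"].to_numpy())
        rho = stats.spearmanr(est, ds.truth.true_mcn).statistic
        assert rho > 0.95


class TestSelectHqMarkers:
    def test_off_target_excluded(self, small_dataset):
        ds = small_dataset
        markers = ds.genotypes.markers.copy()
        auto_idx = markers.index[markers["chromosome"] != "MT"][:10]
        markers.loc[auto_idx, "off_target"] = True
        g = ma.GenotypeMatrix(ds.genotypes.sample_ids, markers, ds.genotypes.calls)
        hq = ma.select_hq_markers(g)
        banned = set(markers.loc[auto_idx, "marker_id"])
        assert not banned & set(hq["autosomal"])

    def test_duplicate_columns_pruned(self):
        rng = np.random.default_rng(193)
        g = random_genotypes(60, 40, rng)
        dup = ma.GenotypeMatrix(
            g.sample_ids,
            pd.concat([g.markers, g.markers.assign(
                marker_id=[f"dup{j}" for j in range(40)],
                position=g.markers["position"] + 1)], ignore_index=True),
            np.hstack([g.calls, g.calls]),
        )
        mito = random_genotypes(60, 3, rng, chromosome="MT")
        full = ma.GenotypeMatrix(
            g.sample_ids,
            pd.concat([dup.markers, mito.markers], ignore_index=True),
            np.hstack([dup.calls, mito.calls]),
        )
        hq = ma.select_hq_markers(full)
        for j in range(40):
            pair = {g.marker_ids[j], f"dup{j}"}
            assert len(pair & set(hq["autosomal"])) <= 1

    def test_thresholds_post_audit(self, small_dataset):
        ds = small_dataset
        hq = ma.select_hq_markers(ds.genotypes)
        stats_df = ma.marker_stats(ds.genotypes, min_mac=0)
        for mid in hq["autosomal"]:
            assert stats_df.loc[mid, "call_rate"] > 0.95
            assert not (np.isfinite(stats_df.loc[mid, "hwe_p"]) and stats_df.loc[mid, "hwe_p"] <= 1e-6)
            assert not ds.markers.set_index("marker_id").loc[mid, "off_target"]

    def test_no_mito_survivors_aborts(self):
        rng = np.random.default_rng(197)
        g = random_genotypes(20, 30, rng)
        with pytest.raises(ma.PipelineError, match="mitochondrial"):
            ma.select_hq_markers(g)

    def test_target_auto_count_cap(self, small_dataset):
        hq = ma.select_hq_markers(small_dataset.genotypes, target_auto_count=10)
        assert len(hq["autosomal"]) == 10


class TestSampleQcAndAssociation:
    def test_planted_lrr_sd_failure(self, small_dataset):
        ds = small_dataset
        lrr = ma.compute_lrr(ds.intensity)
        noisy = lrr.lrr.copy()
        rng = np.random.default_rng(199)
        noisy[0] = rng.normal(0, 0.6, size=noisy.shape[1])
        lrr2 = ma.LRRMatrix(lrr.sample_ids, lrr.markers, noisy)
        flags = ma.mcn_sample_qc(ds.genotypes, lrr2, samples=ds.samples)
        assert not flags["passed"].iloc[0] and "lrr_sd" in flags["reasons"].iloc[0]
        assert flags["passed"].iloc[1:].all()

    def test_phenotype_requirement_mode(self, small_dataset):
        ds = small_dataset
        samples = ds.samples.copy()
        samples.loc[0, ["age", "WBC", "HEMO", "PLT"]] = np.nan
        est_only = ma.mcn_sample_qc(ds.genotypes, None, samples=samples, require_phenotypes=False)
        assoc = ma.mcn_sample_qc(ds.genotypes, None, samples=samples, require_phenotypes=True)
        sid = samples.loc[0, "sample_id"]
        assert est_only.loc[sid, "passed"]
        assert not assoc.loc[sid, "passed"] and "phenotype" in assoc.loc[sid, "reasons"]

    def test_association_recovers_planted_effects(self):
        cfg = ma.SimulationConfig(n_samples=500, n_auto_markers=100, n_mito_markers=5, seed=211)
        ds = ma.simulate_dataset(cfg)
        z = ma.inverse_normal_transform(ds.truth.true_mcn)
        mcn_table = pd.DataFrame(dict(sample_id=ds.genotypes.sample_ids, raw_score=z, mcn=z))
        res = ma.associate(ma.MCNResult(table=mcn_table), ds.samples,
                           phenotypes=("age", "WBC", "HEMO", "PLT"))
        assert res.loc["age", "rho"] < 0 and res.loc["age", "ci_high"] < 0
        assert res.loc["WBC", "rho"] > 0 and res.loc["WBC", "ci_low"] > 0
        for pheno in res.index:
            assert res.loc[pheno, "ci_low"] <= res.loc[pheno, "rho"] <= res.loc[pheno, "ci_high"]

    def test_perfect_monotone_phenotype(self):
        rng = np.random.default_rng(223)
        z = rng.normal(size=50)
        table = pd.DataFrame(dict(sample_id=[f"s{i}" for i in range(50)], raw_score=z, mcn=z))
        samples = pd.DataFrame(dict(sample_id=table["sample_id"], reported_sex="unknown",
                                    age=stats.rankdata(z)))
        res = ma.associate(ma.MCNResult(table=table), samples, phenotypes=("age",))
        assert res.loc["age", "rho"] == pytest.approx(1.0)
        assert -1 <= res.loc["age", "ci_low"] <= 1

    def test_null_phenotype_near_zero(self):
        rng = np.random.default_rng(227)
        z = rng.normal(size=1000)
        table = pd.DataFrame(dict(sample_id=[f"s{i}" for i in range(1000)], raw_score=z, mcn=z))
        samples = pd.DataFrame(dict(sample_id=table["sample_id"], reported_sex="unknown",
                                    age=rng.normal(size=1000)))
        res = ma.associate(ma.MCNResult(table=table), samples, phenotypes=("age",))
        assert abs(res.loc["age", "rho"]) < 0.08


class TestPipeline:
    def test_end_to_end_recovery(self, small_dataset):
        ds = small_dataset
        res = ma.run_mcn_pipeline(ds.genotypes, ds.intensity, markers=ds.markers,
                                  samples=ds.samples, depths=ds.depths, n_pcs=20)
        rho = stats.spearmanr(res.table["mcn"], ds.truth.true_mcn).statistic
        assert rho > 0.8
        assert "wgs_mcn" in res.table.columns
        assert res.stage_report["stage"].tolist() == [
            "input", "compute_lrr", "gc_correct", "select_hq_markers",
            "adjust_mito_lrr", "extract_mcn", "mcn_sample_qc",
        ]

    def test_determinism(self, small_dataset):
        ds = small_dataset
        r1 = ma.run_mcn_pipeline(ds.genotypes, ds.intensity, n_pcs=15)
        r2 = ma.run_mcn_pipeline(ds.genotypes, ds.intensity, n_pcs=15)
        np.testing.assert_array_equal(r1.table["mcn"], r2.table["mcn"])

    def test_standardized_output_properties(self, small_dataset):
        ds = small_dataset
        res = ma.run_mcn_pipeline(ds.genotypes, ds.intensity, n_pcs=15)
        z = res.table["mcn"].to_numpy()
        assert abs(z.mean()) < 1e-8
        assert abs(z.std(ddof=1) - 1) < 0.02
        assert (
            stats.rankdata(res.table["raw_score"]) == stats.rankdata(z)
        ).all()

    def test_empty_mito_aborts(self):
        rng = np.random.default_rng(229)
        g = random_genotypes(30, 40, rng)
        x = ma.IntensityMatrix(g.sample_ids, g.markers, rng.uniform(50, 150, g.calls.shape))
        with pytest.raises(ma.PipelineError):
            ma.run_mcn_pipeline(g, x)


class TestSklearnEstimators:
    def test_gc_corrector_matches_function(self):
        rng = np.random.default_rng(233)
        gc = rng.uniform(0.3, 0.7, 200)
        x = 0.4 * gc[None, :] + rng.normal(0, 0.05, size=(8, 200))
        est = GCWaveCorrector(degree=2)
        out = est.fit_transform(x, gc=gc)
        corrected, model = ma.gc_correct(_lrr(x, make_markers(200, gc=gc)))
        np.testing.assert_allclose(out, corrected.lrr, atol=1e-12)
        np.testing.assert_allclose(est.coef_, model.coefficients.to_numpy(), atol=1e-12)

    def test_pc_adjuster_matches_functions(self):
        rng = np.random.default_rng(239)
        ref = rng.normal(size=(30, 50))
        tgt = rng.normal(size=(30, 6))
        est = PCConfounderAdjuster(n_pcs=10).fit(ref)
        out = est.transform(tgt)
        pcs, _ = ma.autosomal_pcs(_lrr(ref), n_pcs=10)
        expected = ma.adjust_mito_lrr(_lrr(tgt, chromosome="MT"), pcs)
        np.testing.assert_allclose(out, expected.lrr, atol=1e-10)

    def test_mcn_estimator_params_and_fit(self, small_dataset):
        ds = small_dataset
        est = MCNEstimator(n_pcs=15)
        assert est.get_params()["n_pcs"] == 15
        est.set_params(n_pcs=10)
        est.fit(ds.intensity, genotypes=ds.genotypes, samples=ds.samples)
        assert len(est.mcn_) == ds.intensity.n_samples
        func = ma.run_mcn_pipeline(ds.genotypes, ds.intensity, samples=ds.samples, n_pcs=10)
        np.testing.assert_allclose(est.mcn_, func.table["mcn"], atol=1e-12)


def test_mean_impute_fills_column_means():
    x = np.array([[1.0, np.nan], [3.0, 4.0], [np.nan, 6.0]])
    with pytest.warns(UserWarning, match="missing LRR"):
        out = _mean_impute(x)
    assert out[2, 0] == 2.0 and out[0, 1] == 5.0
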