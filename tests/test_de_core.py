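"""Normalization, dispersion machinery and the Monte-Carlo NB test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mztseq as m
from mztseq.de_core import DispersionTrend, FeatureEstimate, NullDistribution, sample_nb

from conftest import bh_stepup_reference


def make_matrix(counts, design, kinds=None):
    df = pd.DataFrame(counts)
    return m.CountMatrix(counts=df.astype(float), design=design, feature_kinds=kinds or {})


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        cm = make_matrix({"a": [10, 20, 5], "b": [10, 20, 5]}, {"a": "x", "b": "y"})
        f = m.compute_size_factors(cm)
        assert f["a"] == pytest.approx(1.0) and f["b"] == pytest.approx(1.0)

    def test_pure_scaling_recovered(self):
        cm = make_matrix({"a": [10, 20, 5], "b": [20, 40, 10]}, {"a": "x", "b": "y"})
        f = m.compute_size_factors(cm)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_library_size_ratio_recovered_from_nb_counts(self):
        rng = np.random.default_rng(42)
        mu = np.exp(rng.uniform(np.log(20), np.log(2000), size=2000))
        counts = {
            "a": sample_nb(rng, mu, 0.05 + 2.0 / mu),
            "b": sample_nb(rng, 3.0 * mu, 0.05 + 2.0 / (3 * mu)),
        }
        f = m.compute_size_factors(make_matrix(counts, {"a": "x", "b": "y"}))
        assert f["b"] / f["a"] == pytest.approx(3.0, rel=0.10)

    def test_geometric_mean_is_one(self):
        cm = make_matrix({"a": [10, 20, 5], "b": [25, 50, 9], "c": [7, 13, 2]},
                         {"a": "x", "b": "y", "c": "z"})
        vals = np.array(list(m.compute_size_factors(cm).factors.values()))
        assert np.exp(np.log(vals).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_fallback_when_no_feature_positive_everywhere(self):
        cm = make_matrix({"a": [10, 0], "b": [0, 10]}, {"a": "x", "b": "y"})
        with pytest.warns(UserWarning, match="no feature positive"):
            f = m.compute_size_factors(cm)
        assert all(v > 0 for v in f.factors.values())


class TestNormalize:
    def test_unit_factors_are_identity(self):
        cm = make_matrix({"a": [10, 20], "b": [10, 20]}, {"a": "x", "b": "y"})
        norm = m.normalize_counts(cm, m.SizeFactors({"a": 1.0, "b": 1.0}))
        np.testing.assert_array_equal(norm.counts.values, cm.counts.values)

    def test_division_by_factor(self):
        cm = make_matrix({"a": [10.0], "b": [10.0]}, {"a": "x", "b": "y"})
        norm = m.normalize_counts(cm, m.SizeFactors({"a": 2.0, "b": 0.5}))
        assert norm.counts.loc[0, "a"] == 5.0 and norm.counts.loc[0, "b"] == 20.0

    def test_normalization_fixed_point(self, mzt_scenario):
        _, _, matrix = mzt_scenario
        norm = m.normalize_counts(matrix, m.compute_size_factors(matrix))
        refit = m.compute_size_factors(norm)
        assert all(v == pytest.approx(1.0, abs=1e-6) for v in refit.factors.values())


class TestEstimateFeature:
    def test_constant_counts_have_zero_dispersion(self):
        cm = make_matrix({"a": [10.0], "b": [10.0], "c": [10.0]},
                         {"a": "x", "b": "x", "c": "x"})
        est = m.estimate_feature(cm, cm, cm.design, 0)
        assert est.observed_dispersion == 0.0

    def test_poisson_data_has_near_zero_dispersion(self):
        rng = np.random.default_rng(1)
        n = 2000
        counts = {f"s{i}": [float(rng.poisson(100))] for i in range(n)}
        cm = make_matrix(counts, {f"s{i}": "x" for i in range(n)})
        est = m.estimate_feature(cm, cm, cm.design, 0)
        assert est.observed_dispersion < 0.01

    def test_moment_estimator_recovers_nb_dispersion(self):
        rng = np.random.default_rng(2)
        n = 200
        draws = sample_nb(rng, 100.0, 0.5, size=2 * n).astype(float)
        design = {f"s{i}": ("x" if i < n else "y") for i in range(2 * n)}
        cm = make_matrix({f"s{i}": [draws[i]] for i in range(2 * n)}, design)
        est = m.estimate_feature(cm, cm, design, 0)
        assert 0.35 <= est.observed_dispersion <= 0.65

    def test_trend_floor_applied(self):
        cm = make_matrix({"a": [10.0], "b": [10.0], "c": [10.0]},
                         {"a": "x", "b": "x", "c": "x"})
        est = m.estimate_feature(cm, cm, cm.design, 0, trend=DispersionTrend(0.1, 5.0))
        assert est.effective_dispersion == pytest.approx(0.1 + 5.0 / 10.0)


def est(mu, alpha):
    return FeatureEstimate("f", {}, mu, alpha)


class TestDispersionTrend:
    def test_exact_recovery_from_noise_free_data(self):
        mus = np.linspace(5, 500, 100)
        trend = m.fit_dispersion_trend([est(mu, 0.1 + 5.0 / mu) for mu in mus])
        assert trend.a0 == pytest.approx(0.1, abs=1e-6)
        assert trend.a1 == pytest.approx(5.0, abs=1e-6)

    def test_constant_dispersion_gives_flat_trend(self):
        mus = np.linspace(5, 500, 50)
        trend = m.fit_dispersion_trend([est(mu, 0.2) for mu in mus])
        assert trend.a0 == pytest.approx(0.2, abs=1e-9)
        assert trend.a1 == pytest.approx(0.0, abs=1e-6)

    def test_noisy_trend_recovery(self):
        rng = np.random.default_rng(3)
        mus = np.exp(rng.uniform(np.log(10), np.log(2000), size=2000))
        alphas = np.maximum(0.0, (0.1 + 5.0 / mus) * rng.normal(1.0, 0.3, size=2000))
        trend = m.fit_dispersion_trend([est(mu, a) for mu, a in zip(mus, alphas)])
        assert trend.a0 == pytest.approx(0.1, rel=0.25)

    def test_too_few_features_errors_with_advice(self):
        with pytest.raises(ValueError, match="constant_dispersion"):
            m.fit_dispersion_trend([est(10.0, 0.1)] * 5)

    def test_trend_is_positive_and_non_increasing(self):
        trend = DispersionTrend(0.05, 2.0)
        mus = np.array([1.0, 10.0, 100.0, 1e6])
        vals = trend.evaluate(mus)
        assert (vals > 0).all() and (np.diff(vals) <= 0).all()


class TestNullSimulation:
    def test_equal_n_null_is_symmetric(self):
        cfg = m.DEConfig(iterations=10000, seed=0)
        rng = np.random.default_rng(0)
        null = m.simulate_null_logfc(50.0, 0.2, 3, 3, cfg, rng)
        assert abs(null.sim_mean) <= 3 * null.sim_sd / math.sqrt(null.iterations)

    def test_poisson_delta_method_sd(self):
        # mu=100, alpha=0, n=3: sd(log2 ratio) ~ sqrt(2/(3*100))/ln2 ~ 0.118
        cfg = m.DEConfig(iterations=10000, seed=0)
        rng = np.random.default_rng(1)
        null = m.simulate_null_logfc(100.0, 0.0, 3, 3, cfg, rng)
        assert null.sim_sd == pytest.approx(0.118, rel=0.25)

    def test_sd_monotone_in_dispersion(self):
        cfg = m.DEConfig(iterations=5000, seed=0)
        sds = []
        for alpha in (0.0, 0.5, 2.0):
            rng = np.random.default_rng(2)
            sds.append(m.simulate_null_logfc(100.0, alpha, 3, 3, cfg, rng).sim_sd)
        assert sds[0] < sds[1] < sds[2]

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            m.simulate_null_logfc(0.0, 0.1, 3, 3, m.DEConfig(), np.random.default_rng(0))


class TestTestFeature:
    def test_observed_at_null_mean_gives_p_one(self):
        z, p = m.test_feature(0.3, NullDistribution(0.3, 0.5, 1000, 0))
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_normal_quantile_identity(self):
        z, p = m.test_feature(1.959964, NullDistribution(0.0, 1.0, 1000, 0))
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_sign_antisymmetry(self):
        null = NullDistribution(0.0, 0.7, 1000, 0)
        z1, p1 = m.test_feature(1.3, null)
        z2, p2 = m.test_feature(-1.3, null)
        assert z1 == -z2 and p1 == p2


class TestBenjaminiHochberg:
    def test_stepup_example(self):
        np.testing.assert_allclose(
            m.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert m.benjamini_hochberg([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            m.benjamini_hochberg([0.1, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(derandomize=True, max_examples=200)
    def test_matches_stepup_formula_and_dominates_raw(self, pvals):
        adj = m.benjamini_hochberg(pvals)
        np.testing.assert_allclose(adj, bh_stepup_reference(pvals), rtol=1e-12, atol=1e-12)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()  # adj respects p ordering


class TestRunDifferentialExpression:
    def test_low_count_feature_not_tested(self):
        design = {f"{c}{i}": c for c in "ab" for i in range(3)}
        counts = {s: [3.5 if s.startswith("a") else 6.0, 50.0] for s in design}
        for s in design:
            counts[s][1] = 50.0
        cm = make_matrix(counts, design)
        recs = m.run_differential_expression(cm, "a", "b", m.DEConfig(seed=0, constant_dispersion=0.1))
        assert recs[0].tested is False and math.isnan(recs[0].p)
        assert recs[1].tested is True

    def test_swap_negates_effect_and_keeps_significance(self, mzt_scenario):
        _, _, matrix = mzt_scenario
        sub = m.CountMatrix(
            counts=matrix.counts.iloc[:150],
            design=dict(matrix.design),
            feature_kinds={f: matrix.feature_kinds[f] for f in matrix.counts.index[:150]},
        )
        cfg = m.DEConfig(seed=5, iterations=500, constant_dispersion=0.05)
        ab = m.run_differential_expression(sub, m.OOCYTE, m.WT2C, cfg)
        ba = m.run_differential_expression(sub, m.WT2C, m.OOCYTE, cfg)
        for r1, r2 in zip(ab, ba):
            if not r1.tested:
                assert not r2.tested
                continue
            assert r1.log2fc == pytest.approx(-r2.log2fc, abs=1e-12)
            # z negates up to the MC error of sim_mean (|z1+z2| = 2|sim_mean|/sd)
            assert abs(r1.z + r2.z) <= 8.0 / math.sqrt(cfg.iterations)
            if min(r1.adj_p, r2.adj_p) < 1e-4 or max(r1.adj_p, r2.adj_p) > 0.2:
                assert r1.significant == r2.significant

    def test_same_seed_bit_reproducible(self, mzt_scenario):
        _, _, matrix = mzt_scenario
        sub = m.CountMatrix(
            counts=matrix.counts.iloc[:100],
            design=dict(matrix.design),
            feature_kinds={f: matrix.feature_kinds[f] for f in matrix.counts.index[:100]},
        )
        cfg = m.DEConfig(seed=9, iterations=300, constant_dispersion=0.05)
        a = m.de_table(m.run_differential_expression(sub, m.OOCYTE, m.WT2C, cfg))
        b = m.de_table(m.run_differential_expression(sub, m.OOCYTE, m.WT2C, cfg))
        pd.testing.assert_frame_equal(a, b)

    def test_changing_seed_moves_p_only_by_mc_error(self, mzt_scenario):
        _, _, matrix = mzt_scenario
        sub = m.CountMatrix(
            counts=matrix.counts.iloc[:200],
            design=dict(matrix.design),
            feature_kinds={f: matrix.feature_kinds[f] for f in matrix.counts.index[:200]},
        )
        za = m.de_table(m.run_differential_expression(sub, m.OOCYTE, m.WT2C, m.DEConfig(seed=1)))
        zb = m.de_table(m.run_differential_expression(sub, m.OOCYTE, m.WT2C, m.DEConfig(seed=2)))
        za, zb = za[za.tested.astype(bool)], zb[zb.tested.astype(bool)]
        # sim_sd has relative MC error ~1/sqrt(2*iterations); z should track closely
        rel = np.abs(za.z - zb.z) / (1.0 + np.abs(za.z))
        assert np.median(rel) < 0.05 and np.corrcoef(za.z, zb.z)[0, 1] > 0.99

    def test_alpha_eff_floored_by_trend_and_genes_repeats_pooled(self, mzt_de):
        tested = [r for r in mzt_de if r.tested]
        kinds = {r.kind for r in tested}
        assert kinds == {m.GENE_LOCUS, m.REPEAT_FAMILY}
        # one pooled BH: adjusted p restricted to any kind respects global step-up
        p = np.array([r.p for r in tested])
        adj = np.array([r.adj_p for r in tested])
        np.testing.assert_allclose(adj, bh_stepup_reference(p), rtol=1e-10, atol=1e-12)

    def test_missing_condition_errors(self, mzt_scenario):
        _, _, matrix = mzt_scenario
        with pytest.raises(ValueError):
            m.run_differential_expression(matrix, m.OOCYTE, "nonexistent", m.DEConfig())


class TestSampleNB:
    def test_mean_and_variance_match_parameterization(self):
        rng = np.random.default_rng(0)
        draws = sample_nb(rng, 50.0, 0.3, size=200000)
        assert draws.mean() == pytest.approx(50.0, rel=0.02)
        assert draws.var() == pytest.approx(50.0 + 0.3 * 2500.0, rel=0.05)

    def test_zero_dispersion_is_poisson(self):
        rng = np.random.default_rng(1)
        draws = sample_nb(rng, 40.0, 0.0, size=100000)
        assert draws.var() / draws.mean() == pytest.approx(1.0, rel=0.05)
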