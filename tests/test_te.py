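"""TE computation and differential testing: hand-computed size factors,
normalisation invariances, agreement with an independent GLM fit, and
the conditional-dependence classifier rule."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ribotekit.annotation import CountMatrix
from ribotekit.simulate import SimConfig, generate_transcriptome, simulate_counts
from ribotekit.te import (
    classify_conditional_dependence,
    compute_te,
    correlate_delta_te,
    delta_te_test,
    size_factors,
)

from conftest import MUT_T, MUT_U, WT_T, WT_U, make_matrix, make_samples


class TestSizeFactors:
    def test_total_count_two_libraries(self):
        samples = make_samples("RNA", (WT_U,), n_reps=2)
        m = make_matrix([[10, 20]], ["g1"], samples, "RNA")
        f = size_factors(m, "total-count")
        assert np.allclose(f.to_numpy(), [1 / math.sqrt(2), math.sqrt(2)])

    def test_median_of_ratios_hand_example(self):
        samples = make_samples("RNA", (WT_U,), n_reps=2)
        m = make_matrix([[10, 20], [30, 60]], ["g1", "g2"], samples, "RNA")
        f = size_factors(m, "median-of-ratios")
        assert np.allclose(f.to_numpy(), [0.7071, 1.4142], atol=1e-4)

    @pytest.mark.parametrize("method", ["total-count", "median-of-ratios"])
    def test_identical_columns_give_unit_factors(self, method):
        samples = make_samples("RNA", (WT_U,), n_reps=2)
        m = make_matrix([[7, 7], [3, 3]], ["g1", "g2"], samples, "RNA")
        assert np.allclose(size_factors(m, method).to_numpy(), 1.0)

    def test_all_zero_sample_rejected(self):
        samples = make_samples("RNA", (WT_U,), n_reps=2)
        m = make_matrix([[5, 0], [3, 0]], ["g1", "g2"], samples, "RNA")
        with pytest.raises(ValueError, match="all-zero"):
            size_factors(m)

    def test_invariant_to_feature_order(self):
        samples = make_samples("RNA", (WT_U,), n_reps=2)
        m1 = make_matrix([[10, 20], [30, 60], [5, 9]], list("abc"),
                         samples, "RNA")
        m2 = make_matrix([[5, 9], [10, 20], [30, 60]], list("cab"),
                         samples, "RNA")
        for method in ("total-count", "median-of-ratios"):
            assert np.allclose(size_factors(m1, method).to_numpy(),
                               size_factors(m2, method).to_numpy())


class TestComputeTE:
    def test_ratio_with_unit_factors(self):
        s_rpf = make_samples("RPF", (WT_U,), n_reps=2)
        s_rna = make_samples("RNA", (WT_U,), n_reps=2)
        rpf = make_matrix([[100, 100]], ["g1"], s_rpf, "RPF")
        rna = make_matrix([[50, 50]], ["g1"], s_rna, "RNA")
        ones = pd.Series(1.0, index=[s.name for s in s_rpf])
        ones_r = pd.Series(1.0, index=[s.name for s in s_rna])
        te = compute_te(rpf, rna, ones, ones_r)
        assert te.loc["g1", "TE:WT:untreated:mean"] == pytest.approx(2.0)

    def test_invariant_to_scaling_one_library_with_its_factor(self, paired_counts):
        rpf, rna = paired_counts
        sf_rpf = size_factors(rpf, "total-count")
        sf_rna = size_factors(rna, "total-count")
        base = compute_te(rpf, rna, sf_rpf, sf_rna)
        c = 7
        scaled_counts = rpf.counts.copy()
        name = rpf.sample_names[0]
        scaled_counts[name] = scaled_counts[name] * c
        rpf2 = CountMatrix(scaled_counts, rpf.samples, "RPF")
        sf2 = sf_rpf.copy()
        sf2[name] = sf2[name] * c
        scaled = compute_te(rpf2, rna, sf2, sf_rna)
        pd.testing.assert_frame_equal(base, scaled)

    def test_undetected_genes_carry_nan(self):
        s_rpf = make_samples("RPF", (WT_U,), n_reps=2)
        s_rna = make_samples("RNA", (WT_U,), n_reps=2)
        rpf = make_matrix([[100, 100], [0, 1]], ["g1", "g2"], s_rpf, "RPF")
        rna = make_matrix([[50, 50], [0, 0]], ["g1", "g2"], s_rna, "RNA")
        ones = pd.Series(1.0, index=[s.name for s in s_rpf])
        ones_r = pd.Series(1.0, index=[s.name for s in s_rna])
        te = compute_te(rpf, rna, ones, ones_r)
        assert not te.loc["g2", "detected"]
        assert np.isnan(te.loc["g2", "TE:WT:untreated:mean"])

    def test_noise_free_te_ratios_match_truth(self):
        cfg = SimConfig(seed=2, n_genes=40, noise=False)
        tx = generate_transcriptome(cfg)
        sim = simulate_counts(tx, cfg)
        ones = pd.Series(1.0, index=sim.rpf.sample_names)
        ones_r = pd.Series(1.0, index=sim.rna.sample_names)
        te = compute_te(sim.rpf, sim.rna, ones, ones_r)
        got = te["TE:WT:untreated:mean"]
        want = sim.truth.te["WT:untreated"]
        assert np.allclose(got, want)


class TestDeltaTE:
    def test_identical_counts_give_exactly_zero(self):
        # every gene repeats its replicate counts across the two
        # conditions, so the interaction estimate must be exactly zero
        s_rpf = make_samples("RPF", (WT_U, WT_T))
        s_rna = make_samples("RNA", (WT_U, WT_T))
        rpf = make_matrix([[80, 90, 80, 90], [40, 41, 40, 41],
                           [30, 29, 30, 29]],
                          ["g1", "g2", "g3"], s_rpf, "RPF")
        rna = make_matrix([[50, 55, 50, 55], [30, 29, 30, 29],
                           [25, 27, 25, 27]],
                          ["g1", "g2", "g3"], s_rna, "RNA")
        res = delta_te_test(rpf, rna, (WT_T, WT_U), sf_method="total-count")
        assert (res.table["log2fc"] == 0.0).all()

    def test_wald_estimate_matches_plugin_ratio_at_high_counts(self):
        cfg = SimConfig(seed=12, n_genes=200, expression_log_mean=math.log(3e4),
                        expression_log_sd=0.2, size_factor_sd=0.0)
        tx = generate_transcriptome(cfg)
        sim = simulate_counts(tx, cfg)
        res = delta_te_test(sim.rpf, sim.rna, (WT_T, WT_U))
        sf_rpf = size_factors(sim.rpf.subset([WT_T, WT_U]), "median-of-ratios")
        sf_rna = size_factors(sim.rna.subset([WT_T, WT_U]), "median-of-ratios")
        def cond_mean(m, sf, cond):
            cols = m.columns_for(cond)
            return (m.counts[cols] / sf[cols]).mean(axis=1)
        plug = np.log2(
            (cond_mean(sim.rpf, sf_rpf, WT_T) / cond_mean(sim.rna, sf_rna, WT_T))
            / (cond_mean(sim.rpf, sf_rpf, WT_U) / cond_mean(sim.rna, sf_rna, WT_U))
        )
        assert np.abs(res.table["log2fc"] - plug).max() < 0.05

    def test_agrees_with_statsmodels_glm_oracle(self):
        """Independent check: statsmodels NB GLM with the same fixed
        dispersion and offsets reproduces coefficient and SE."""
        cfg = SimConfig(seed=13, n_genes=8)
        tx = generate_transcriptome(cfg)
        sim = simulate_counts(tx, cfg)
        res = delta_te_test(sim.rpf, sim.rna, (WT_T, WT_U),
                            sf_method="total-count")
        sf_rpf = size_factors(sim.rpf.subset([WT_T, WT_U]), "total-count")
        sf_rna = size_factors(sim.rna.subset([WT_T, WT_U]), "total-count")
        for gene in res.table.index[:5]:
            alpha = float(res.table.loc[gene, "dispersion"])
            y, off, is_rpf, is_t = [], [], [], []
            for m, sf in ((sim.rpf, sf_rpf), (sim.rna, sf_rna)):
                for s in m.subset([WT_T, WT_U]).samples:
                    y.append(m.counts.loc[gene, s.name])
                    off.append(math.log(sf[s.name]))
                    is_rpf.append(1.0 if s.assay == "RPF" else 0.0)
                    is_t.append(1.0 if s.treatment == "treated" else 0.0)
            X = np.column_stack([
                np.ones(len(y)), is_rpf, is_t,
                np.array(is_rpf) * np.array(is_t),
            ])
            fit = sm.GLM(
                np.array(y), X, offset=np.array(off),
                family=sm.families.NegativeBinomial(alpha=max(alpha, 1e-8)),
            ).fit()
            assert fit.params[3] / math.log(2) == pytest.approx(
                res.table.loc[gene, "log2fc"], abs=1e-4
            )
            assert fit.bse[3] / math.log(2) == pytest.approx(
                res.table.loc[gene, "se_log2"], rel=0.02
            )

    def test_invariant_to_swapping_replicates_within_condition(self):
        cfg = SimConfig(seed=14, n_genes=60)
        tx = generate_transcriptome(cfg)
        sim = simulate_counts(tx, cfg)
        res1 = delta_te_test(sim.rpf, sim.rna, (WT_T, WT_U))
        cols = sim.rpf.sample_names
        swapped = sim.rpf.counts[cols].copy()
        a, b = sim.rpf.columns_for(WT_U)
        swapped[[a, b]] = swapped[[b, a]].to_numpy()
        rpf2 = CountMatrix(swapped, sim.rpf.samples, "RPF")
        res2 = delta_te_test(rpf2, sim.rna, (WT_T, WT_U))
        pd.testing.assert_series_equal(res1.table["log2fc"],
                                       res2.table["log2fc"])

    def test_requires_two_replicates(self):
        s_rpf = make_samples("RPF", (WT_U, WT_T), n_reps=1)
        s_rna = make_samples("RNA", (WT_U, WT_T), n_reps=1)
        rpf = make_matrix([[10, 12]], ["g1"], s_rpf, "RPF")
        rna = make_matrix([[10, 11]], ["g1"], s_rna, "RNA")
        with pytest.raises(ValueError, match="replicates"):
            delta_te_test(rpf, rna, (WT_T, WT_U))

    def test_bh_qvalues_monotone_in_pvalue_rank(self):
        cfg = SimConfig(seed=15, n_genes=400)
        tx = generate_transcriptome(cfg)
        sim = simulate_counts(tx, cfg)
        t = delta_te_test(sim.rpf, sim.rna, (MUT_T, WT_T)).table
        t = t.sort_values("pvalue")
        assert (t["qvalue"].diff().dropna() >= -1e-12).all()


class TestCorrelation:
    def _result_series(self, values):
        return pd.Series(values, index=[f"g{i}" for i in range(len(values))])

    def test_self_correlation_is_one(self):
        a = self._result_series([0.5, -1.0, 2.0, 0.1])
        r, _ = correlate_delta_te(a, a)
        assert r == pytest.approx(1.0)

    def test_anti_correlation_is_minus_one(self):
        a = self._result_series([0.5, -1.0, 2.0, 0.1])
        r, _ = correlate_delta_te(a, -a)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        a = self._result_series([1.0, 1.0, 1.0])
        b = self._result_series([0.1, 0.5, 0.9])
        with pytest.raises(ValueError, match="variance"):
            correlate_delta_te(a, b)

    def test_recovers_closed_form_shared_effect_correlation(self):
        # x = e + n1, y = e + n2 with var_e/(var_e+var_n) = rho
        rng = np.random.default_rng(0)
        n = 1000
        var_e, var_n = 1.0, 0.25
        e = rng.normal(0, math.sqrt(var_e), n)
        x = self._result_series(e + rng.normal(0, math.sqrt(var_n), n))
        y = self._result_series(e + rng.normal(0, math.sqrt(var_n), n))
        rho = var_e / (var_e + var_n)
        r, p = correlate_delta_te(x, y)
        assert r == pytest.approx(rho, abs=0.05)
        assert p < 1e-10


class TestConditionalClassifier:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["c1", "c2", "c3", "c4"],
            index=[f"g{i}" for i in range(len(rows))],
        )

    def test_pattern_rule(self):
        delta = self._frame([
            (-1.0, -1.0, 0.0, 0.0),    # conditional by definition
            (-1.0, -1.0, -1.0, -1.0),  # reduced everywhere: not conditional
            (-1.0, -0.2, 0.0, 0.0),    # no reduction in contrast 2
            (-0.5, -0.5, -0.25, -0.25),  # boundary values all pass
            (0.0, 0.0, 0.0, 0.0),
        ])
        labels = classify_conditional_dependence(delta).labels
        assert labels["g0"] == "conditional"
        assert labels["g1"] == "other"
        assert labels["g2"] == "other"
        assert labels["g3"] == "conditional"
        assert labels["g4"] == "other"

    def test_missing_contrast_is_unclassifiable(self):
        delta = self._frame([(-1.0, np.nan, 0.0, 0.0)])
        labels = classify_conditional_dependence(delta).labels
        assert labels["g0"] == "unclassifiable"

    def test_cluster_order_is_deterministic_and_complete(self):
        rng = np.random.default_rng(1)
        delta = self._frame(rng.normal(size=(12, 4)))
        a = classify_conditional_dependence(delta)
        b = classify_conditional_dependence(delta.sample(frac=1, random_state=3))
        assert a.cluster_order == b.cluster_order
        assert sorted(a.cluster_order) == sorted(delta.index)
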