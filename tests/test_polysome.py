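"""Polysome-gradient estimator: the 2^-ΔCt arithmetic, each correction
factor's neutral case, the full-chain inverse property, and the
ΔTE ± SEM summary."""

import math

import numpy as np
import pandas as pd
import pytest

from ribotekit.polysome import (
    GradientFractions,
    ct_to_level,
    delta_te_with_sem,
    estimate_te,
    estimate_te_table,
    pm_ratio,
    recovery_factors,
    volume_corrections,
)
from ribotekit.simulate import CONDITIONS, GradientSimConfig, simulate_gradient


def _gradient(levels, multipliers, input_level=1.0, volumes=300.0,
              evol=25.0, a260=None, ct_18s=0.0):
    """Hand-built single gradient with unit corrections by default."""
    n = len(levels)
    frame = pd.DataFrame({
        "label": [f"f{i}" for i in range(n)],
        "multiplier": multipliers,
        "a260_area": a260 if a260 is not None else [1.0] * n,
        "volume_ul": [volumes] * n if np.isscalar(volumes) else volumes,
        "extraction_volume_ul": [evol] * n if np.isscalar(evol) else evol,
        "ct_18s": [ct_18s] * n,
        "ct:X": [-math.log2(max(l, 1e-300)) for l in levels],
    })
    return GradientFractions("g1", "WT", "untreated", 1, frame,
                             input_ct={"X": -math.log2(input_level)},
                             input_ref_ct=0.0)


class TestCtArithmetic:
    def test_delta_ct_zero_gives_unit_level(self):
        assert ct_to_level(5.0, 5.0) == pytest.approx(1.0)

    def test_delta_ct_three_gives_one_eighth(self):
        assert ct_to_level(8.0, 5.0) == pytest.approx(0.125)

    def test_forward_encoding_inverts_exactly(self):
        for level in (1e-6, 0.37, 1.0, 42.0):
            ct = -math.log2(level)
            assert ct_to_level(ct, 0.0) == pytest.approx(level, rel=1e-12)


class TestVolumeCorrections:
    def test_neutral_case(self):
        assert volume_corrections(300.0, 25.0) == pytest.approx(1.0)

    def test_double_volume_doubles_factor(self):
        assert volume_corrections(600.0, 25.0) == pytest.approx(2.0)

    def test_half_extraction_volume_doubles_factor(self):
        assert volume_corrections(300.0, 12.5) == pytest.approx(2.0)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            volume_corrections(0.0, 25.0)
        with pytest.raises(ValueError):
            volume_corrections(300.0, -1.0)


class TestRecoveryFactors:
    def test_matching_shares_give_unit_fraction_factors(self):
        # 18S shares identical to A260 shares -> all factors 1
        g = _gradient([0.1, 0.2, 0.3], [1, 2, 3], a260=[2.0, 3.0, 5.0])
        # encode 18S proportional to a260 with unit volume corrections
        g.fractions["ct_18s"] = [-math.log2(v) for v in (2.0, 3.0, 5.0)]
        frac, grad = recovery_factors(g)
        assert np.allclose(frac.to_numpy(), 1.0)
        assert grad == pytest.approx(1.0)

    def test_gradient_with_half_the_mean_polysomal_a260(self):
        g1 = _gradient([0.1], [1], a260=[2.0])
        g2 = _gradient([0.1], [1], a260=[6.0])
        _, f1 = recovery_factors(g1, [g1, g2])
        assert f1 == pytest.approx(2.0)  # (2+6)/2 / 2

    def test_zero_total_a260_rejected(self):
        g = _gradient([0.1], [1], a260=[0.0])
        with pytest.raises(ValueError, match="A260"):
            recovery_factors(g)


class TestEstimate:
    def test_mrna_only_in_2mer_pool(self):
        # all factors neutral, level L in the 2-mer pool, input I
        L, I = 0.3, 0.6
        g = _gradient([0.0, L, 0.0], [1, 2, 3], input_level=I)
        g.fractions["ct_18s"] = 0.0
        # make 18S shares equal a260 shares for unit recovery factors
        g.fractions["a260_area"] = 1.0
        te = estimate_te(g)
        assert te["X"] == pytest.approx(2 * L / I)

    def test_doubling_levels_and_input_leaves_te_unchanged(self):
        g1 = _gradient([0.1, 0.2, 0.05], [1, 2, 3], input_level=0.5)
        g2 = _gradient([0.2, 0.4, 0.1], [1, 2, 3], input_level=1.0)
        assert estimate_te(g1)["X"] == pytest.approx(estimate_te(g2)["X"])

    def test_zero_input_level_rejected(self):
        g = _gradient([0.1], [1], input_level=1.0)
        g.input_ct["X"] = float("inf")
        with pytest.raises(ValueError, match="input"):
            estimate_te(g)

    def test_multipliers_must_increase(self):
        with pytest.raises(ValueError, match="increase"):
            _gradient([0.1, 0.1], [2, 1])


class TestFullChainInverse:
    TE_TRUTH = {
        "X": {c: te for c, te in zip(CONDITIONS, (3.0, 2.4, 3.0, 1.2))},
        "ref": {c: 4.0 for c in CONDITIONS},
    }

    def test_noise_free_identity(self):
        grads = simulate_gradient(self.TE_TRUTH, GradientSimConfig(seed=0))
        table = estimate_te_table(grads)
        for _, row in table.iterrows():
            cond = (row["genotype"], row["treatment"])
            for tgt, m in self.TE_TRUTH.items():
                assert abs(row[tgt] - m[cond]) / m[cond] < 1e-9

    def test_te_zero_means_no_polysomal_signal(self):
        truth = {"X": {c: 0.0 for c in CONDITIONS}}
        grads = simulate_gradient(truth, GradientSimConfig(seed=1))
        table = estimate_te_table(grads)
        assert np.allclose(table["X"], 0.0, atol=1e-12)
        f = grads[0].fractions
        bound_levels = ct_to_level(
            f.loc[f["multiplier"] >= 1, "ct:X"], 0.0
        )
        assert np.all(bound_levels < 1e-200)  # all signal in unbound pool

    def test_distortions_are_inverted_exactly_without_noise(self):
        # extraction and loading losses but zero measurement noise:
        # the correction chain undoes them up to a per-gradient constant
        # that cancels in condition ratios
        cfg = GradientSimConfig(seed=2, extraction_loss_sd=0.2,
                                loading_loss_sd=0.2)
        grads = simulate_gradient(self.TE_TRUTH, cfg)
        table = estimate_te_table(grads)
        got = [
            row["X"] / row["ref"]
            for _, row in table.iterrows()
        ]
        want = [
            self.TE_TRUTH["X"][(row["genotype"], row["treatment"])] / 4.0
            for _, row in table.iterrows()
        ]
        assert np.allclose(got, want, rtol=1e-9)


class TestDeltaTE:
    def _table(self, wt_ratios, mut_ratios):
        rows = []
        for geno, ratios in (("WT", wt_ratios), ("mutant", mut_ratios)):
            for rep, r in enumerate(ratios, start=1):
                rows.append({"genotype": geno, "treatment": "untreated",
                             "replicate": rep, "X": 1.0})
                rows.append({"genotype": geno, "treatment": "treated",
                             "replicate": rep, "X": r})
        return pd.DataFrame(rows)

    def test_sem_of_1_2_3(self):
        out = delta_te_with_sem(self._table([1, 2, 3], [1, 2, 3]), "X")
        assert out.loc["WT", "mean_ratio"] == pytest.approx(2.0)
        assert out.loc["WT", "sem"] == pytest.approx(1 / math.sqrt(3))
        assert out.loc["WT", "sem"] == pytest.approx(0.5774, abs=1e-4)

    def test_constant_ratios_have_zero_sem(self):
        out = delta_te_with_sem(self._table([2, 2, 2], [2, 2, 2]), "X")
        assert out.loc["WT", "sem"] == 0.0
        # identical ratio sets in both genotypes: no difference
        assert out["welch_p"].iloc[0] == pytest.approx(1.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            delta_te_with_sem(self._table([2], [2]), "X")


class TestPMRatio:
    def test_simple_ratio(self):
        assert pm_ratio(2.0, 6.0) == pytest.approx(3.0)

    def test_zero_polysomes(self):
        assert pm_ratio(2.0, 0.0) == 0.0

    def test_zero_monosome_rejected(self):
        with pytest.raises(ValueError):
            pm_ratio(0.0, 5.0)

    def test_simulated_trace_areas_give_analytic_ratio(self):
        from scipy import stats as sps

        te = 2.0
        truth = {"X": {c: te for c in CONDITIONS}}
        cfg = GradientSimConfig(seed=3)
        grads = simulate_gradient(truth, cfg)
        f = grads[0].fractions
        mono = float(f.loc[f["multiplier"] == 1, "a260_area"].sum())
        poly = float(f.loc[f["multiplier"] >= 2, "a260_area"].sum())
        # analytic forward model: ribosomes per pool = rescaled bulk
        # profile plus the target's truncated-Poisson occupancy x k
        k = np.arange(1, cfg.max_ribosomes + 1)
        p = cfg.occupancy_profile(te)
        target = p * k
        bulk_w = sps.poisson.pmf(k, mu=3.0)
        bulk = bulk_w / bulk_w.sum() * (cfg.bulk_scale - target.sum())
        ribo = bulk + target
        want = ribo[k >= 2].sum() / ribo[k == 1].sum()
        assert pm_ratio(mono, poly) == pytest.approx(want, rel=1e-9)
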