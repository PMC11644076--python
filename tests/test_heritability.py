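"""ANOVA, Tukey letter groups and heritability: hand-computed mean
squares, expected-mean-squares algebra, and recovery of planted
variance components from simulated trials."""

import numpy as np
import pandas as pd
import pytest

from rhizoscreen.heritability import (
    _oneway_ms,
    estimate_heritability,
    factorial_anova,
    significance_stars,
    tukey_letters,
    variance_components,
)
from rhizoscreen.simulate import simulate_trait_panel


def long_table(values_by_group, treatment="C", trait="X"):
    rows = []
    for g, vals in values_by_group.items():
        for b, v in enumerate(vals, start=1):
            rows.append({"genotype": g, "treatment": treatment, "block": b,
                         "trait": trait, "value": v})
    return pd.DataFrame(rows)


class TestOneWayMeanSquares:
    def test_hand_anova(self):
        # groups {1,2} vs {3,4}: SS_between=4, SS_within=1, F=8
        ms_g, ms_e, k = _oneway_ms(np.array([1.0, 2.0, 3.0, 4.0]),
                                   np.array([1, 1, 2, 2]))
        assert ms_g == pytest.approx(4.0)
        assert ms_e == pytest.approx(0.5)
        assert ms_g / ms_e == pytest.approx(8.0)

    def test_constant_data_zero_between(self):
        ms_g, ms_e, _ = _oneway_ms(np.ones(6), np.array([1, 1, 2, 2, 3, 3]))
        assert ms_g == pytest.approx(0.0)
        assert ms_e == pytest.approx(0.0)


class TestVarianceComponents:
    def test_single_treatment_algebra(self):
        vd = variance_components(ms_g=10.0, ms_e=2.0, r=4)
        assert vd.v_g == pytest.approx(2.0)
        assert vd.heritability == pytest.approx(0.8)

    def test_equal_mean_squares_zero_heritability(self):
        vd = variance_components(ms_g=2.0, ms_e=2.0, r=4)
        assert vd.v_g == 0.0
        assert vd.heritability == 0.0

    def test_combined_mode_direct_evaluation(self):
        # components V_G=1, V_GE=1, V_e=1 with e=4, r=4 imply
        # MS_E=1, MS_GE=5, MS_G=21
        vd = variance_components(ms_g=21.0, ms_e=1.0, r=4, ms_ge=5.0, e=4)
        assert vd.v_g == pytest.approx(1.0)
        assert vd.v_ge == pytest.approx(1.0)
        assert vd.heritability_combined == pytest.approx(1 / (1 + 0.25 + 0.0625))
        assert vd.heritability_combined == pytest.approx(0.7619, abs=1e-4)

    def test_negative_estimates_truncated(self):
        vd = variance_components(ms_g=1.0, ms_e=5.0, r=4)
        assert vd.v_g == 0.0 and vd.truncated
        assert 0.0 <= vd.heritability <= 1.0

    def test_replication_required(self):
        with pytest.raises(ValueError, match="r must be >= 2"):
            variance_components(ms_g=1.0, ms_e=1.0, r=1)

    @pytest.mark.parametrize("ms_g, ms_e, ms_ge", [(3.0, 1.0, 2.0),
                                                   (0.5, 2.0, 1.0),
                                                   (10.0, 0.1, 5.0)])
    def test_heritability_bounded(self, ms_g, ms_e, ms_ge):
        vd = variance_components(ms_g, ms_e, r=3, ms_ge=ms_ge, e=4)
        assert 0.0 <= vd.heritability_combined <= 1.0


class TestFactorialAnova:
    def test_terms_present_and_ss_decomposition(self, small_traits):
        res = factorial_anova(small_traits, "RL")
        terms = set(res.table["term"])
        assert {"G", "P", "W", "G:P", "G:W", "P:W", "G:P:W", "block",
                "residual"} == terms
        df = small_traits[small_traits["trait"] == "RL"]
        total_ss = ((df["value"] - df["value"].mean()) ** 2).sum()
        assert res.table["ss"].sum() == pytest.approx(total_ss, rel=1e-6)
        n = len(df)
        assert res.table["df"].sum() == pytest.approx(n - 1)

    def test_genotype_signal_detected_without_treatment_effect(self):
        """Strong genotype variance, no treatment effect: the G term is
        significant and P/W are not, in nearly all simulations."""
        hits_g, ns_p, ns_w, n_sim = 0, 0, 0, 12
        for s in range(n_sim):
            panel = simulate_trait_panel(1, 10, n_blocks=3, var_g=0.5,
                                         var_e=0.05, seed=100 + s)
            res = factorial_anova(panel, "t0001")
            p = res.table.set_index("term")["p"]
            hits_g += p["G"] < 0.05
            ns_p += p["P"] > 0.05
            ns_w += p["W"] > 0.05
        assert hits_g == n_sim
        assert ns_p >= round(0.75 * n_sim)
        assert ns_w >= round(0.75 * n_sim)

    def test_unknown_treatment_code_rejected(self):
        df = long_table({1: [1, 2], 2: [3, 4]}, treatment="HP")
        with pytest.raises(ValueError, match="decomposition|levels"):
            factorial_anova(df, "X")

    def test_missing_trait_rejected(self, small_traits):
        with pytest.raises(ValueError, match="no data"):
            factorial_anova(small_traits, "NOPE")


class TestTukeyLetters:
    def test_indistinguishable_groups_share_a_letter(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(10, 1, 40)
        groups = np.repeat(["C", "D"], 20)
        out = tukey_letters(pd.DataFrame({"value": vals, "treatment": groups}))
        assert set(out["letters"]) == {"a"}

    def test_separated_groups_get_distinct_letters(self):
        vals = np.concatenate([np.random.default_rng(1).normal(0, 0.1, 10),
                               np.random.default_rng(2).normal(100, 0.1, 10)])
        groups = np.repeat(["lo", "hi"], 10)
        out = tukey_letters(pd.DataFrame({"value": vals, "treatment": groups}))
        by = out.set_index("treatment")["letters"]
        assert by["hi"] == "a" and by["lo"] == "b"

    def test_drought_alone_tops_letter_display(self):
        """Four treatments with one far above the rest: the high one is
        alone in letter class 'a' (the pattern drought shows for root
        length at study scale)."""
        rng = np.random.default_rng(5)
        means = {"C": 1290.0, "LP": 1390.0, "D": 1847.0, "DLP": 1242.0}
        rows = []
        for trt, mu in means.items():
            for v in rng.normal(mu, 60.0, 30):
                rows.append({"treatment": trt, "value": v})
        out = tukey_letters(pd.DataFrame(rows))
        by = out.set_index("treatment")["letters"]
        assert by["D"] == "a"
        assert all("a" not in by[t] for t in ("C", "LP", "DLP"))

    def test_zero_variance_everywhere_errors(self):
        df = pd.DataFrame({"value": [1.0, 1.0, 2.0, 2.0],
                           "treatment": ["C", "C", "D", "D"]})
        with pytest.raises(ValueError, match="zero within-group variance"):
            tukey_letters(df)


class TestHeritabilityEstimation:
    def test_single_treatment_recovery(self):
        panel = simulate_trait_panel(40, 60, treatments=("C",), n_blocks=4,
                                     var_g=2.0, var_e=2.0, seed=21)
        hs = [estimate_heritability(panel[panel["trait"] == t], t,
                                    treatment="C", log_scale=True).heritability
              for t in panel["trait"].unique()]
        assert abs(np.mean(hs) - 0.8) < 0.05
        assert all(0.0 <= h <= 1.0 for h in hs)

    def test_combined_not_above_single_with_interaction(self):
        panel = simulate_trait_panel(20, 50, n_blocks=4, var_g=1.0,
                                     var_gt=0.5, var_e=0.5, seed=33)
        for t in panel["trait"].unique()[:10]:
            sub = panel[panel["trait"] == t]
            h_single = estimate_heritability(sub, t, treatment="C",
                                             log_scale=True)
            h_com = estimate_heritability(sub, t, log_scale=True)
            # G x T variance discounts the combined estimate
            assert (h_com.heritability_combined
                    <= h_single.heritability + 0.15)

    def test_log_scale_requires_positive_values(self):
        df = long_table({1: [0.0, 1.0], 2: [2.0, 3.0]})
        with pytest.raises(ValueError, match="positive"):
            estimate_heritability(df, "X", treatment="C", log_scale=True)


def test_significance_star_classes():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0005) == "***"
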