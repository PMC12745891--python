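import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from motion4d.errors import DegenerateVarianceError
from motion4d.stats import (
    effect_sizes,
    games_howell,
    lmm_compare,
    significance_stars,
    welch_anova,
)


def make_table(groups: dict) -> pd.DataFrame:
    rows = [
        {"protocol": name, "displacement": v} for name, vals in groups.items() for v in vals
    ]
    return pd.DataFrame(rows)


def welch_oracle(groups):
    """Independent direct transcription of Welch's formulas (oracle)."""
    k = len(groups)
    n = np.array([len(g) for g in groups], float)
    m = np.array([np.mean(g) for g in groups])
    v = np.array([np.var(g, ddof=1) for g in groups])
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    A = np.sum(w * (m - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
    F = A / (1 + 2 * (k - 2) / (k * k - 1) * lam)
    df2 = (k * k - 1) / (3 * lam)
    return F, k - 1, df2


class TestWelchAnova:
    def test_matches_direct_formula_on_three_groups(self):
        groups = {"a": [1.0, 2, 3], "b": [2.0, 3, 4], "c": [5.0, 6, 7]}
        res = welch_anova(make_table(groups), "protocol")
        F, df1, df2 = welch_oracle(list(groups.values()))
        assert res.F == pytest.approx(F, abs=1e-10)
        assert res.df1 == df1
        assert res.df2 == pytest.approx(df2, abs=1e-10)

    def test_reduces_to_classical_anova_under_equal_variances(self):
        # limiting case: for two groups of equal size and equal variance the
        # Welch correction term vanishes and F coincides with classical ANOVA
        base = np.array([0.3, -1.2, 0.9, 1.4, -0.8, 0.1, 2.0, -0.7])
        groups = {"a": base, "b": base + 1.0}
        res = welch_anova(make_table(groups), "protocol")
        F_classic, _ = sps.f_oneway(*groups.values())
        assert res.F == pytest.approx(F_classic, abs=1e-8)

    def test_equal_means_give_near_zero_f(self):
        rng = np.random.default_rng(0)
        vals = np.array([2.0, 2, 2, 2])
        groups = {"a": vals + 1e-9 * rng.standard_normal(4), "b": vals + 1e-9 * rng.standard_normal(4)}
        res = welch_anova(make_table(groups), "protocol")
        assert res.F < 10  # jitter-dominated, no systematic separation
        assert res.p > 0.01

    def test_null_distribution_not_significant(self):
        rng = np.random.default_rng(1)
        groups = {"a": rng.normal(0, 1, 50), "b": rng.normal(0, 1, 50)}
        assert welch_anova(make_table(groups), "protocol").p > 0.01

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        table = make_table(
            {
                "a": rng.normal(0, 1, 12),
                "b": rng.normal(0.8, 2, 9),
                "c": rng.normal(-0.5, 0.5, 15),
            }
        )
        ours = welch_anova(table, "protocol")
        ref = pingouin.welch_anova(table, dv="displacement", between="protocol")
        assert ours.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert ours.df2 == pytest.approx(float(ref["ddof2"].iloc[0]), rel=1e-9)
        assert ours.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_zero_variance_group_rejected(self):
        table = make_table({"a": [1.0, 1.0, 1.0], "b": [2.0, 3.0, 4.0]})
        with pytest.raises(DegenerateVarianceError):
            welch_anova(table, "protocol")


class TestGamesHowell:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 20)
        table = make_table({"a": base, "b": base.copy()})
        gh = games_howell(table, "protocol")
        assert gh["p_adj"].iloc[0] > 0.99

    def test_large_shift_detected(self):
        rng = np.random.default_rng(3)
        table = make_table({"a": rng.normal(0, 1, 20), "b": rng.normal(5, 1, 20)})
        gh = games_howell(table, "protocol")
        assert gh["p_adj"].iloc[0] < 0.001
        assert gh["stars"].iloc[0] == "***"

    def test_mean_diff_antisymmetric(self):
        rng = np.random.default_rng(4)
        groups = {
            "a": rng.normal(0, 1, 10),
            "b": rng.normal(1, 2, 10),
            "c": rng.normal(2, 1, 10),
        }
        gh = games_howell(make_table(groups), "protocol")
        for _, row in gh.iterrows():
            assert row["mean_diff"] == pytest.approx(
                np.mean(groups[row["A"]]) - np.mean(groups[row["B"]]), abs=1e-12
            )

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        table = make_table(
            {
                "a": rng.normal(0, 1, 10),
                "b": rng.normal(1.0, 2, 14),
                "c": rng.normal(0.5, 0.7, 8),
            }
        )
        ours = games_howell(table, "protocol").set_index(["A", "B"])
        ref = pingouin.pairwise_gameshowell(table, dv="displacement", between="protocol")
        for _, r in ref.iterrows():
            mine = ours.loc[(r["A"], r["B"])]
            assert mine["mean_diff"] == pytest.approx(float(r["diff"]), abs=1e-9)
            assert mine["p_adj"] == pytest.approx(float(r["pval"]), abs=1e-6)


class TestEffectSizes:
    def test_closed_form_pairs(self):
        assert effect_sizes(0.2).cohens_f == pytest.approx(0.5, abs=1e-12)
        assert effect_sizes(0.0).cohens_f == 0.0
        # the conventional large-effect thresholds are mutually consistent
        assert effect_sizes(0.14).cohens_f == pytest.approx(0.4034, abs=5e-4)

    def test_invalid_eta_squared_rejected(self):
        with pytest.raises(ValueError):
            effect_sizes(1.0)
        with pytest.raises(ValueError):
            effect_sizes(-0.1)

    def test_stars_convention(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.2) == ""


def synthetic_lmm_table(
    offsets={"MR_coronal_10bin": 0.0, "MR_axial_5bin": -1.7, "CT": -0.9},
    n_waveforms=9,
    replicates=5,
    waveform_sd=1.0,
    residual_sd=0.5,
    seed=0,
):
    """Protocol-offset recovery design shaped like the patient-waveform
    study: per-waveform random level plus protocol fixed effects."""
    rng = np.random.default_rng(seed)
    rows = []
    for w in range(n_waveforms):
        level = 10.0 + waveform_sd * rng.standard_normal()
        for protocol, off in offsets.items():
            for r in range(replicates):
                rows.append(
                    {
                        "protocol": protocol,
                        "waveform_id": f"wf{w}",
                        "ground_truth_pp": 11.0,
                        "displacement": level + off + residual_sd * rng.standard_normal(),
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows)


class TestLmmCompare:
    def test_recovers_injected_protocol_offsets(self):
        table = synthetic_lmm_table(seed=11)
        res = lmm_compare(table, "MR_coronal_10bin", include_waveform_mean=False)
        assert res.converged
        t = res.table.set_index("condition")
        for cond, truth in (("MR_axial_5bin", -1.7), ("CT", -0.9)):
            est, se = t.loc[cond, "estimate"], t.loc[cond, "se"]
            assert abs(est - truth) < 2 * se

    def test_zero_offsets_cis_cover_zero(self):
        table = synthetic_lmm_table(
            offsets={"MR_coronal_10bin": 0.0, "MR_axial_5bin": 0.0, "CT": 0.0}, seed=12
        )
        res = lmm_compare(table, "MR_coronal_10bin", include_waveform_mean=False)
        for _, row in res.table.iterrows():
            assert row["ci_low"] <= 0 <= row["ci_high"]

    def test_ci_is_wald_interval(self):
        table = synthetic_lmm_table(seed=13)
        res = lmm_compare(table, "MR_coronal_10bin", include_waveform_mean=False)
        for _, row in res.table.iterrows():
            assert row["ci_low"] == pytest.approx(row["estimate"] - 1.96 * row["se"], abs=1e-6)
            assert row["ci_high"] == pytest.approx(row["estimate"] + 1.96 * row["se"], abs=1e-6)

    def test_waveform_mean_contrast_reports_reference_bias(self):
        # reference protocol sits ~1 mm below the programmed amplitude
        table = synthetic_lmm_table(seed=14)
        table["ground_truth_pp"] = 11.0
        res = lmm_compare(table, "MR_coronal_10bin", include_waveform_mean=True)
        t = res.table.set_index("condition")
        assert "waveform_mean" in t.index
        assert t.loc["waveform_mean", "estimate"] == pytest.approx(1.0, abs=0.8)

    def test_missing_reference_rejected(self):
        table = synthetic_lmm_table()
        with pytest.raises(ValueError):
            lmm_compare(table, "nope")
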