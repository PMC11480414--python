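"""Inferential layer: mixed model, rm-ANOVA vs sums-of-squares oracle,
effect sizes, transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from periphoton.stats import (
    cohens_d,
    fit_auc_lmm,
    log_transform_vigilance,
    rm_anova,
    two_way_anova_planned,
    variance_diagnostics,
)
from periphoton.synth import SessionDesign, generate_auc_table


def rm_anova_oracle(y: np.ndarray):
    """Brute-force two-within-factor rm-ANOVA F statistics.

    ``y`` has shape (subjects, levels_A, levels_B), one observation per cell.
    Returns (F_A, F_B, F_AB) using within-subject error terms, computed from
    first-principles sums of squares, independent of statsmodels.
    """
    S, A, B = y.shape
    g = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)
    ss_a = S * B * np.sum((m_a - g) ** 2)
    ss_as = B * np.sum((m_sa - m_s[:, None] - m_a[None, :] + g) ** 2)
    ss_b = S * A * np.sum((m_b - g) ** 2)
    ss_bs = A * np.sum((m_sb - m_s[:, None] - m_b[None, :] + g) ** 2)
    ss_ab = S * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
    resid = (y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :] - g)
    ss_abs = np.sum(resid ** 2)
    f_a = (ss_a / (A - 1)) / (ss_as / ((A - 1) * (S - 1)))
    f_b = (ss_b / (B - 1)) / (ss_bs / ((B - 1) * (S - 1)))
    f_ab = (ss_ab / ((A - 1) * (B - 1))) / (ss_abs / ((A - 1) * (B - 1) * (S - 1)))
    return f_a, f_b, f_ab


def table_from_cube(y: np.ndarray) -> pd.DataFrame:
    S, A, B = y.shape
    stress = ["pre", "post"][:A]
    social = ["non-aggressive", "aggressive"][:B]
    rows = []
    for s in range(S):
        for a in range(A):
            for b in range(B):
                rows.append({"mouse": f"m{s}", "stress": stress[a],
                             "social": social[b], "auc": y[s, a, b]})
    return pd.DataFrame(rows)


class TestLmm:
    def test_all_zero_response_gives_null_coefficients(self):
        design = SessionDesign(mice=("a", "b", "c"), events_per_label=4,
                               noise_sd=0.0, random_intercept_sd=0.0)
        tab = generate_auc_table(design, seed=0)
        tab["auc"] = 0.0
        # degenerate zero-variance data: add hair-thin noise so the
        # likelihood is defined, coefficients must stay ~0
        rng = np.random.default_rng(0)
        tab["auc"] += 1e-8 * rng.standard_normal(len(tab))
        res = fit_auc_lmm(tab)
        assert np.all(np.abs(res.terms["beta"]) < 1e-6)

    def test_recovers_injected_after_effect(self):
        design = SessionDesign(true_lmm_effects={"timepoint[after]": 3.0})
        tab = generate_auc_table(design, seed=7)
        res = fit_auc_lmm(tab)
        row = res.term("timepoint[after]")
        assert abs(row["beta"] - 3.0) <= 2 * row["se"]
        assert res.n_groups == 7
        assert res.n_obs == len(tab)

    def test_duplicating_rows_keeps_beta_shrinks_se(self):
        design = SessionDesign(mice=("a", "b", "c", "d"), events_per_label=5,
                               true_lmm_effects={"timepoint[after]": 2.0})
        tab = generate_auc_table(design, seed=3)
        res1 = fit_auc_lmm(tab)
        res2 = fit_auc_lmm(pd.concat([tab, tab], ignore_index=True))
        b1 = res1.term("timepoint[after]")
        b2 = res2.term("timepoint[after]")
        assert b2["beta"] == pytest.approx(b1["beta"], rel=1e-4)
        assert b2["se"] < b1["se"]

    def test_requires_two_mice_and_full_factors(self):
        design = SessionDesign(mice=("a",), events_per_label=2)
        tab = generate_auc_table(design, seed=0)
        with pytest.raises(ValueError, match="2 mice"):
            fit_auc_lmm(tab)
        design2 = SessionDesign(mice=("a", "b"), events_per_label=2)
        tab2 = generate_auc_table(design2, seed=0)
        with pytest.raises(ValueError, match="stress"):
            fit_auc_lmm(tab2[tab2.stress == "pre"])


class TestRmAnova:
    def test_identical_response_f_near_zero(self):
        y = np.tile(np.array([3.0, 4.0, 5.0, 6.0])[:, None, None], (1, 2, 2))
        tab = rm_anova(table_from_cube(y), dv="auc")
        assert np.all(np.nan_to_num(tab["F"].to_numpy()) < 1e-10)

    def test_pure_stress_effect_zero_noise(self):
        y = np.zeros((4, 2, 2))
        y[:, 1, :] = 2.0  # additive stress effect, no interaction
        y += np.arange(4)[:, None, None]  # subject offsets
        # tiny jitter keeps the error strata nonzero
        rng = np.random.default_rng(5)
        y += 1e-6 * rng.standard_normal(y.shape)
        tab = rm_anova(table_from_cube(y), dv="auc")
        assert tab.loc["stress", "F"] > 1e8
        assert tab.loc["stress x social", "F"] < 10.0

    def test_matches_hand_computed_toy_table(self):
        # 4-mouse toy fixture; expected F values frozen from the
        # sums-of-squares oracle computed by hand
        y = np.array([
            [[1.0, 2.0], [4.0, 5.0]],
            [[0.5, 1.5], [3.5, 6.0]],
            [[1.2, 1.8], [4.2, 5.5]],
            [[0.8, 2.2], [3.8, 5.8]],
        ])
        tab = rm_anova(table_from_cube(y), dv="auc")
        assert tab.loc["stress", "F"] == pytest.approx(472.52631578947353, rel=1e-8)
        assert tab.loc["social", "F"] == pytest.approx(38.707964601769895, rel=1e-8)
        assert tab.loc["stress x social", "F"] == pytest.approx(
            5.157894736842109, rel=1e-8)

    def test_agrees_with_oracle_on_random_tables(self, rng):
        for _ in range(5):
            y = rng.normal(size=(6, 2, 2)) + rng.normal(size=(6, 1, 1))
            f_a, f_b, f_ab = rm_anova_oracle(y)
            tab = rm_anova(table_from_cube(y), dv="auc")
            assert tab.loc["stress", "F"] == pytest.approx(f_a, rel=1e-8)
            assert tab.loc["social", "F"] == pytest.approx(f_b, rel=1e-8)
            assert tab.loc["stress x social", "F"] == pytest.approx(f_ab, rel=1e-8)

    def test_missing_cell_named(self):
        y = np.zeros((3, 2, 2))
        tab = table_from_cube(y)
        tab = tab[~((tab.mouse == "m1") & (tab.stress == "post")
                    & (tab.social == "aggressive"))]
        with pytest.raises(ValueError, match="m1.*post.*aggressive"):
            rm_anova(tab, dv="auc")


class TestCohensD:
    def test_unit_difference_unit_sd(self):
        a = np.array([0.0, 1.0, 2.0]) + 1.0
        b = np.array([0.0, 1.0, 2.0])
        assert cohens_d(a, b).d == pytest.approx(1.0)

    def test_identical_groups_zero(self):
        g = np.array([1.0, 2.0, 3.0])
        assert cohens_d(g, g).d == 0.0

    def test_antisymmetry(self, rng):
        a, b = rng.normal(1, 1, 20), rng.normal(0, 1, 20)
        assert cohens_d(a, b).d == pytest.approx(-cohens_d(b, a).d)

    @given(st.floats(0.1, 100), st.integers(0, 3))
    def test_invariant_to_common_rescaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(1, 1, 15), rng.normal(0, 2, 12)
        d0 = cohens_d(a, b).d
        d1 = cohens_d(scale * a, scale * b).d
        assert d1 == pytest.approx(d0, rel=1e-9)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestLogTransform:
    def test_zero_maps_to_zero_and_em1_to_one(self):
        out = log_transform_vigilance([0.0, np.e - 1.0])
        assert out[0] == 0.0
        assert out[1] == pytest.approx(1.0)

    def test_monotone(self, rng):
        v = np.sort(rng.uniform(0, 100, 50))
        out = log_transform_vigilance(v)
        assert np.all(np.diff(out) >= 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            log_transform_vigilance([-0.1])


class TestTwoWayAnovaPlanned:
    def test_omnibus_and_planned_contrasts(self, rng):
        rows = []
        for sex in ("female", "male"):
            for trt in ("saline", "hcrt1"):
                shift = 3.0 if (sex == "female" and trt == "hcrt1") else 0.0
                for _ in range(8):
                    rows.append({"sex": sex, "treatment": trt,
                                 "approach": rng.normal(10.0 - shift, 1.0)})
        tab = pd.DataFrame(rows)
        out = two_way_anova_planned(
            tab, dv="approach",
            planned=[({"sex": "female", "treatment": "saline"},
                      {"sex": "female", "treatment": "hcrt1"})])
        assert out["omnibus"].loc["C(sex):C(treatment)", "PR(>F)"] < 0.01
        comp = out["planned"][0]
        assert comp["p"] < 0.01 and comp["d"] > 1.0

    def test_variance_diagnostics_emitted(self, rng):
        out = variance_diagnostics(rng.normal(0, 1, 30), rng.normal(0, 5, 30))
        assert 0.0 <= out["fligner_p"] <= 1.0
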