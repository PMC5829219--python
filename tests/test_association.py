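"""Contingency statistics, logistic layer, diagnostics and bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from candgene.association import (
    GenotypeCounts,
    LogisticModel,
    Table2x2,
    bootstrap_adjust,
    carrier_burden,
    collapse,
    hosmer_lemeshow,
    hwe_chi2,
    interaction_test,
    logistic_fit,
    nagelkerke_r2,
    odds_ratio_woolf,
    pearson_chi2,
    score_test,
    severity_classes,
    stepwise_forward_wald,
)

PNPLA3 = GenotypeCounts((92, 91, 35), (123, 56, 48))
GCKR = GenotypeCounts((43, 90, 85), (49, 123, 55))


# ------------------------------------------------------------------ HWE

def test_hwe_exact_equilibrium_is_zero():
    assert hwe_chi2((25, 50, 25)) == (0.0, 1.0)


def test_hwe_complete_heterozygote_deficit():
    chi2, p = hwe_chi2((100, 0, 100))
    assert chi2 == pytest.approx(200.0)
    assert p < 1e-20


def test_hwe_flags_deviating_control_sample():
    # published control genotype counts for the PNPLA3 index SNP;
    # allele frequency 152/454 = 0.335
    chi2, p = hwe_chi2((123, 56, 48))
    assert chi2 > 3.84 and p < 0.05


def test_hwe_monomorphic_returns_null():
    assert hwe_chi2((50, 0, 0)) == (0.0, 1.0)


# ------------------------------------------------------------- collapse

def test_dominant_collapse_matches_published_carrier_rows():
    t = collapse(PNPLA3, "dominant")
    assert (t.a, t.b, t.c, t.d) == (126, 92, 104, 123)


def test_recessive_collapse_matches_published_homozygote_rows():
    t = collapse(GCKR, "recessive")
    assert (t.a, t.b, t.c, t.d) == (85, 133, 55, 172)


def test_collapse_models_coincide_without_heterozygotes():
    gc = GenotypeCounts((30, 0, 10), (35, 0, 5))
    assert collapse(gc, "dominant") == collapse(gc, "recessive")


# -------------------------------------------------------------- Pearson

def test_pearson_2x2_reproduces_published_statistics():
    chi2, df, p = pearson_chi2(Table2x2(126, 92, 104, 123))
    assert df == 1
    assert round(chi2, 2) == 6.39 and p < 0.05
    chi2, _, _ = pearson_chi2(Table2x2(85, 133, 55, 172))
    assert round(chi2, 1) == 11.2


def test_pearson_zero_for_proportional_rows():
    chi2, _, p = pearson_chi2(Table2x2(40, 60, 20, 30))
    assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)


def test_pearson_zero_margin_is_error():
    with pytest.raises(ValueError):
        pearson_chi2(np.array([[0, 10], [0, 20]]))


@given(st.lists(st.integers(min_value=1, max_value=400), min_size=4,
                max_size=4))
def test_pearson_equals_2x2_shortcut_formula(cells):
    a, b, c, d = cells
    chi2, _, _ = pearson_chi2(Table2x2(a, b, c, d))
    n = a + b + c + d
    shortcut = n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    assert chi2 == pytest.approx(shortcut, rel=1e-9)


@given(st.lists(st.integers(min_value=1, max_value=200), min_size=6,
                max_size=6))
def test_genotypic_chi2_is_sum_of_cell_contributions(cells):
    table = np.array(cells, dtype=float).reshape(2, 3)
    chi2, df, _ = pearson_chi2(table)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    contributions = (table - expected) ** 2 / expected
    assert df == 2
    assert chi2 == pytest.approx(float(contributions.sum()), rel=1e-9)


def test_pearson_invariant_under_row_and_column_permutation():
    t = np.array([[30, 50, 20], [45, 25, 30]], dtype=float)
    base = pearson_chi2(t)[0]
    assert pearson_chi2(t[::-1])[0] == pytest.approx(base)
    assert pearson_chi2(t[:, ::-1])[0] == pytest.approx(base)


# ---------------------------------------------------------------- Woolf

def test_woolf_interval_reproduces_published_cis():
    orci = odds_ratio_woolf(Table2x2(126, 92, 104, 123))
    assert orci.or_point == pytest.approx(1.62, abs=0.005)
    assert orci.ci_low == pytest.approx(1.11, abs=0.005)
    assert orci.ci_high == pytest.approx(2.36, abs=0.005)
    orci = odds_ratio_woolf(Table2x2(85, 133, 55, 172))
    assert orci.or_point == pytest.approx(2.00, abs=0.005)
    assert orci.ci_low == pytest.approx(1.33, abs=0.005)
    assert round(orci.ci_high, 2) == 3.00


def test_or_is_unity_for_proportional_table():
    orci = odds_ratio_woolf(Table2x2(40, 60, 20, 30))
    assert orci.or_point == pytest.approx(1.0)


@given(st.lists(st.integers(min_value=1, max_value=300), min_size=4,
                max_size=4))
def test_woolf_group_transpose_gives_reciprocal(cells):
    a, b, c, d = cells
    fwd = odds_ratio_woolf(Table2x2(a, b, c, d))
    rev = odds_ratio_woolf(Table2x2(c, d, a, b))
    assert rev.or_point == pytest.approx(1 / fwd.or_point, rel=1e-9)
    assert rev.ci_low == pytest.approx(1 / fwd.ci_high, rel=1e-9)
    assert rev.ci_high == pytest.approx(1 / fwd.ci_low, rel=1e-9)


def test_zero_cell_handling():
    corrected = odds_ratio_woolf(Table2x2(0, 50, 10, 40))
    assert corrected.corrected and np.isfinite(corrected.or_point)
    na = odds_ratio_woolf(Table2x2(0, 50, 10, 40), zero_policy="na")
    assert not na.estimable and np.isnan(na.or_point)


# ------------------------------------------------------- carrier burden

def test_equal_carrier_fractions_give_unit_or():
    rng = np.random.default_rng(0)
    status = np.array(["case"] * 500 + ["control"] * 500)
    flags = rng.random(1000) < 0.3
    _, res = carrier_burden(flags, status)
    assert res.or_point == pytest.approx(1.0, abs=0.35)
    assert res.p > 0.01


def test_enriched_gene_matches_published_burden_analysis():
    """~14% of 218 cases vs ~8% of 227 controls carrying a variant gives
    OR ~= 2 (the reported gene-burden signal, matched to 1 dp)."""
    flags = np.r_[np.ones(31), np.zeros(187), np.ones(17), np.zeros(210)]
    status = np.array(["case"] * 218 + ["control"] * 227)
    table, res = carrier_burden(flags.astype(bool), status)
    assert (table.a, table.c) == (31, 17)
    assert round(res.or_point, 1) == 2.0
    assert res.p < 0.05


def test_no_carriers_flagged_non_estimable():
    status = np.array(["case"] * 10 + ["control"] * 10)
    _, res = carrier_burden(np.zeros(20, dtype=bool), status)
    assert not res.estimable


def test_permuted_burden_chi2_follows_null():
    rng = np.random.default_rng(42)
    flags = rng.random(400) < 0.25
    status = np.array(["case"] * 200 + ["control"] * 200)
    stats_null = []
    for _ in range(400):
        perm = rng.permutation(status)
        _, res = carrier_burden(flags, perm)
        stats_null.append(res.statistic)
    stats_null = np.asarray(stats_null)
    assert stats_null.mean() == pytest.approx(1.0, abs=0.25)
    assert (stats_null > stats.chi2.isf(0.05, 1)).mean() < 0.10


# ------------------------------------------------------------- logistic

def test_intercept_only_fit_recovers_logit_of_case_fraction():
    y = np.r_[np.ones(30), np.zeros(70)]
    model = logistic_fit(pd.DataFrame(index=range(100)), y)
    assert model.params["const"] == pytest.approx(np.log(30 / 70), abs=1e-6)
    assert model.ll_fitted == pytest.approx(model.ll_null, abs=1e-8)


def test_score_equations_hold_at_convergence(regression_design):
    X, y = regression_design
    model = logistic_fit(X, y)
    assert model.converged
    residual = model.exog.to_numpy().T @ (model.y - model.fitted_probs)
    assert np.max(np.abs(residual)) < 1e-5
    assert model.ll_fitted >= model.ll_null


def test_separation_is_flagged_not_silent():
    x = np.r_[np.zeros(20), np.ones(20)]
    y = x.copy()
    model = logistic_fit(pd.DataFrame({"x": x}), y)
    assert not model.converged


def test_rank_deficient_design_rejected():
    X = pd.DataFrame({"a": [0, 1, 2, 1.0], "b": [0, 2, 4, 2.0]})
    with pytest.raises(ValueError, match="rank"):
        logistic_fit(X, [0, 1, 1, 0])


def test_known_coefficients_recovered_within_2_se(regression_design):
    X, y = regression_design
    model = logistic_fit(X, y)
    generative = {
        "rs738409": np.log(2.0), "rs58542926": np.log(2.5),
        "rs1260326": np.log(1.5), "rs641738": np.log(1.4),
        "age": 0.02, "sex_m": 0.20, "bmi": 0.19,
        "log_homa": 0.80, "log_tg": 0.60,
    }
    for term, beta in generative.items():
        z = abs(model.params[term] - beta) / model.bse[term]
        assert z < 2.0, f"{term}: |z| = {z:.2f}"


# ------------------------------------------------------------- stepwise

def test_score_test_agrees_with_wald_for_strong_effect():
    rng = np.random.default_rng(1)
    x = rng.normal(size=800)
    y = (rng.random(800) < 1 / (1 + np.exp(-x))).astype(int)
    null = logistic_fit(pd.DataFrame(index=range(800)), y)
    chi2, p = score_test(null, x)
    full = logistic_fit(pd.DataFrame({"x": x}), y)
    assert p < 1e-6
    # score and Wald statistics diverge for strong effects; same order
    assert chi2 == pytest.approx(float(full.wald_chi2["x"]), rel=0.3)


def test_stepwise_selects_strong_predictor_first():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.normal(size=(1500, 5)),
                     columns=[f"x{i}" for i in range(5)])
    eta = 1.2 * X["x0"].to_numpy()
    y = (rng.random(1500) < 1 / (1 + np.exp(-eta))).astype(int)
    result = stepwise_forward_wald(X, y)
    assert result.trace[0]["term"] == "x0"


def test_stepwise_degenerate_threshold_enters_all_by_strength():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(1200, 3)), columns=["a", "b", "c"])
    eta = 1.5 * X["a"].to_numpy() + 0.5 * X["b"].to_numpy()
    y = (rng.random(1200) < 1 / (1 + np.exp(-eta))).astype(int)
    result = stepwise_forward_wald(X, y, entry_p=1.0, removal_p=1.0)
    assert set(result.selected) == {"a", "b", "c"}
    assert [t["term"] for t in result.trace[:2]] == ["a", "b"]


def test_stepwise_null_selection_is_rare():
    """A single unassociated candidate enters in about entry_p of runs."""
    rng = np.random.default_rng(4)
    entered = 0
    runs = 300
    for _ in range(runs):
        x = rng.normal(size=250)
        y = (rng.random(250) < 0.4).astype(int)
        res = stepwise_forward_wald(pd.DataFrame({"x": x}), y)
        entered += bool(res.selected)
    assert entered / runs <= 0.09  # ~5% expected; >=94% empty allowing noise


# ---------------------------------------------------------- diagnostics

def test_hosmer_lemeshow_two_groups_non_informative(regression_design):
    X, y = regression_design
    model = logistic_fit(X[["bmi"]], y)
    res = hosmer_lemeshow(model, groups=2)
    assert res.df == 0 and not res.informative


def test_hosmer_lemeshow_calibrated_model_not_rejected(regression_design):
    X, y = regression_design
    model = logistic_fit(X, y)
    res = hosmer_lemeshow(model)
    assert res.groups_used == 10 and res.df == 8
    assert res.p > 0.001


def test_hosmer_lemeshow_p_roughly_uniform_under_correct_model():
    rng = np.random.default_rng(5)
    pvals = []
    for _ in range(120):
        x = rng.normal(size=400)
        y = (rng.random(400) < 1 / (1 + np.exp(-0.8 * x))).astype(int)
        model = logistic_fit(pd.DataFrame({"x": x}), y)
        res = hosmer_lemeshow(model)
        pvals.append(res.p)
    pvals = np.asarray(pvals)
    assert 0.25 < pvals.mean() < 0.75
    assert (pvals < 0.05).mean() < 0.15


def test_nagelkerke_zero_when_model_adds_nothing():
    model = logistic_fit(pd.DataFrame(index=range(50)),
                         np.r_[np.ones(20), np.zeros(30)])
    assert nagelkerke_r2(model) == pytest.approx(0.0, abs=1e-6)


def test_nagelkerke_hand_computed_small_example():
    # n=4, balanced outcome: ll_null = 4*ln(1/2); take ll_fitted = -1.0
    ll_null = 4 * np.log(0.5)
    ll_fit = -1.0
    model = LogisticModel(
        params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
        wald_chi2=pd.Series(dtype=float), pvalues=pd.Series(dtype=float),
        ll_null=ll_null, ll_fitted=ll_fit, n=4, converged=True,
        fitted_probs=np.zeros(4), y=np.zeros(4), exog=pd.DataFrame(),
    )
    r2_cs = 1 - np.exp(2 * (ll_null - ll_fit) / 4)
    expected = r2_cs / (1 - np.exp(2 * ll_null / 4))
    assert nagelkerke_r2(model) == pytest.approx(expected, rel=1e-12)


def test_nagelkerke_reaches_one_in_perfect_fit_limit():
    model = LogisticModel(
        params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
        wald_chi2=pd.Series(dtype=float), pvalues=pd.Series(dtype=float),
        ll_null=100 * np.log(0.5), ll_fitted=0.0, n=100, converged=True,
        fitted_probs=np.zeros(100), y=np.zeros(100), exog=pd.DataFrame(),
    )
    assert nagelkerke_r2(model) == pytest.approx(1.0)


# ------------------------------------------------------------ bootstrap

def test_bootstrap_is_seed_reproducible(regression_design):
    X, y = regression_design
    cols = X[["rs738409", "bmi"]]
    a = bootstrap_adjust(cols, y, B=150, seed=9)
    b = bootstrap_adjust(cols, y, B=150, seed=9)
    pd.testing.assert_frame_equal(a, b)
    c = bootstrap_adjust(cols, y, B=150, seed=10)
    assert not a["or_ci_low"].equals(c["or_ci_low"])


def test_bootstrap_strong_effect_stays_significant(regression_design):
    X, y = regression_design
    res = bootstrap_adjust(X[["rs738409", "bmi", "log_homa"]], y,
                           B=200, seed=1)
    assert res.loc["rs738409", "p_adj"] < 0.05
    assert res.loc["rs738409", "or_ci_low"] > 1.0


def test_bootstrap_requires_minimum_replicates(regression_design):
    X, y = regression_design
    with pytest.raises(ValueError):
        bootstrap_adjust(X[["bmi"]], y, B=50)


# ---------------------------------------------------------- interaction

def test_interaction_sign_recovered():
    rng = np.random.default_rng(7)
    n = 3000
    snp = rng.binomial(1, 0.4, size=n).astype(float)
    z = rng.normal(size=n)
    eta = 0.8 * snp + 0.5 * z - 0.7 * snp * z
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    X = pd.DataFrame({"snp": snp, "z": z})
    res, _ = interaction_test(X, y, "snp", "z")
    assert res.or_point < 1.0 and res.p < 0.01
    assert res.ci_high < 1.0


def test_interaction_null_type_one_error_near_alpha():
    rng = np.random.default_rng(8)
    hits = 0
    runs = 200
    for _ in range(runs):
        snp = rng.binomial(1, 0.4, size=300).astype(float)
        z = rng.normal(size=300)
        eta = 0.6 * snp + 0.4 * z
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(int)
        res, _ = interaction_test(pd.DataFrame({"snp": snp, "z": z}),
                                  y, "snp", "z")
        hits += res.p < 0.05
    assert 0.01 <= hits / runs <= 0.10


def test_self_interaction_is_aliased():
    snp = np.r_[np.zeros(50), np.ones(50)]
    y = np.r_[np.zeros(40), np.ones(60)]
    with pytest.raises(ValueError, match="aliased"):
        interaction_test(pd.DataFrame({"snp": snp}), y, "snp", "snp")


# ------------------------------------------------------------- severity

@pytest.mark.parametrize(
    "grade, label, severe",
    [(0, "absent", False), (1, "mild", False), (2, "mild", False),
     (3, "moderate", False), (4, "moderate", False), (5, "severe", True),
     (6, "severe", True)],
)
def test_severity_classes(grade, label, severe):
    assert severity_classes(grade) == (label, severe)


def test_out_of_range_grade_rejected():
    with pytest.raises(ValueError):
        severity_classes(7)
    with pytest.raises(ValueError):
        severity_classes(-1)
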