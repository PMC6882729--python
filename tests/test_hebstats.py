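"""Nested likelihood-ratio test: MLEs, LRT identities, BH, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import xlogy

from octoscope.hebstats import (
    bh_correct,
    classify_heb,
    fit_nested,
    fpkm,
    heb_analysis,
    heb_summary,
    lrt,
)
from octoscope.hebstats import testable_pairs as pair_filter
from octoscope.simdata import simulate_pair_counts


def grid_oracle(x_a, x_b, q, grid=200_001):
    """Brute-force maximized log-likelihoods for H0/H1/H2 on a fine grid."""
    x_a = np.asarray(x_a, float)
    x_b = np.asarray(x_b, float)
    ps = np.linspace(1e-9, 1 - 1e-9, grid)
    per_tissue = xlogy(x_a[:, None], ps) + xlogy(x_b[:, None], 1 - ps)
    ll0 = float(np.sum(xlogy(x_a, q) + xlogy(x_b, 1 - q)))
    ll1 = float(per_tissue.sum(axis=0).max())
    ll2 = float(per_tissue.max(axis=1).sum())
    return ll0, ll1, ll2


# --- fpkm -------------------------------------------------------------------

def test_fpkm_formula_and_invariances():
    assert fpkm(100, 10_000_000, 2000) == pytest.approx(5.0)
    assert fpkm(0, 10_000_000, 2000) == 0.0
    assert fpkm(200, 20_000_000, 2000) == pytest.approx(fpkm(100, 10_000_000, 2000))
    with pytest.raises(ValueError):
        fpkm(10, 0, 2000)
    with pytest.raises(ValueError):
        fpkm(10, 1e6, 0)


# --- testable-pair filter ---------------------------------------------------

def test_testable_pair_filter_boundaries():
    pairs = pd.DataFrame({"support": [85, 80, 90]})
    x_a = np.array([[5, 5, 5], [5, 5, 5], [0, 3, 4]])
    x_b = np.array([[1, 1, 1], [1, 1, 1], [0, 2, 2]])
    mask = pair_filter(pairs, x_a, x_b)
    # support 80 is dropped (strict >80); a 0+0 tissue is dropped
    assert mask.tolist() == [True, False, False]


# --- nested fits ------------------------------------------------------------

def test_null_identity_pair():
    fit = fit_nested([10, 20, 30], [10, 20, 30], 1000, 1000)
    assert fit.q == 0.5
    assert fit.p_common == pytest.approx(0.5)
    assert fit.s_hat == pytest.approx(1.0)
    assert fit.ll0 == pytest.approx(fit.ll1)
    assert fit.ll1 == pytest.approx(fit.ll2)
    res = lrt(fit)
    assert res.d01 == pytest.approx(0.0)
    assert res.p01 == pytest.approx(1.0)


def test_worked_example_closed_form():
    # counts (30,10), (60,20), (90,30) with equal lengths
    fit = fit_nested([30, 60, 90], [10, 20, 30], 1500, 1500)
    assert fit.p_common == pytest.approx(0.75)
    assert np.allclose(fit.p_per_tissue, 0.75)
    assert fit.s_hat == pytest.approx(3.0)
    assert fit.ll1 == pytest.approx(fit.ll2)
    res = lrt(fit)
    d01_exact = 2 * (180 * np.log(0.75) + 60 * np.log(0.25) - 240 * np.log(0.5))
    assert d01_exact == pytest.approx(62.7897, abs=1e-3)
    assert res.d01 == pytest.approx(d01_exact, abs=1e-9)
    assert res.d12 == pytest.approx(0.0, abs=1e-9)
    assert res.p12 == pytest.approx(1.0)


def test_length_offset_pulls_expectation():
    # L_A = 2 L_B, equal counts: q = 2/3 but p̂ = 1/2 → bias toward B
    fit = fit_nested([50, 50, 50], [50, 50, 50], 2000, 1000)
    assert fit.q == pytest.approx(2 / 3)
    assert fit.p_common == pytest.approx(0.5)
    assert fit.s_hat < 1.0


@pytest.mark.parametrize("seed", range(5))
def test_fit_matches_grid_search_oracle(seed):
    rng = np.random.default_rng(seed)
    x_a = rng.integers(0, 60, size=3)
    x_b = rng.integers(1, 60, size=3)
    la, lb = rng.integers(500, 3000, size=2)
    fit = fit_nested(x_a, x_b, la, lb)
    ll0, ll1, ll2 = grid_oracle(x_a, x_b, fit.q)
    assert fit.ll0 == pytest.approx(ll0, abs=1e-6)
    assert fit.ll1 == pytest.approx(ll1, abs=1e-4)
    assert fit.ll2 == pytest.approx(ll2, abs=1e-4)


@given(
    st.lists(st.tuples(st.integers(0, 500), st.integers(0, 500)), min_size=2, max_size=6),
    st.integers(500, 5000),
    st.integers(500, 5000),
)
def test_nesting_and_additivity_invariants(counts, la, lb):
    x_a = np.array([c[0] for c in counts])
    x_b = np.array([c[1] for c in counts])
    fit = fit_nested(x_a, x_b, la, lb)
    assert fit.ll0 <= fit.ll1 + 1e-9 <= fit.ll2 + 2e-9
    res = lrt(fit)
    assert res.d01 >= 0 and res.d12 >= 0
    assert 2 * (fit.ll2 - fit.ll0) == pytest.approx(res.d01 + res.d12, abs=1e-9)


def test_depth_scaling_leaves_estimates_unchanged():
    fit1 = fit_nested([30, 60, 90], [10, 20, 30], 1500, 1500)
    fit10 = fit_nested([300, 600, 900], [100, 200, 300], 1500, 1500)
    assert fit10.p_common == pytest.approx(fit1.p_common)
    assert fit10.s_hat == pytest.approx(fit1.s_hat)
    assert fit10.q == fit1.q


def test_missing_lengths_fall_back_to_half():
    with pytest.warns(UserWarning, match="q = 0.5"):
        fit = fit_nested([10, 20], [10, 20], None, None)
    assert fit.q == 0.5


# --- BH correction ----------------------------------------------------------

def test_bh_step_up_examples():
    qvals, reject = bh_correct([0.001, 0.004, 0.02, 0.5], alpha=0.01)
    assert reject.sum() == 2
    assert np.allclose(qvals, [0.004, 0.008, 0.02 * 4 / 3, 0.5])

    _, none = bh_correct([1.0, 1.0, 1.0], alpha=0.01)
    assert none.sum() == 0

    q_single, rej_single = bh_correct([0.004], alpha=0.01)
    assert q_single[0] == pytest.approx(0.004)
    assert rej_single[0]


def test_bh_rejects_bad_pvalues():
    with pytest.raises(ValueError):
        bh_correct([0.5, 1.5])


# --- classification ---------------------------------------------------------

def test_classification_rules():
    base = dict(subgenome_a="A", subgenome_b="B")
    results = pd.DataFrame(
        [
            {**base, "p01": 1e-6, "p12": 0.5, "s_hat": 3.0},   # consistent toward A
            {**base, "p01": 1e-6, "p12": 1e-4, "s_hat": 3.0},  # inconsistent
            {**base, "p01": 0.5, "p12": 1e-4, "s_hat": 3.0},   # unbiased despite p12
            {**base, "p01": 1e-6, "p12": 0.5, "s_hat": 0.2},   # consistent toward B
        ]
    )
    classed = classify_heb(results, alpha=0.01)
    assert classed["class"].tolist() == [
        "consistent-bias", "inconsistent", "unbiased", "consistent-bias",
    ]
    assert classed["direction"].tolist() == ["A", None, None, "B"]


# --- null calibration & summaries -------------------------------------------

def test_null_pvalues_approximately_uniform():
    rng = np.random.default_rng(123)
    pairs, x_a, x_b, _ = simulate_pair_counts(
        10_000, rng, n_tissues=3, depth=500.0, mixture=(1.0, 0.0, 0.0)
    )
    classed = heb_analysis(pairs, x_a, x_b)
    p = np.sort(classed["p01"].to_numpy())
    ks = np.max(np.abs(p - (np.arange(1, len(p) + 1) / len(p))))
    assert ks < 0.02


def test_power_and_direction_under_consistent_bias():
    rng = np.random.default_rng(7)
    pairs, x_a, x_b, truth = simulate_pair_counts(
        400, rng, n_tissues=3, depth=1000.0, mixture=(0.0, 1.0, 0.0),
        scale=4.0, bias_toward_a=1.0,
    )
    classed = heb_analysis(pairs, x_a, x_b)
    frac = ((classed["class"] == "consistent-bias") & (classed["direction"] == "A")).mean()
    assert frac >= 0.95


def test_summary_mirrors_under_label_swap():
    rng = np.random.default_rng(42)
    pairs, x_a, x_b, _ = simulate_pair_counts(
        300, rng, n_tissues=3, depth=800.0, mixture=(0.5, 0.5, 0.0), bias_toward_a=0.8
    )
    classed = heb_analysis(pairs, x_a, x_b)
    summary = heb_summary(classed, dominant="A")

    swapped = classed.rename(
        columns={"subgenome_a": "subgenome_b", "subgenome_b": "subgenome_a"}
    ).copy()
    swapped["s_hat"] = 1.0 / swapped["s_hat"]
    summary_swapped = heb_summary(swapped, dominant="B")
    k, ks = "A_vs_B", "B_vs_A"
    # swapping labels exchanges which side counts as dominant
    assert summary[k]["n_biased_dominant"] == summary_swapped[ks]["n_biased_other"]
    assert summary[k]["n_biased_other"] == summary_swapped[ks]["n_biased_dominant"]
    assert summary[k]["n_biased_dominant"] > summary[k]["n_biased_other"]


def test_summary_all_unbiased_counts_zero():
    classed = pd.DataFrame(
        {
            "subgenome_a": ["A"] * 5,
            "subgenome_b": ["B"] * 5,
            "s_hat": [1.0, 1.1, 0.9, 1.0, 1.0],
            "class": ["unbiased"] * 5,
            "direction": [None] * 5,
        }
    )
    summary = heb_summary(classed, dominant="A")
    assert summary["A_vs_B"]["n_biased_dominant"] == 0
    assert summary["A_vs_B"]["n_biased_other"] == 0
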