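"""Weights, burden aggregation, the logistic burden test and lambda_GC."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from wgsburden.burden import (
    BurdenAssociation,
    BurdenDesign,
    WeightScheme,
    analysis_mask,
    bonferroni_threshold,
    burden_logistic_test,
    lambda_gc,
    sample_burden,
    total_burden_covariate,
    variant_weight,
)


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------


def test_weight_limits_and_closed_form():
    assert variant_weight(1e-12) == pytest.approx(25.0, rel=1e-6)
    assert variant_weight(0.5) == pytest.approx(25.0 * 0.5**24)
    assert variant_weight(0.01) > variant_weight(0.04)


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
def test_weight_rejects_out_of_range(bad):
    with pytest.raises(ValueError):
        variant_weight(bad)


@given(
    st.floats(min_value=1e-6, max_value=0.49),
    st.floats(min_value=1e-6, max_value=0.49),
)
@settings(derandomize=True, max_examples=50)
def test_weight_strictly_decreasing(a, b):
    lo, hi = min(a, b), max(a, b)
    if lo < hi:
        assert variant_weight(lo) > variant_weight(hi)


def test_custom_scheme_is_beta_density():
    assert variant_weight(0.3, WeightScheme(2, 5)) == pytest.approx(
        stats.beta.pdf(0.3, 2, 5)
    )


# ---------------------------------------------------------------------------
# burden aggregation
# ---------------------------------------------------------------------------


def test_single_variant_burden_is_scaled_dosage():
    dosage = np.array([[0.0], [1.0], [2.0]])
    w = np.array([3.5])
    assert np.allclose(sample_burden(dosage, w, np.array([0])), [0, 3.5, 7.0])


def test_burden_invariant_under_member_order(rng):
    dosage = rng.integers(0, 3, size=(20, 30)).astype(float)
    w = rng.random(30)
    idx = np.arange(5, 25)
    b1 = sample_burden(dosage, w, idx)
    b2 = sample_burden(dosage, w, rng.permutation(idx))
    assert np.allclose(b1, b2)


def test_burden_matches_double_loop_oracle(small_cohort, small_annotation):
    vt = small_cohort.variant_table
    idx = np.arange(vt.n_samples)
    maf = vt.maf()
    design = BurdenDesign()
    mask = analysis_mask(
        maf, vt.variants["is_snv"].to_numpy(), small_annotation.excluded, design
    )
    members = np.where(mask)[0][:250]
    w = np.zeros(vt.n_variants)
    w[members] = variant_weight(maf[members])
    dosage = vt.dosage()
    fast = sample_burden(dosage, w, members)
    slow = np.zeros(vt.n_samples)
    for i in range(vt.n_samples):
        for v in members:
            slow[i] += w[v] * dosage[i, v]
    assert np.allclose(fast, slow)


def test_empty_member_set_gives_zero_burden():
    dosage = np.ones((4, 6))
    assert np.allclose(sample_burden(dosage, np.ones(6), np.array([], dtype=int)), 0)


def test_out_of_range_member_ids_rejected():
    with pytest.raises(IndexError, match="out of range"):
        sample_burden(np.ones((2, 3)), np.ones(3), np.array([5]))


def test_total_burden_is_sum_over_partition(small_cohort, small_annotation):
    vt = small_cohort.variant_table
    maf = vt.maf()
    design = BurdenDesign()
    mask = analysis_mask(
        maf, vt.variants["is_snv"].to_numpy(), small_annotation.excluded, design
    )
    w = np.zeros(vt.n_variants)
    w[mask] = variant_weight(maf[mask])
    dosage = vt.dosage()
    total = total_burden_covariate(dosage, w)
    # chromatin states partition all variants (incl. "unassigned")
    labels = small_annotation.labels["chrom_state"]
    parts = np.zeros(vt.n_samples)
    for lab in np.unique(labels):
        members = np.where((labels == lab) & mask)[0]
        parts += sample_burden(dosage, w, members)
    assert np.allclose(total, parts)
    carriers = dosage[:, mask].sum(axis=1) > 0
    assert np.all(total[carriers] > 0)


# ---------------------------------------------------------------------------
# the logistic burden test
# ---------------------------------------------------------------------------


def test_type_one_error_within_binomial_bounds(rng):
    n, reps = 800, 400
    hits = 0
    for _ in range(reps):
        y = rng.binomial(1, 0.35, size=n)
        if y.sum() in (0, n):
            continue
        burden = rng.gamma(2.0, 1.5, size=n)
        res = burden_logistic_test(y, burden)
        hits += res.pvalue < 0.05
    rate = hits / reps
    lo, hi = 0.05 + np.array([-1, 1]) * 1.96 * np.sqrt(0.05 * 0.95 / reps)
    assert lo <= rate <= hi


def test_separation_triggers_firth_fallback(rng):
    burden = rng.normal(size=200)
    y = (burden > np.median(burden)).astype(float)
    res = burden_logistic_test(y, burden)
    assert res.method_used == "firth"
    assert np.isfinite(res.beta) and np.isfinite(res.se)
    assert 0 < res.pvalue <= 1


def test_constant_burden_degenerates_to_p_one():
    y = np.array([0, 1, 0, 1, 1, 0])
    res = burden_logistic_test(y, np.full(6, 2.0))
    assert res.degenerate and res.pvalue == 1.0


def test_rank_deficient_covariates_error_names_columns(rng):
    n = 100
    y = rng.binomial(1, 0.5, n)
    burden = rng.normal(size=n)
    x = rng.normal(size=n)
    cov = np.column_stack([x, 2 * x])
    with pytest.raises(ValueError, match="collinear"):
        burden_logistic_test(y, burden, cov, covariate_names=["x1", "x1_copy"])


def test_effect_recovery_within_three_se(rng):
    beta_true, n, reps = 0.3, 2000, 200
    covered = 0
    for _ in range(reps):
        burden = rng.gamma(2.0, 0.5, size=n)
        eta = -1.0 + beta_true * burden
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        res = burden_logistic_test(y, burden)
        covered += abs(res.beta - beta_true) <= 3 * res.se
    assert covered / reps >= 0.95


def test_unit_weight_single_variant_reduces_to_logistic(rng):
    n = 500
    g = rng.binomial(2, 0.2, size=n).astype(float)
    y = rng.binomial(1, 1 / (1 + np.exp(-(-0.5 + 0.4 * g))))
    res = burden_logistic_test(y, g)
    ref = sm.Logit(y, sm.add_constant(g)).fit(disp=0)
    assert res.beta == pytest.approx(ref.params[1], rel=1e-6)
    assert res.pvalue == pytest.approx(ref.pvalues[1], rel=1e-4)
    assert res.or_ == pytest.approx(np.exp(res.beta))


def test_result_invariant_under_sample_reordering(rng):
    n = 300
    y = rng.binomial(1, 0.4, n).astype(float)
    burden = rng.gamma(2, 1, n)
    cov = rng.normal(size=(n, 2))
    perm = rng.permutation(n)
    r1 = burden_logistic_test(y, burden, cov)
    r2 = burden_logistic_test(y[perm], burden[perm], cov[perm])
    assert r1.beta == pytest.approx(r2.beta, rel=1e-8)
    assert r1.pvalue == pytest.approx(r2.pvalue, rel=1e-8)


def test_lrt_option_close_to_wald_for_regular_fit(rng):
    n = 1000
    burden = rng.gamma(2, 1, n)
    y = rng.binomial(1, 1 / (1 + np.exp(-(-0.7 + 0.2 * burden))))
    wald = burden_logistic_test(y, burden)
    lrt = burden_logistic_test(y, burden, method="lrt")
    assert np.log10(wald.pvalue) == pytest.approx(np.log10(lrt.pvalue), abs=0.3)


def test_summary_contains_key_quantities(rng):
    y = rng.binomial(1, 0.5, 100)
    res = burden_logistic_test(y, rng.normal(size=100))
    text = res.summary()
    assert "OR per unit" in text and "p (two-sided)" in text


# ---------------------------------------------------------------------------
# lambda_GC and thresholds
# ---------------------------------------------------------------------------


def test_lambda_gc_at_half_is_one():
    assert lambda_gc([0.5] * 10) == pytest.approx(1.0)


def test_lambda_gc_uniform_near_one(rng):
    p = rng.uniform(size=10_000)
    assert lambda_gc(p) == pytest.approx(1.0, abs=0.03)


def test_lambda_gc_scales_linearly_in_chi2():
    p = np.linspace(0.05, 0.95, 99)
    chi = stats.chi2.isf(p, 1)
    p_half = stats.chi2.sf(chi / 2, 1)
    assert lambda_gc(p_half) == pytest.approx(0.5 * lambda_gc(p), rel=1e-9)


def test_lambda_gc_input_validation():
    with pytest.raises(ValueError):
        lambda_gc([])
    with pytest.raises(ValueError):
        lambda_gc([0.0, 0.5])


def test_bonferroni_threshold_exact_rationals():
    assert bonferroni_threshold(0.05, 200) == 0.05 / 200
    assert bonferroni_threshold(0.05, 200) == pytest.approx(0.00025)
    assert bonferroni_threshold(0.05, 22) == pytest.approx(0.0023, abs=5e-5)
    assert bonferroni_threshold(0.05, 200, 7) == pytest.approx(3.6e-5, abs=5e-7)
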