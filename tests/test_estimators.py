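import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrcascade import (
    egger,
    ivw,
    leave_one_out,
    mode_estimators,
    run_all_methods,
    select_instruments,
    wald_ratio,
    weighted_median,
)
from mrcascade.estimators import _weighted_median_point, cochran_q


# ------------------------------------------------------------------ Wald ratio
def test_wald_ratio_arithmetic():
    assert wald_ratio(0.1, 0.05, 0.02) == (pytest.approx(0.5), pytest.approx(0.2))
    assert wald_ratio(0.1, 0.0, 0.02)[0] == 0.0


def test_wald_ratio_zero_exposure_beta():
    with pytest.raises(ZeroDivisionError):
        wald_ratio(0.0, 0.1, 0.02)


def test_wald_se_close_to_monte_carlo_for_strong_instruments():
    """First-order se within 5% of the empirical ratio sd when |bx|/sx > 10."""
    rng = np.random.default_rng(0)
    bx, sx, by, sy = 0.2, 0.01, 0.1, 0.02
    draws = rng.normal(by, sy, 200_000) / rng.normal(bx, sx, 200_000)
    _, se = wald_ratio(bx, by, sy)
    # the exposure noise contributes var(by/bx) ~ (by/bx)^2 (sx/bx)^2 extra
    full = np.sqrt((sy / bx) ** 2 + (by * sx / bx**2) ** 2)
    assert np.std(draws) == pytest.approx(full, rel=0.05)
    assert se == pytest.approx(np.std(draws), rel=0.06)


# ------------------------------------------------------------------------ IVW
def test_single_snp_ivw_equals_wald_ratio():
    fit, het = ivw([0.1], [0.05], [0.02])
    est, se = wald_ratio(0.1, 0.05, 0.02)
    assert fit.beta == pytest.approx(est) and fit.se == pytest.approx(se)
    assert fit.n_snp == 1 and het.df == 0 and het.pval == 1.0


def test_homogeneous_ratios_fixed_model():
    # all ratios exactly 0.5 with bx=1 -> Q = 0, fixed model
    fit, het = ivw([1, 1, 1], [0.5, 0.5, 0.5], [0.1, 0.1, 0.1])
    assert het.q == pytest.approx(0.0, abs=1e-12)
    assert het.pval == pytest.approx(1.0)
    assert fit.method == "ivw_fixed"
    assert fit.se == pytest.approx(1 / np.sqrt(3 / 0.01))


def test_three_snp_hand_oracle():
    """ratios {0.4, 0.5, 0.6} with ratio-se 0.1 each: beta 0.5, Q 2.0."""
    fit, het = ivw([1.0, 1.0, 1.0], [0.4, 0.5, 0.6], [0.1, 0.1, 0.1], "fixed")
    assert fit.beta == pytest.approx(0.5, abs=1e-10)
    assert fit.se == pytest.approx(0.1 / np.sqrt(3), abs=1e-10)
    assert fit.se == pytest.approx(0.05774, abs=1e-5)
    assert het.q == pytest.approx(2.0, abs=1e-10)


def test_q_matches_brute_force():
    rng = np.random.default_rng(1)
    bx, by, sy = rng.uniform(0.05, 0.2, 20), rng.normal(0, 0.05, 20), rng.uniform(0.01, 0.05, 20)
    fit, het = ivw(bx, by, sy, "fixed")
    ratios, w = by / bx, (bx / sy) ** 2
    brute = np.sum(w * (ratios - fit.beta) ** 2)
    assert het.q == pytest.approx(brute, abs=1e-10)


def test_random_effects_inflates_se_only_under_heterogeneity():
    bx = np.ones(5)
    by = np.array([0.1, 0.5, -0.3, 0.8, -0.6])  # wildly heterogeneous
    sy = np.full(5, 0.05)
    fixed, het = ivw(bx, by, sy, "fixed")
    auto, _ = ivw(bx, by, sy, "auto")
    assert het.pval < 0.05
    assert auto.method == "ivw_random"
    assert auto.se == pytest.approx(fixed.se * np.sqrt(het.q / het.df))
    assert auto.beta == pytest.approx(fixed.beta)  # multiplicative: point unchanged


def test_random_effects_floor_never_deflates():
    fit_f, _ = ivw([1, 1, 1], [0.5, 0.5, 0.5], [0.1, 0.1, 0.1], "fixed")
    fit_r, _ = ivw([1, 1, 1], [0.5, 0.5, 0.5], [0.1, 0.1, 0.1], "random")
    assert fit_r.se >= fit_f.se  # sqrt(Q/df) floored at 1


# ---------------------------------------------------------------------- Egger
def test_egger_exact_wls_oracle():
    fit, pleio = egger([0.1, 0.2, 0.3], [0.06, 0.11, 0.16], [0.01, 0.01, 0.01])
    assert fit.beta == pytest.approx(0.5, abs=1e-10)
    assert pleio.intercept == pytest.approx(0.01, abs=1e-10)


def test_zero_intercept_egger_reduces_to_fixed_ivw():
    rng = np.random.default_rng(2)
    bx = rng.uniform(0.05, 0.3, 15)
    by = 0.4 * bx + rng.normal(0, 0.01, 15)
    sy = rng.uniform(0.01, 0.03, 15)
    # constrained WLS through the origin == IVW fixed
    wls = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
    fit, _ = ivw(bx, by, sy, "fixed")
    assert fit.beta == pytest.approx(float(wls.params[0]), abs=1e-12)
    assert fit.se == pytest.approx(
        float(wls.bse[0] / np.sqrt(wls.scale)), abs=1e-12
    )  # IVW se is the unscaled WLS se


def test_egger_needs_three_snps():
    with pytest.raises(ValueError):
        egger([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])


def test_egger_orientation_invariance():
    """Flipping the allele coding of some SNPs (bx, by both negated) must not
    change the Egger fit — orientation is normalised internally."""
    rng = np.random.default_rng(3)
    bx = rng.uniform(0.05, 0.3, 12)
    by = 0.3 * bx + 0.01 + rng.normal(0, 0.01, 12)
    sy = np.full(12, 0.02)
    flip = rng.choice([1, -1], 12)
    a, _ = egger(bx, by, sy)
    b, _ = egger(bx * flip, by * flip, sy)
    assert a.beta == pytest.approx(b.beta) and a.se == pytest.approx(b.se)


# -------------------------------------------------------------- median & modes
def test_weighted_median_equal_weights_is_median():
    assert _weighted_median_point(np.array([1.0, 2.0, 9.0]), np.ones(3)) == 2.0


def test_all_methods_agree_on_identical_ratios():
    bx = np.array([0.1, 0.2, 0.4, 0.25])
    by = 0.7 * bx
    sx = np.full(4, 0.001)
    sy = np.full(4, 0.01)
    ivw_fit, _ = ivw(bx, by, sy)
    egger_fit, _ = egger(bx, by, sy)
    wm = weighted_median(bx, sx, by, sy, n_boot=50, seed=0)
    sm_fit, wmode = mode_estimators(bx, sx, by, sy, n_boot=50, seed=0)
    for fit in (ivw_fit, egger_fit, wm, sm_fit, wmode):
        assert fit.beta == pytest.approx(0.7, abs=1e-6)


def test_weighted_median_majority_valid_breakdown():
    """51% of weight on ratio 0.3, 49% on a wild invalid ratio: the weighted
    median tracks the valid majority."""
    bx = np.ones(100)
    sy = np.full(100, 0.05)
    by = np.where(np.arange(100) < 51, 0.3, 2.0)
    wm = weighted_median(bx, np.full(100, 0.001), by, sy, n_boot=50, seed=1)
    assert wm.beta == pytest.approx(0.3, abs=0.05)


def test_mode_estimator_finds_dominant_cluster():
    rng = np.random.default_rng(4)
    bx = np.ones(30)
    by = np.r_[rng.normal(0.5, 0.01, 20), rng.normal(1.5, 0.01, 10)]
    sy = np.full(30, 0.02)
    simple, weighted = mode_estimators(bx, np.full(30, 1e-4), by, sy, n_boot=50, seed=2)
    assert simple.beta == pytest.approx(0.5, abs=0.1)
    assert weighted.beta == pytest.approx(0.5, abs=0.1)


# ---------------------------------------------------------------- leave-one-out
def test_loo_equals_brute_force_subsets():
    rng = np.random.default_rng(5)
    bx = rng.uniform(0.05, 0.3, 8)
    by = 0.4 * bx + rng.normal(0, 0.02, 8)
    sy = rng.uniform(0.01, 0.03, 8)
    loo = leave_one_out(bx, by, sy)
    for i, row in loo.iterrows():
        keep = np.arange(8) != i
        fit, _ = ivw(bx[keep], by[keep], sy[keep], "fixed")
        assert row.beta == pytest.approx(fit.beta, abs=1e-12)


def test_loo_homogeneous_refits_equal_full():
    loo = leave_one_out([1, 1, 1, 1], [0.5] * 4, [0.1] * 4)
    assert np.allclose(loo.beta, 0.5)
    assert not loo.outlier_flag.any()


def test_loo_flags_planted_outlier():
    bx = np.ones(10)
    by = np.r_[np.full(9, 0.5), 5.0]  # one 10x ratio
    sy = np.full(10, 0.05)
    loo = leave_one_out(bx, by, sy)
    assert loo.outlier_flag.iloc[9]
    # the planted SNP's omission moves the estimate more than any other's
    assert loo["shift"].abs().idxmax() == 9


# ------------------------------------------------------------------ properties
@given(c=st.floats(0.1, 10.0))
@settings(max_examples=25, deadline=None)
def test_scale_equivariance(c):
    bx = np.array([0.1, 0.2, 0.3, 0.15])
    by = np.array([0.05, 0.09, 0.16, 0.07])
    sy = np.array([0.01, 0.02, 0.01, 0.015])
    base, _ = ivw(bx, by, sy, "fixed")
    scaled, _ = ivw(bx, c * by, c * sy, "fixed")
    assert scaled.beta == pytest.approx(c * base.beta, rel=1e-9)
    assert scaled.se == pytest.approx(c * base.se, rel=1e-9)
    eb, _ = egger(bx, by, sy)
    es, _ = egger(bx, c * by, c * sy)
    assert es.beta == pytest.approx(c * eb.beta, rel=1e-9)


def test_sign_antisymmetry():
    bx = np.array([0.1, 0.2, 0.3])
    by = np.array([0.05, 0.09, 0.16])
    sy = np.array([0.01, 0.02, 0.01])
    pos, _ = ivw(bx, by, sy)
    neg, _ = ivw(bx, -by, sy)
    assert neg.beta == pytest.approx(-pos.beta)
    ep, _ = egger(bx, by, sy)
    en, _ = egger(bx, -by, sy)
    assert en.beta == pytest.approx(-ep.beta)


def test_parameter_recovery_no_pleiotropy(chain_study):
    """Simulated total effect 0.25 recovered with small bias at n=100k."""
    hset = select_instruments(chain_study.exposure, chain_study.outcome, chain_study.ld)
    r = hset.records
    fit, _ = ivw(r.beta_exp, r.beta_out, r.se_out)
    assert fit.beta == pytest.approx(chain_study.truth.total_effect, abs=0.02)


def test_run_all_methods_emits_five_fits(chain_study):
    hset = select_instruments(chain_study.exposure, chain_study.outcome, chain_study.ld)
    res = run_all_methods(hset, n_boot=60, seed=0)
    assert set(res.fits) == {"ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"}
    frame = res.to_frame()
    assert len(frame) == 5
    assert {"or", "or_ci_low", "or_ci_high"} <= set(frame.columns)
    # OR transform consistency
    ivw_row = frame[frame.method.str.startswith("ivw")].iloc[0]
    assert ivw_row["or"] == pytest.approx(np.exp(ivw_row.beta))
    assert ivw_row.or_ci_low < ivw_row["or"] < ivw_row.or_ci_high
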