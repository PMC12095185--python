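"""Two-sample MR estimators and the sensitivity-analysis suite.

All estimators consume harmonized per-SNP summary statistics: exposure
betas ``bx`` (with standard errors ``sx``), aligned outcome betas ``by``
(standard errors ``sy``).  The inverse-variance-weighted (IVW) estimator is
a precision-weighted meta-analysis of per-SNP Wald ratios — algebraically
the zero-intercept weighted least-squares fit of ``by`` on ``bx`` with
weights ``1/sy²``.  Cochran's Q on the ratios decides between the fixed
model and multiplicative random effects (standard error inflated by
``sqrt(Q/df)``, floored at 1).  MR-Egger frees the intercept, which
estimates average directional pleiotropy.  The weighted median and the
simple/weighted mode estimators provide robustness when a minority of
instruments are invalid; their standard errors come from a seeded
parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MrFit:
    """One estimator's causal estimate, on the per-unit-exposure log scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int

    @property
    def or_point(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        lo = np.exp(self.beta - Z95 * self.se)
        hi = np.exp(self.beta + Z95 * self.se)
        return float(lo), float(hi)

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - Z95 * self.se, self.beta + Z95 * self.se)


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q across per-SNP ratios; p > 0.05 ⇒ no heterogeneity."""

    q: float
    df: int
    pval: float


@dataclass(frozen=True)
class PleiotropyResult:
    """MR-Egger intercept test for average directional pleiotropy."""

    intercept: float
    se: float
    pval: float


def _as_arrays(*cols) -> tuple[np.ndarray, ...]:
    return tuple(np.asarray(c, dtype=float) for c in cols)


def wald_ratio(bx: float, by: float, sy: float) -> tuple[float, float]:
    """Per-SNP causal estimate by/bx with first-order standard error sy/|bx|."""
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined for bx = 0")
    return by / bx, sy / abs(bx)


def cochran_q(ratios: np.ndarray, weights: np.ndarray, beta: float) -> HeterogeneityResult:
    q = float(np.sum(weights * (ratios - beta) ** 2))
    df = len(ratios) - 1
    pval = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    return HeterogeneityResult(q, df, pval)


def ivw(
    bx, by, sy, effects_model: str = "auto"
) -> tuple[MrFit, HeterogeneityResult]:
    """IVW meta-analysis of Wald ratios with fixed/random model switching.

    ``effects_model``: "fixed", "random", or "auto" (random iff Q's p < 0.05,
    the heterogeneity-driven switch).  Random effects are multiplicative —
    the fixed-effect point estimate with standard error inflated by
    ``sqrt(Q/df)`` floored at 1.
    """
    bx, by, sy = _as_arrays(bx, by, sy)
    if len(bx) == 0:
        raise ValueError("ivw needs at least one instrument")
    ratios = by / bx
    w = (bx / sy) ** 2  # = 1 / se(ratio)^2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    het = cochran_q(ratios, w, beta)
    if effects_model == "fixed":
        se = se_fixed
        method = "ivw_fixed"
    else:
        inflate = np.sqrt(het.q / het.df) if het.df > 0 else 1.0
        inflate = max(inflate, 1.0)
        random_requested = effects_model == "random" or (
            effects_model == "auto" and het.pval < 0.05
        )
        se = se_fixed * inflate if random_requested else se_fixed
        method = "ivw_random" if random_requested else "ivw_fixed"
    pval = 2.0 * float(stats.norm.sf(abs(beta) / se)) if se > 0 else (
        1.0 if beta == 0 else 0.0
    )
    return MrFit(method, beta, se, min(pval, 1.0), len(bx)), het


def egger(bx, by, sy) -> tuple[MrFit, PleiotropyResult]:
    """MR-Egger: weighted regression of by on bx with a free intercept.

    SNPs are re-oriented so every exposure beta is positive before fitting
    (the estimate is invariant to allele coding only after orientation).
    Inference uses the t reference with n − 2 degrees of freedom.
    """
    bx, by, sy = _as_arrays(bx, by, sy)
    n = len(bx)
    if n < 3:
        raise ValueError("MR-Egger needs at least three instruments")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x, y = bx * flip, by * flip
    model = sm.WLS(y, sm.add_constant(x), weights=1.0 / sy**2).fit()
    df = n - 2
    slope, slope_se = float(model.params[1]), float(model.bse[1])
    icept, icept_se = float(model.params[0]), float(model.bse[0])
    slope_p = 2.0 * float(stats.t.sf(abs(slope / slope_se), df))
    icept_p = 2.0 * float(stats.t.sf(abs(icept / icept_se), df))
    return (
        MrFit("egger", slope, slope_se, slope_p, n),
        PleiotropyResult(icept, icept_se, icept_p),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """50th weighted percentile with linear interpolation between order stats."""
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(0.5, cum, r))


def _bootstrap_se(
    point_fn: Callable[[np.ndarray, np.ndarray], float],
    bx: np.ndarray,
    sx: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    n_boot: int,
    seed: int,
) -> float:
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        bxb[bxb == 0] = np.finfo(float).tiny
        est[b] = point_fn(byb / bxb, (bxb / sy) ** 2)
    return float(np.std(est, ddof=1))


def weighted_median(
    bx, sx, by, sy, n_boot: int = 1000, seed: int = 0
) -> MrFit:
    """Weighted-median estimator: consistent if ≥50% of weight is valid."""
    bx, sx, by, sy = _as_arrays(bx, sx, by, sy)
    if len(bx) < 3:
        raise ValueError("weighted median needs at least three instruments")
    ratios = by / bx
    w = (bx / sy) ** 2
    beta = _weighted_median_point(ratios, w)
    se = _bootstrap_se(_weighted_median_point, bx, sx, by, sy, n_boot, seed)
    pval = 2.0 * float(stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0
    return MrFit("weighted_median", beta, se, min(pval, 1.0), len(bx))


def _mode_point(
    ratios: np.ndarray, weights: np.ndarray, bandwidth_phi: float
) -> float:
    """Mode of the weighted Gaussian-kernel-smoothed ratio distribution."""
    w = weights / np.sum(weights)
    s = np.std(ratios, ddof=1) if len(ratios) > 1 else 1.0
    mad = stats.median_abs_deviation(ratios, scale="normal")
    spread = min(s, mad) if mad > 0 else s
    if spread == 0:
        return float(ratios[0])
    h = bandwidth_phi * 0.9 * spread * len(ratios) ** (-1 / 5)
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = np.sum(
        w[:, None] * stats.norm.pdf(grid[None, :], ratios[:, None], h), axis=0
    )
    return float(grid[np.argmax(dens)])


def mode_estimators(
    bx, sx, by, sy, bandwidth_phi: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> tuple[MrFit, MrFit]:
    """Simple (unweighted) and weighted mode-based estimates, bootstrap SEs."""
    bx, sx, by, sy = _as_arrays(bx, sx, by, sy)
    n = len(bx)
    if n < 3:
        raise ValueError("mode estimators need at least three instruments")
    ratios = by / bx
    ivw_w = (bx / sy) ** 2
    ones = np.ones(n)
    fits = []
    for name, w0, fn_w in (
        ("simple_mode", ones, lambda r, w: _mode_point(r, np.ones_like(r), bandwidth_phi)),
        ("weighted_mode", ivw_w, lambda r, w: _mode_point(r, w, bandwidth_phi)),
    ):
        beta = _mode_point(ratios, w0, bandwidth_phi)
        se = _bootstrap_se(fn_w, bx, sx, by, sy, n_boot, seed)
        pval = 2.0 * float(stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0
        fits.append(MrFit(name, beta, se, min(pval, 1.0), n))
    return fits[0], fits[1]


def leave_one_out(
    bx, by, sy, flag_multiple: float = 2.0
) -> pd.DataFrame:
    """IVW refit with each SNP omitted in turn.

    Flags a SNP when its omission moves the estimate by more than
    ``flag_multiple`` × the full-set standard error.
    """
    bx, by, sy = _as_arrays(bx, by, sy)
    n = len(bx)
    if n < 2:
        raise ValueError("leave-one-out needs at least two instruments")
    full, _ = ivw(bx, by, sy, effects_model="fixed")
    rows = []
    for i in range(n):
        keep = np.arange(n) != i
        fit, _ = ivw(bx[keep], by[keep], sy[keep], effects_model="fixed")
        rows.append(
            {
                "omitted_index": i,
                "beta": fit.beta,
                "se": fit.se,
                "pval": fit.pval,
                "shift": fit.beta - full.beta,
                "outlier_flag": abs(fit.beta - full.beta) > flag_multiple * full.se,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MrResultSet:
    """All estimators plus diagnostics for one exposure→outcome pair."""

    exposure_id: str
    outcome_id: str
    fits: dict[str, MrFit]
    heterogeneity: HeterogeneityResult | None
    pleiotropy: PleiotropyResult | None
    loo: pd.DataFrame | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fit in self.fits.values():
            lo, hi = fit.or_ci
            rows.append(
                {
                    "exposure": self.exposure_id,
                    "outcome": self.outcome_id,
                    "method": fit.method,
                    "nsnp": fit.n_snp,
                    "beta": fit.beta,
                    "se": fit.se,
                    "pval": fit.pval,
                    "or": fit.or_point,
                    "or_ci_low": lo,
                    "or_ci_high": hi,
                }
            )
        return pd.DataFrame(rows)


def run_all_methods(
    hset,
    effects_model: str = "auto",
    n_boot: int = 1000,
    seed: int = 0,
    with_loo: bool = True,
) -> MrResultSet:
    """The five-method MR table for one harmonized instrument set.

    With a single instrument only the Wald ratio (≡ IVW) is emitted; Egger
    and the median/mode estimators require at least three instruments.
    """
    rec = hset.records
    bx, sx = rec.beta_exp.to_numpy(), rec.se_exp.to_numpy()
    by, sy = rec.beta_out.to_numpy(), rec.se_out.to_numpy()
    fits: dict[str, MrFit] = {}
    het = pleio = None
    n = len(bx)
    if n == 0:
        return MrResultSet(hset.exposure_id, hset.outcome_id, fits, None, None)
    ivw_fit, het = ivw(bx, by, sy, effects_model)
    fits["ivw"] = ivw_fit
    if n >= 3:
        egger_fit, pleio = egger(bx, by, sy)
        fits["egger"] = egger_fit
        fits["weighted_median"] = weighted_median(bx, sx, by, sy, n_boot, seed)
        simple, weighted = mode_estimators(bx, sx, by, sy, 1.0, n_boot, seed + 1)
        fits["simple_mode"] = simple
        fits["weighted_mode"] = weighted
    loo = leave_one_out(bx, by, sy) if (with_loo and n >= 2) else None
    if loo is not None:
        loo = loo.assign(snp_id=rec.snp_id.to_numpy())
    return MrResultSet(hset.exposure_id, hset.outcome_id, fits, het, pleio, loo)
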