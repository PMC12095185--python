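"""Four-step mediation MR with delta-method confidence intervals.

For one exposure → mediator → outcome triple:

1. total effect ``beta_all`` from exposure→outcome MR;
2. reverse-causation check — outcome→exposure MR on the outcome's
   instruments *excluding* the forward instrument set must be
   non-significant (a Steiger-style variance-explained comparison is
   available as a stricter optional gate);
3. ``beta1`` from exposure→mediator MR;
4. ``beta2`` from mediator→outcome MR using the mediator's own instruments
   with every SNP already used in step 3 removed, so the two coefficient
   estimates rest on distinct (hence approximately independent) instrument
   sets.

The indirect effect is the product ``beta12 = beta1·beta2`` with
first-order delta-method variance ``beta1²·se2² + beta2²·se1²`` (the
covariance term vanishes under the distinct-instrument, two-sample
design); the direct effect is ``beta_all − beta12`` by the difference
method, and the mediated proportion ``Z = beta12 / beta_all`` carries the
delta-method variance for a ratio.  The verdict follows the IVW-first
decision rules: IVW and Egger both significant → supported; IVW alone →
accepted on IVW; neither, but both decomposition steps significant in both
methods → direction defined by sign(beta1)·sign(beta2); otherwise
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import MrFit, egger, ivw
from .instruments import LdReference, select_instruments
from .io import TraitPanel

Z95 = stats.norm.ppf(0.975)

MEDIATION_DEFAULTS = dict(
    alpha=0.05,
    reverse_gate="reverse_mr",  # "reverse_mr" | "steiger"
)


@dataclass(frozen=True)
class Estimate:
    """A point estimate with its standard error."""

    beta: float
    se: float

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - Z95 * self.se, self.beta + Z95 * self.se)


@dataclass
class MediationResult:
    """Effect decomposition for one exposure→mediator→outcome triple."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_all: Estimate
    beta1: Estimate
    beta2: Estimate
    beta12: Estimate
    beta_dir: Estimate
    z: float | None
    z_se: float | None
    reverse_ok: bool
    verdict: str  # supported | ivw_only | stepwise_direction | rejected
    stepwise_sign: int | None = None
    inconsistent_mediation: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def beta12_ci(self) -> tuple[float, float]:
        return self.beta12.ci

    @property
    def z_ci(self) -> tuple[float, float] | None:
        if self.z is None:
            return None
        return (self.z - Z95 * self.z_se, self.z + Z95 * self.z_se)

    def to_row(self) -> dict:
        z_ci = self.z_ci or (np.nan, np.nan)
        return {
            "exposure": self.exposure_id,
            "mediator": self.mediator_id,
            "outcome": self.outcome_id,
            "beta_all": self.beta_all.beta,
            "beta_all_se": self.beta_all.se,
            "beta1": self.beta1.beta,
            "beta1_se": self.beta1.se,
            "beta2": self.beta2.beta,
            "beta2_se": self.beta2.se,
            "beta12": self.beta12.beta,
            "beta12_se": self.beta12.se,
            "beta12_ci_low": self.beta12.ci[0],
            "beta12_ci_high": self.beta12.ci[1],
            "beta_dir": self.beta_dir.beta,
            "z": np.nan if self.z is None else self.z,
            "z_ci_low": z_ci[0],
            "z_ci_high": z_ci[1],
            "reverse_ok": self.reverse_ok,
            "verdict": self.verdict,
            "notes": ";".join(self.notes),
        }


def product_delta(beta1: Estimate, beta2: Estimate) -> Estimate:
    """Indirect effect beta1·beta2 with first-order delta-method SE."""
    b12 = beta1.beta * beta2.beta
    var = beta1.beta**2 * beta2.se**2 + beta2.beta**2 * beta1.se**2
    return Estimate(b12, float(np.sqrt(var)))


def proportion_delta(
    beta12: Estimate, beta_all: Estimate
) -> tuple[float, float]:
    """Mediated proportion beta12/beta_all with delta-method SE."""
    z = beta12.beta / beta_all.beta
    var = (
        beta12.se**2 / beta_all.beta**2
        + beta12.beta**2 * beta_all.se**2 / beta_all.beta**4
    )
    return z, float(np.sqrt(var))


def causal_verdict(
    ivw_fit: MrFit,
    egger_fit: MrFit | None,
    step_fits: tuple[tuple[MrFit, MrFit | None], tuple[MrFit, MrFit | None]]
    | None = None,
    alpha: float = 0.05,
) -> tuple[str, int | None]:
    """IVW-first decision rule for the decisive effect.

    Returns ``(verdict, stepwise_sign)`` where the sign is only set for the
    stepwise fallback (sign(beta1)·sign(beta2)).
    """
    ivw_sig = ivw_fit.pval < alpha
    egger_sig = egger_fit is not None and egger_fit.pval < alpha
    if ivw_sig and egger_sig:
        return "supported", None
    if ivw_sig:
        return "ivw_only", None
    if step_fits is not None:
        signs = []
        for step_ivw, step_egger in step_fits:
            both = (
                step_ivw.pval < alpha
                and step_egger is not None
                and step_egger.pval < alpha
            )
            if not both:
                break
            signs.append(np.sign(step_ivw.beta))
        else:
            return "stepwise_direction", int(signs[0] * signs[1])
    return "rejected", None


def _fit_pair(
    exposure: TraitPanel,
    outcome: TraitPanel,
    ld: LdReference | None,
    config: dict | None,
    exclude_snps: set[str] | None = None,
):
    """Instruments + IVW (+ Egger when possible) for one direction."""
    hset = select_instruments(exposure, outcome, ld, config)
    if exclude_snps and not hset.records.empty:
        hset.records = hset.records[
            ~hset.records.snp_id.isin(exclude_snps)
        ].reset_index(drop=True)
        hset.no_instruments = hset.records.empty
    if hset.no_instruments:
        return hset, None, None
    rec = hset.records
    bx, by, sy = rec.beta_exp.to_numpy(), rec.beta_out.to_numpy(), rec.se_out.to_numpy()
    ivw_fit, _ = ivw(bx, by, sy, effects_model="auto")
    egger_fit = egger(bx, by, sy)[0] if len(bx) >= 3 else None
    return hset, ivw_fit, egger_fit


def steiger_ok(hset_fwd, hset_rev) -> bool:
    """Directionality check: exposure instruments should explain more of the
    exposure than the reverse instruments explain of the outcome."""
    if hset_fwd.records.empty or hset_rev.records.empty:
        return True
    return float(hset_fwd.records.r2_explained.sum()) > float(
        hset_rev.records.r2_explained.sum()
    )


def mediate(
    exposure: TraitPanel,
    mediator: TraitPanel,
    outcome: TraitPanel,
    ld: LdReference | None = None,
    config: dict | None = None,
) -> MediationResult | None:
    """Run the four-step mediation decomposition for one triple.

    Returns None when the total-effect step has no instruments (nothing to
    decompose).  A failed step 4 (no mediator instruments left after the
    distinct-SNP exclusion) is recorded in ``notes`` with NaN step-2 terms.
    """
    cfg = dict(MEDIATION_DEFAULTS)
    cfg.update(config or {})
    alpha = cfg["alpha"]
    inst_cfg = cfg.get("instruments")
    notes: list[str] = []

    # step 1: total effect
    hset_all, ivw_all, egger_all = _fit_pair(exposure, outcome, ld, inst_cfg)
    if ivw_all is None:
        return None

    # step 2: reverse causation.  The outcome's instruments are purged of the
    # forward instrument set first: in a true causal chain the exposure's own
    # SNPs are outcome-associated through the chain, and re-using them would
    # flag every genuine forward effect as reverse causation.
    forward_snps = set(hset_all.records.snp_id)
    hset_rev, ivw_rev, _ = _fit_pair(
        outcome, exposure, ld, inst_cfg, exclude_snps=forward_snps
    )
    if cfg["reverse_gate"] == "steiger":
        reverse_ok = steiger_ok(hset_all, hset_rev)
    else:
        reverse_ok = ivw_rev is None or ivw_rev.pval >= alpha
    if not reverse_ok:
        notes.append("reverse_causation_detected")

    # step 3: exposure -> mediator
    hset1, ivw1, egger1 = _fit_pair(exposure, mediator, ld, inst_cfg)
    if ivw1 is None:
        notes.append("no_step3_instruments")
        return None
    step3_snps = set(hset1.records.snp_id)

    # step 4: mediator -> outcome on distinct SNPs
    hset2, ivw2, egger2 = _fit_pair(
        mediator, outcome, ld, inst_cfg, exclude_snps=step3_snps
    )
    if ivw2 is None:
        notes.append("no_step4_instruments_after_exclusion")
        return None

    beta_all = Estimate(ivw_all.beta, ivw_all.se)
    beta1 = Estimate(ivw1.beta, ivw1.se)
    beta2 = Estimate(ivw2.beta, ivw2.se)
    beta12 = product_delta(beta1, beta2)
    beta_dir = Estimate(
        beta_all.beta - beta12.beta,
        float(np.sqrt(beta_all.se**2 + beta12.se**2)),
    )
    if abs(beta_all.beta) < 1e-12:
        z = z_se = None
        notes.append("z_undefined_total_effect_zero")
    else:
        z, z_se = proportion_delta(beta12, beta_all)
    inconsistent = z is not None and (z < 0 or z > 1)
    if inconsistent:
        notes.append("inconsistent_mediation")

    verdict, sign = causal_verdict(
        ivw_all, egger_all, ((ivw1, egger1), (ivw2, egger2)), alpha
    )
    return MediationResult(
        exposure.trait_id,
        mediator.trait_id,
        outcome.trait_id,
        beta_all,
        beta1,
        beta2,
        beta12,
        beta_dir,
        z,
        z_se,
        reverse_ok,
        verdict,
        sign,
        inconsistent,
        notes,
    )
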