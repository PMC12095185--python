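"""Three-stage bidirectional batch screening over trait panels.

Stage 1 screens every immune-cell and inflammatory-factor panel as an
exposure against each disease ("positive" factors).  Stage 2 runs MR in
both directions between the stage-1 positives of the same disease
(immune→inflammatory and inflammatory→immune), yielding "double-positive"
factors — stage-1 positives participating in at least one significant
cross-class association.  Stage 3 re-screens every double-positive factor
as an exposure against its disease; survivors are "triple-positive" and
feed the mediation analysis.

A pair is called positive when the gating estimate (IVW) has p < alpha and
the MR-Egger intercept shows no directional pleiotropy (p ≥ alpha_pleio).
Heterogeneity switches the IVW model between fixed and random effects; it
is not itself a gate.  Screening is nominal by default (no multiplicity
correction, mirroring batch-screening practice); Bonferroni or
Benjamini-Hochberg can be switched on per stage-1 class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .estimators import HeterogeneityResult, MrFit, PleiotropyResult, egger, ivw
from .instruments import LdReference, select_instruments
from .io import TraitPanel

SCREEN_DEFAULTS = dict(
    alpha=0.05,
    alpha_pleio=0.05,
    gating_method="ivw",
    correction=None,  # None | "bonferroni" | "fdr_bh"
)


@dataclass
class ScreenCall:
    """One exposure→outcome screening decision with its audit trail."""

    exposure_id: str
    outcome_id: str
    fit: MrFit | None
    het: HeterogeneityResult | None
    pleio: PleiotropyResult | None
    positive: bool
    reasons: list[str] = field(default_factory=list)
    fallback_used: bool = False

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure_id,
            "outcome": self.outcome_id,
            "nsnp": self.fit.n_snp if self.fit else 0,
            "beta": self.fit.beta if self.fit else np.nan,
            "se": self.fit.se if self.fit else np.nan,
            "pval": self.fit.pval if self.fit else np.nan,
            "het_q_pval": self.het.pval if self.het else np.nan,
            "egger_intercept_pval": self.pleio.pval if self.pleio else np.nan,
            "positive": self.positive,
            "reasons": ";".join(self.reasons),
        }


def screen_pair(
    exposure: TraitPanel,
    outcome: TraitPanel,
    ld: LdReference | None = None,
    config: dict | None = None,
) -> ScreenCall:
    """Instrument selection plus gated IVW/Egger screening for one pair.

    Failures (no instruments after all filters) become negative calls with
    the reason recorded, never errors — a batch screen must keep going.
    """
    cfg = dict(SCREEN_DEFAULTS)
    cfg.update(config or {})
    hset = select_instruments(exposure, outcome, ld, cfg.get("instruments"))
    if hset.no_instruments:
        return ScreenCall(
            exposure.trait_id,
            outcome.trait_id,
            None,
            None,
            None,
            False,
            ["no instruments"],
            hset.fallback_used,
        )
    rec = hset.records
    bx, by, sy = rec.beta_exp.to_numpy(), rec.beta_out.to_numpy(), rec.se_out.to_numpy()
    fit, het = ivw(bx, by, sy, effects_model="auto")
    pleio = None
    reasons = []
    positive = fit.pval < cfg["alpha"]
    reasons.append(f"ivw_p={'pass' if positive else 'fail'}")
    if len(bx) >= 3:
        egger_fit, pleio = egger(bx, by, sy)
        if pleio.pval < cfg["alpha_pleio"]:
            positive = False
            reasons.append("pleiotropy_detected")
        else:
            reasons.append("pleiotropy=pass")
        if np.sign(egger_fit.beta) != np.sign(fit.beta) and cfg["gating_method"] != "ivw":
            positive = False
            reasons.append("direction_disagreement")
    else:
        reasons.append("pleiotropy_untestable")
    if hset.fallback_used:
        reasons.append("fallback_threshold")
    return ScreenCall(
        exposure.trait_id,
        outcome.trait_id,
        fit,
        het,
        pleio,
        positive,
        reasons,
        hset.fallback_used,
    )


@dataclass
class CascadeState:
    """Positive / double-positive / triple-positive bookkeeping per disease."""

    stage1_positive: dict  # disease -> {"immune_cell": [...], "inflammatory_factor": [...]}
    stage2_pairs: dict  # disease -> {"immune_to_inflam": [(exp,out)], "inflam_to_immune": [...]}
    stage3_triple: dict  # disease -> {"immune_cell": [...], "inflammatory_factor": [...]}
    calls: list[ScreenCall] = field(default_factory=list, repr=False)

    def double_positive(self, disease: str) -> dict:
        pairs = self.stage2_pairs.get(disease, {})
        imm = sorted(
            {e for e, _ in pairs.get("immune_to_inflam", [])}
            | {o for _, o in pairs.get("inflam_to_immune", [])}
        )
        inf = sorted(
            {o for _, o in pairs.get("immune_to_inflam", [])}
            | {e for e, _ in pairs.get("inflam_to_immune", [])}
        )
        return {"immune_cell": imm, "inflammatory_factor": inf}

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_row() for c in self.calls])

    def to_manifest(self) -> dict:
        return {
            "stage1_positive": self.stage1_positive,
            "stage2_pairs": {
                d: {k: [list(p) for p in v] for k, v in dirs.items()}
                for d, dirs in self.stage2_pairs.items()
            },
            "stage3_triple": self.stage3_triple,
        }


def _apply_correction(calls: list[ScreenCall], method: str, alpha: float) -> None:
    """Re-gate a family of stage-1 calls on multiplicity-adjusted p-values."""
    testable = [c for c in calls if c.fit is not None]
    if not testable:
        return
    pvals = [c.fit.pval for c in testable]
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method=method)
    for c, rej in zip(testable, reject):
        if c.positive and not rej:
            c.positive = False
            c.reasons.append(f"failed_{method}")


def run_cascade(
    immune: list[TraitPanel],
    inflam: list[TraitPanel],
    diseases: list[TraitPanel],
    ld: LdReference | None = None,
    config: dict | None = None,
) -> CascadeState:
    """The full positive → double-positive → triple-positive screen.

    Outputs are deterministically ordered (panels sorted by trait_id), and
    permutation of the input panel lists cannot change the result.
    """
    if not diseases or (not immune and not inflam):
        raise ValueError("cascade needs at least one disease and one factor panel")
    cfg = dict(SCREEN_DEFAULTS)
    cfg.update(config or {})
    immune = sorted(immune, key=lambda p: p.trait_id)
    inflam = sorted(inflam, key=lambda p: p.trait_id)
    diseases = sorted(diseases, key=lambda p: p.trait_id)
    by_id = {p.trait_id: p for p in immune + inflam + diseases}

    state = CascadeState({}, {}, {})
    for disease in diseases:
        d = disease.trait_id
        stage1 = {"immune_cell": [], "inflammatory_factor": []}
        class_calls: dict[str, list[ScreenCall]] = {
            "immune_cell": [],
            "inflammatory_factor": [],
        }
        for panel in immune + inflam:
            call = screen_pair(panel, disease, ld, cfg)
            state.calls.append(call)
            class_calls[panel.trait_class].append(call)
        if cfg["correction"]:
            for cls_calls in class_calls.values():
                _apply_correction(cls_calls, cfg["correction"], cfg["alpha"])
        for cls, cls_calls in class_calls.items():
            stage1[cls] = sorted(c.exposure_id for c in cls_calls if c.positive)
        state.stage1_positive[d] = stage1

        # stage-2 participation requires a *significant* cross-class MR
        # (gating-method p < alpha); the pleiotropy exclusion belongs to the
        # disease-facing screens where the causal claim is made
        pairs = {"immune_to_inflam": [], "inflam_to_immune": []}
        for imm_id in stage1["immune_cell"]:
            for inf_id in stage1["inflammatory_factor"]:
                fwd = screen_pair(by_id[imm_id], by_id[inf_id], ld, cfg)
                state.calls.append(fwd)
                if fwd.fit is not None and fwd.fit.pval < cfg["alpha"]:
                    pairs["immune_to_inflam"].append((imm_id, inf_id))
                rev = screen_pair(by_id[inf_id], by_id[imm_id], ld, cfg)
                state.calls.append(rev)
                if rev.fit is not None and rev.fit.pval < cfg["alpha"]:
                    pairs["inflam_to_immune"].append((inf_id, imm_id))
        state.stage2_pairs[d] = pairs

        stage3 = {"immune_cell": [], "inflammatory_factor": []}
        double = state.double_positive(d)
        for cls in ("immune_cell", "inflammatory_factor"):
            for tid in double[cls]:
                call = screen_pair(by_id[tid], disease, ld, cfg)
                state.calls.append(call)
                if call.positive:
                    stage3[cls].append(tid)
            stage3[cls] = sorted(stage3[cls])
        state.stage3_triple[d] = stage3
    return state
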