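"""Instrumental-variable selection and exposure/outcome harmonization.

The selection pipeline applies, in order: genome-wide significance with a
relaxed fallback threshold, greedy LD clumping against a reference panel,
a minor-allele-frequency filter, per-SNP instrument-strength (R² and F)
screening, and allele harmonization against the outcome panel with
exclusion of strand-ambiguous palindromic SNPs.  Every removal is counted
by reason in an audit so that input = retained + Σ removals at each step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import TraitPanel

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default thresholds (genome-wide significance, relaxed fallback, clumping,
#: MAF, instrument strength, palindrome ambiguity band)
DEFAULTS = dict(
    primary_p=5e-8,
    fallback_p=5e-6,
    clump_r2=0.001,
    clump_window_kb=10_000.0,
    min_maf=0.01,
    min_f=10.0,
    ambiguity_band=(0.42, 0.58),
)


@dataclass
class LdReference:
    """Sparse pairwise r² lookup between SNPs.

    Absent pairs are treated as r² = 0 (unlinked); the diagonal is
    implicitly 1.  Keys are stored unordered, queried symmetrically.
    """

    snp_ids: list[str] = field(default_factory=list)
    _r2: dict[frozenset, float] = field(default_factory=dict)

    @classmethod
    def from_pairs(
        cls, pairs: Mapping[tuple[str, str], float] | None = None
    ) -> "LdReference":
        ref = cls()
        for (a, b), r2 in (pairs or {}).items():
            ref.set_r2(a, b, r2)
        return ref

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 must be in [0,1], got {r2}")
        if a == b:
            return
        for s in (a, b):
            if s not in self._seen():
                self.snp_ids.append(s)
        self._r2[frozenset((a, b))] = float(r2)

    def _seen(self) -> set:
        return set(self.snp_ids)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"snp_a": min(k), "snp_b": max(k), "r2": v} for k, v in self._r2.items()
        ]
        rows.sort(key=lambda r: (r["snp_a"], r["snp_b"]))
        return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LdReference":
        return cls.from_pairs(
            {(r.snp_a, r.snp_b): r.r2 for r in df.itertuples(index=False)}
        )


@dataclass(frozen=True)
class InstrumentRecord:
    """Per-SNP instrument strength: variance explained and F-statistic."""

    snp_id: str
    r2_explained: float
    f_stat: float
    r2_formula_used: str  # "eaf_based" | "n_based"
    valid: bool = True


@dataclass
class HarmonizedInstrumentSet:
    """Exposure/outcome-aligned instruments plus a per-step removal audit.

    ``records`` columns: snp_id, beta_exp, se_exp, pval_exp, eaf_exp,
    beta_out, se_out, r2_explained, f_stat.
    """

    exposure_id: str
    outcome_id: str
    records: pd.DataFrame
    audit: dict[str, int] = field(default_factory=dict)
    fallback_used: bool = False
    no_instruments: bool = False

    @property
    def n_snp(self) -> int:
        return len(self.records)


def select_by_pvalue(
    panel: TraitPanel, primary_p: float = 5e-8, fallback_p: float = 5e-6
) -> tuple[pd.DataFrame, bool]:
    """Genome-wide significant SNPs, falling back to the relaxed threshold.

    Returns ``(subset, fallback_used)``.  An empty subset at both thresholds
    is returned empty (the caller records the pair as untestable rather than
    failing).
    """
    if not primary_p < fallback_p:
        raise ValueError("primary_p must be below fallback_p")
    df = panel.data
    hit = df[df.pval < primary_p]
    if len(hit):
        return hit.reset_index(drop=True), False
    hit = df[df.pval < fallback_p]
    if len(hit):
        return hit.reset_index(drop=True), True
    return df.iloc[0:0].reset_index(drop=True), False


def clump(
    snps: pd.DataFrame,
    ld: LdReference,
    clump_r2: float = 0.001,
    window_kb: float = 10_000.0,
) -> pd.DataFrame:
    """Greedy LD clumping: keep the lowest-p SNP of every correlated cluster.

    SNPs are visited in ascending p (ties broken by snp_id); a SNP is kept
    iff its r² with every already-kept SNP on the same chromosome within
    ``window_kb`` (closed interval, base pairs) is ≤ ``clump_r2``.
    """
    window_bp = window_kb * 1000.0
    order = snps.sort_values(["pval", "snp_id"], kind="stable").reset_index(drop=True)
    ids = order.snp_id.to_numpy()
    chroms = order.chrom.to_numpy()
    pos = order.pos.to_numpy(dtype=np.int64)
    kept: list[int] = []
    for i in range(len(order)):
        ok = True
        for j in kept:
            if (
                chroms[j] == chroms[i]
                and abs(int(pos[j]) - int(pos[i])) <= window_bp
                and ld.r2(ids[j], ids[i]) > clump_r2
            ):
                ok = False
                break
        if ok:
            kept.append(i)
    return order.iloc[kept].reset_index(drop=True)


def filter_maf(snps: pd.DataFrame, min_maf: float = 0.01) -> pd.DataFrame:
    """Drop SNPs with minor-allele frequency ≤ ``min_maf`` (boundary excluded).

    SNPs with missing eaf pass with a warning — their frequency cannot be
    judged and instrument strength falls back to the sample-size formula.
    """
    eaf = snps["eaf"]
    maf = np.minimum(eaf, 1.0 - eaf)
    # strict boundary exclusion robust to float representation (0.99 -> 0.01)
    keep = (maf - min_maf > 1e-12) | eaf.isna()
    n_missing = int(eaf.isna().sum())
    if n_missing:
        logger.warning("%d SNPs missing eaf pass the MAF filter unchecked", n_missing)
    return snps[keep].reset_index(drop=True)


def instrument_strength(
    snp_id: str,
    beta: float,
    se: float,
    n: int,
    eaf: float | None = None,
) -> InstrumentRecord:
    """Variance explained and F-statistic for one instrument.

    Uses R² = 2·EAF·(1−EAF)·β² when the allele frequency is available,
    otherwise R² = β²/(β² + SE²·N); F = R²(N−2)/(1−R²).  R² ≥ 1 marks the
    record invalid (betas not on a standardized scale).
    """
    if n < 3:
        raise ValueError("instrument strength needs n >= 3")
    if eaf is not None and np.isfinite(eaf):
        r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
        formula = "eaf_based"
    else:
        r2 = beta**2 / (beta**2 + se**2 * n)
        formula = "n_based"
    if r2 >= 1.0:
        logger.warning("SNP %s has R^2 = %.3f >= 1; flagged invalid", snp_id, r2)
        return InstrumentRecord(snp_id, r2, np.inf, formula, valid=False)
    f = r2 * (n - 2) / (1.0 - r2)
    return InstrumentRecord(snp_id, r2, f, formula)


def _strength_columns(snps: pd.DataFrame) -> pd.DataFrame:
    """Vectorized counterpart of :func:`instrument_strength` over a frame."""
    out = snps.copy()
    eaf, beta, se, n = (out[c].to_numpy() for c in ("eaf", "beta", "se", "n"))
    has_eaf = np.isfinite(eaf)
    r2 = np.where(
        has_eaf,
        2.0 * eaf * (1.0 - eaf) * beta**2,
        beta**2 / (beta**2 + se**2 * n),
    )
    valid = r2 < 1.0
    with np.errstate(divide="ignore"):
        f = np.where(valid, r2 * (n - 2) / (1.0 - r2), np.inf)
    out["r2_explained"] = r2
    out["f_stat"] = f
    out["r2_formula_used"] = np.where(has_eaf, "eaf_based", "n_based")
    out["strength_valid"] = valid
    return out


def is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def harmonize(
    exposure_snps: pd.DataFrame,
    outcome_panel: TraitPanel,
    ambiguity_band: tuple[float, float] = (0.42, 0.58),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Align outcome effects to the exposure's effect allele.

    Rules, per SNP present in both panels:

    * same alleles → keep outcome beta as-is;
    * swapped alleles → flip outcome beta sign (and eaf);
    * complementary-strand codings → complement, then apply the two rules;
    * palindromic pair (A/T or G/C): dropped when either trait's eaf lies in
      the ambiguity band or is missing, since strand cannot be resolved;
    * anything else (mismatched loci) → dropped.
    """
    lo, hi = ambiguity_band
    cols = ["snp_id", "beta_exp", "se_exp", "pval_exp", "eaf_exp", "beta_out", "se_out"]
    audit = {"absent_in_outcome": 0, "palindromic_ambiguous": 0, "allele_mismatch": 0}
    merged = exposure_snps.merge(
        outcome_panel.data, on="snp_id", how="left", suffixes=("", "_o")
    )
    present = merged.beta_o.notna()
    audit["absent_in_outcome"] = int((~present).sum())
    m = merged[present]
    if m.empty:
        return pd.DataFrame(columns=cols), audit

    ea, oa = m.effect_allele.to_numpy(), m.other_allele.to_numpy()
    oea, ooa = m.effect_allele_o.to_numpy(), m.other_allele_o.to_numpy()
    comp = np.vectorize(COMPLEMENT.get)
    cea, coa = comp(oea), comp(ooa)

    palindromic = comp(ea) == oa
    same = (oea == ea) & (ooa == oa)
    swapped = (oea == oa) & (ooa == ea)
    comp_same = (cea == ea) & (coa == oa)
    comp_swapped = (cea == oa) & (coa == ea)

    eaf_e, eaf_o = m.eaf.to_numpy(), m.eaf_o.to_numpy()
    inside_band = lambda f: ~np.isfinite(f) | ((lo < f) & (f < hi))
    ambiguous = palindromic & (inside_band(eaf_e) | inside_band(eaf_o))
    # unambiguous palindrome: orient by which side of 0.5 the frequencies fall
    pal_flip = palindromic & ~ambiguous & ((eaf_e < 0.5) != (eaf_o < 0.5))
    mismatch = ~palindromic & ~(same | swapped | comp_same | comp_swapped)

    audit["palindromic_ambiguous"] = int(ambiguous.sum())
    audit["allele_mismatch"] = int(mismatch.sum())
    keep = ~ambiguous & ~mismatch
    flip = np.where(palindromic, pal_flip, swapped | comp_swapped)

    out = pd.DataFrame(
        {
            "snp_id": m.snp_id.to_numpy(),
            "beta_exp": m.beta.to_numpy(),
            "se_exp": m.se.to_numpy(),
            "pval_exp": m.pval.to_numpy(),
            "eaf_exp": eaf_e,
            "beta_out": np.where(flip, -m.beta_o.to_numpy(), m.beta_o.to_numpy()),
            "se_out": m.se_o.to_numpy(),
        }
    )[keep].reset_index(drop=True)
    return out, audit


def select_instruments(
    exposure: TraitPanel,
    outcome: TraitPanel,
    ld: LdReference | None = None,
    config: Mapping | None = None,
) -> HarmonizedInstrumentSet:
    """Full instrument pipeline: p-threshold → clump → MAF → F → harmonize."""
    cfg = dict(DEFAULTS)
    cfg.update(config or {})
    ld = ld or LdReference()
    audit: dict[str, int] = {"input": len(exposure.data)}

    hits, fallback = select_by_pvalue(exposure, cfg["primary_p"], cfg["fallback_p"])
    audit["below_p_threshold"] = len(exposure.data) - len(hits)
    if hits.empty:
        return HarmonizedInstrumentSet(
            exposure.trait_id,
            outcome.trait_id,
            pd.DataFrame(),
            audit,
            fallback,
            no_instruments=True,
        )

    clumped = clump(hits, ld, cfg["clump_r2"], cfg["clump_window_kb"])
    audit["clumped_away"] = len(hits) - len(clumped)

    maf_ok = filter_maf(clumped, cfg["min_maf"])
    audit["maf_filtered"] = len(clumped) - len(maf_ok)

    strong = _strength_columns(maf_ok)
    keep = strong.strength_valid & (strong.f_stat >= cfg["min_f"])
    audit["weak_or_invalid_f"] = int((~keep).sum())
    strong = strong[keep].reset_index(drop=True)

    harmonized, h_audit = harmonize(strong, outcome, tuple(cfg["ambiguity_band"]))
    audit.update(h_audit)
    audit["retained"] = len(harmonized)

    if not harmonized.empty:
        meta = strong.set_index("snp_id")
        harmonized["r2_explained"] = meta.loc[
            harmonized.snp_id, "r2_explained"
        ].to_numpy()
        harmonized["f_stat"] = meta.loc[harmonized.snp_id, "f_stat"].to_numpy()
        harmonized = harmonized.sort_values("snp_id", kind="stable").reset_index(
            drop=True
        )
    return HarmonizedInstrumentSet(
        exposure.trait_id,
        outcome.trait_id,
        harmonized,
        audit,
        fallback,
        no_instruments=harmonized.empty,
    )
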