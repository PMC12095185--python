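"""Synthetic GWAS summary statistics with a known causal chain.

The generator emulates the statistical structure of two-sample MR inputs:
marginal per-SNP effect estimates with sampling noise, an allele-frequency
spectrum, block LD, and a causal chain exposure → mediator → outcome with
configurable direct and indirect effects and optional horizontal pleiotropy.
Summary statistics are produced directly — no individual-level genotypes —
because two-sample MR consumes only the marginals, and exposure, mediator
and outcome samples are independent (no overlap), matching the two-sample
design.

Effect propagation for an exposure-instrument SNP with exposure effect b:

* mediator effect  = ``beta_xm`` · b
* outcome effect   = ``beta_my`` · ``beta_xm`` · b + ``beta_xy_direct`` · b
  (+ a pleiotropy term when configured)

so the total exposure→outcome effect recoverable by MR is
``beta_xm·beta_my + beta_xy_direct``.  Mediator-specific SNPs instrument the
mediator directly (outcome effect = ``beta_my`` · effect) and are null for
the exposure; they are what makes the mediation step-4 "distinct SNPs"
requirement satisfiable.  Each observed beta is the true effect plus
Gaussian noise with sd equal to its standard error
``1/sqrt(2·n·eaf·(1−eaf))``; noise is block-correlated at ``ld_rho`` within
LD blocks.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LdReference
from .io import TraitPanel, panel_from_arrays

# non-palindromic allele pairs used for ordinary SNPs
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC_PAIRS = [("A", "T"), ("G", "C")]


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of one simulated three-trait study.

    Defaults are the chain used throughout the test-bench: 100 strong
    exposure instruments and 100 mediator-specific instruments, GWAS sample
    sizes of 100 000 per trait, exposure→mediator effect 0.3,
    mediator→outcome effect 0.5 and direct exposure→outcome effect 0.1
    (total effect 0.25, mediated proportion 0.6), no pleiotropy, no LD.
    """

    n_snps: int = 100
    n_mediator_snps: int = 100
    n_exposure: int = 100_000
    n_mediator: int = 100_000
    n_outcome: int = 100_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    effect_range: tuple[float, float] = (0.05, 0.12)
    beta_xm: float = 0.3
    beta_my: float = 0.5
    beta_xy_direct: float = 0.1
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    n_palindromic: int = 0
    ld_block_size: int = 1
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 3:
            raise ValueError("n_snps must be >= 3")
        for n in (self.n_exposure, self.n_mediator, self.n_outcome):
            if n < 1000:
                raise ValueError("sample sizes must be >= 1000")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError("pleiotropy must be none|balanced|directional")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")

    @property
    def total_effect(self) -> float:
        """True exposure→outcome effect on the exposure scale."""
        return self.beta_xm * self.beta_my + self.beta_xy_direct

    @property
    def mediated_proportion(self) -> float:
        return self.beta_xm * self.beta_my / self.total_effect


@dataclass
class SimulatedStudy:
    """Three trait panels sharing one SNP set, plus the generating truth."""

    exposure: TraitPanel
    mediator: TraitPanel
    outcome: TraitPanel
    truth: SimulationConfig
    ld: LdReference

    def truth_manifest(self) -> dict:
        return asdict(self.truth)


def null_config(**overrides) -> SimulationConfig:
    """A configuration with every causal coupling switched off.

    Exposure instruments keep real effects on the exposure (instrument
    relevance holds) but mediator and outcome carry pure sampling noise, so
    any downstream "positive" is a false positive.
    """
    base = dict(beta_xm=0.0, beta_my=0.0, beta_xy_direct=0.0, n_mediator_snps=0)
    base.update(overrides)
    return SimulationConfig(**base)


def _block_noise(
    rng: np.random.Generator, n: int, block_size: int, rho: float
) -> np.ndarray:
    """Standard-normal noise, block-constant correlation rho within blocks."""
    z = rng.standard_normal(n)
    if block_size <= 1 or rho == 0.0:
        return z
    shared = np.repeat(
        rng.standard_normal(int(np.ceil(n / block_size))), block_size
    )[:n]
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * z


def _observed(
    rng: np.random.Generator,
    true_beta: np.ndarray,
    se: np.ndarray,
    block_size: int,
    rho: float,
) -> tuple[np.ndarray, np.ndarray]:
    beta = true_beta + se * _block_noise(rng, len(true_beta), block_size, rho)
    pval = 2.0 * stats.norm.sf(np.abs(beta) / se)
    # p-values of exactly 0 underflow; clamp into the valid domain (0, 1]
    return beta, np.clip(pval, 1e-320, 1.0)


def simulate_chain(config: SimulationConfig) -> SimulatedStudy:
    """Draw one study (exposure, mediator, outcome panels) from the chain model."""
    rng = np.random.default_rng(config.seed)
    n_x, n_m, n_pal = config.n_snps, config.n_mediator_snps, config.n_palindromic
    n_tot = n_x + n_m + n_pal

    snp_id = np.array([f"rs{100000 + i}" for i in range(n_tot)])
    chrom = np.array(["1"] * n_tot)
    # LD blocks of consecutive SNPs; blocks 20 Mb apart (beyond any clumping
    # window), SNPs within a block 5 kb apart
    block = np.arange(n_tot) // config.ld_block_size
    pos = 1_000_000 + block * 20_000_000 + (np.arange(n_tot) % config.ld_block_size) * 5_000

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), n_tot)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    eaf = rng.uniform(*config.maf_range, n_tot)
    if n_pal:
        pal = slice(n_x + n_m, n_tot)
        pi = rng.integers(0, len(_PALINDROMIC_PAIRS), n_pal)
        ea[pal] = [_PALINDROMIC_PAIRS[i][0] for i in pi]
        oa[pal] = [_PALINDROMIC_PAIRS[i][1] for i in pi]
        eaf[pal] = rng.uniform(0.44, 0.56, n_pal)  # inside the ambiguity band

    mag = rng.uniform(*config.effect_range, n_tot)
    sign = rng.choice([-1.0, 1.0], n_tot)
    raw = mag * sign

    bx = np.zeros(n_tot)  # true effect on exposure
    bm = np.zeros(n_tot)  # true effect on mediator
    by = np.zeros(n_tot)  # true effect on outcome
    xi = np.r_[0:n_x, n_x + n_m : n_tot]  # exposure instruments incl. palindromes
    mi = np.arange(n_x, n_x + n_m)  # mediator-specific instruments
    bx[xi] = raw[xi]
    bm[xi] = config.beta_xm * bx[xi]
    by[xi] = config.beta_my * bm[xi] + config.beta_xy_direct * bx[xi]
    bm[mi] = raw[mi]
    by[mi] = config.beta_my * bm[mi]

    # pleiotropy is defined in the orientation with positive exposure effect
    # (the frame Egger regression fits in), so a directional term is a
    # constant intercept there rather than cancelling across allele codings
    if config.pleiotropy == "directional":
        by[xi] += config.pleiotropy_sd * np.sign(bx[xi])
    elif config.pleiotropy == "balanced":
        by[xi] += rng.normal(0.0, config.pleiotropy_sd, len(xi))

    panels = {}
    for name, true_beta, n_samp, tclass in (
        ("exposure", bx, config.n_exposure, "immune_cell"),
        ("mediator", bm, config.n_mediator, "inflammatory_factor"),
        ("outcome", by, config.n_outcome, "disease"),
    ):
        se = 1.0 / np.sqrt(2.0 * n_samp * eaf * (1.0 - eaf))
        beta, pval = _observed(rng, true_beta, se, config.ld_block_size, config.ld_rho)
        panels[name] = panel_from_arrays(
            f"sim_{name}",
            tclass,
            snp_id=snp_id,
            chrom=chrom,
            pos=pos,
            effect_allele=ea,
            other_allele=oa,
            eaf=eaf,
            beta=beta,
            se=se,
            pval=pval,
            n=np.full(n_tot, n_samp),
        )

    ld = LdReference()
    if config.ld_block_size > 1 and config.ld_rho > 0.0:
        r2 = config.ld_rho**2  # genotype correlation rho ⇒ r² = rho²
        for b in np.unique(block):
            members = snp_id[block == b]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    ld.set_r2(members[i], members[j], r2)

    return SimulatedStudy(
        panels["exposure"], panels["mediator"], panels["outcome"], config, ld
    )


def simulate_panel_universe(
    n_immune: int,
    n_inflam: int,
    config: SimulationConfig,
    planted: tuple[int, int] | None = None,
    snps_per_trait: int = 20,
) -> tuple[list[TraitPanel], list[TraitPanel], TraitPanel]:
    """Many factor panels plus one disease panel on a shared SNP universe.

    Every factor trait receives its own block of ``snps_per_trait``
    instrument SNPs; every panel reports marginal statistics for the whole
    universe, so any pair of panels can be harmonized.  All cross-trait and
    trait→disease couplings are zero (pure noise) except, when ``planted``
    names an (immune index, inflammatory index) pair, the chain
    immune → inflammatory → disease with the config's ``beta_xm``,
    ``beta_my`` and ``beta_xy_direct``.

    Returns ``(immune_panels, inflam_panels, disease_panel)``.
    """
    rng = np.random.default_rng(config.seed)
    n_traits = n_immune + n_inflam
    n_tot = n_traits * snps_per_trait
    snp_id = np.array([f"rs{200000 + i}" for i in range(n_tot)])
    chrom = np.array(["1"] * n_tot)
    pos = 1_000_000 + np.arange(n_tot) * 20_000_000  # all mutually unlinked
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), n_tot)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    eaf = rng.uniform(*config.maf_range, n_tot)
    raw = rng.uniform(*config.effect_range, n_tot) * rng.choice([-1.0, 1.0], n_tot)

    def own_slice(t: int) -> slice:
        return slice(t * snps_per_trait, (t + 1) * snps_per_trait)

    # true effect matrix: one row per trait plus the disease row
    true = np.zeros((n_traits + 1, n_tot))
    for t in range(n_traits):
        true[t, own_slice(t)] = raw[own_slice(t)]
    if planted is not None:
        xi, fi = planted[0], n_immune + planted[1]
        bx = true[xi, own_slice(xi)]
        true[fi, own_slice(xi)] = config.beta_xm * bx
        true[-1, own_slice(xi)] = (
            config.beta_my * config.beta_xm + config.beta_xy_direct
        ) * bx
        bm = true[fi, own_slice(fi)]
        true[-1, own_slice(fi)] = config.beta_my * bm

    names = (
        [(f"immune_{i:02d}", "immune_cell", config.n_exposure) for i in range(n_immune)]
        + [(f"inflam_{i:02d}", "inflammatory_factor", config.n_mediator)
           for i in range(n_inflam)]
        + [("disease", "disease", config.n_outcome)]
    )
    panels = []
    for row, (tid, tclass, n_samp) in enumerate(names):
        se = 1.0 / np.sqrt(2.0 * n_samp * eaf * (1.0 - eaf))
        beta, pval = _observed(rng, true[row], se, 1, 0.0)
        panels.append(
            panel_from_arrays(
                tid, tclass,
                snp_id=snp_id, chrom=chrom, pos=pos,
                effect_allele=ea, other_allele=oa, eaf=eaf,
                beta=beta, se=se, pval=pval, n=np.full(n_tot, n_samp),
            )
        )
    return panels[:n_immune], panels[n_immune:-1], panels[-1]


def rescreen_panel(
    study: SimulatedStudy, trait_id: str, trait_class: str, which: str
) -> TraitPanel:
    """Relabel one panel of a study (cascade tests build many named panels)."""
    panel = getattr(study, which)
    return TraitPanel(trait_id, trait_class, panel.data)


def simulate_qpcr_groups(
    group_specs: Sequence[tuple[str, float, float, int]], seed: int = 0
) -> pd.DataFrame:
    """Gaussian replicate fold-changes per group.

    ``group_specs`` rows are ``(label, mean, sd, n_replicates)`` — the shape
    of a qPCR plate with replicate wells.  Returns a tidy frame with columns
    label / replicate / value, reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label, mean, sd, n_rep in group_specs:
        if sd < 0:
            raise ValueError("sd must be >= 0")
        if n_rep < 2:
            raise ValueError("n_replicates must be >= 2")
        values = mean + sd * rng.standard_normal(n_rep)
        rows.extend(
            {"label": label, "replicate": i + 1, "value": v}
            for i, v in enumerate(values)
        )
    return pd.DataFrame(rows, columns=["label", "replicate", "value"])
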