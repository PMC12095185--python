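# Methods

## Model and assumptions

All estimation is two-sample summary-statistic MR. For SNP *i* the inputs
are marginal effect estimates (β̂ˣᵢ, σˣᵢ) on the exposure and (β̂ʸᵢ, σʸᵢ)
on the outcome, from non-overlapping samples. Under the instrumental-variable
assumptions (relevance, independence from confounders, exclusion
restriction) each Wald ratio β̂ʸᵢ/β̂ˣᵢ estimates the same causal effect θ.

**IVW.** The fixed-effect estimate is the precision-weighted mean of the
ratios with weights wᵢ = (β̂ˣᵢ/σʸᵢ)², algebraically identical to
zero-intercept weighted least squares of β̂ʸ on β̂ˣ with weights 1/σʸ².
Cochran's Q = Σwᵢ(ratioᵢ − θ̂)² on n−1 degrees of freedom tests
heterogeneity; when its p < 0.05 the standard error is inflated by
√(Q/(n−1)), floored at 1 (multiplicative random effects; the point
estimate is unchanged). IVW p-values use the normal reference.

**MR-Egger.** Weighted regression of β̂ʸ on β̂ˣ with a free intercept,
after re-orienting SNPs so all β̂ˣ > 0. The slope estimates θ under the
InSIDE assumption; the intercept estimates average directional
pleiotropy. Inference uses t(n−2). The regression itself is delegated to
statsmodels WLS; everything around it is implemented here.

**Weighted median / modes.** The weighted median is the 50th weighted
percentile of the ratio distribution with IVW weights (consistent when
≥50% of weight is valid); the mode estimators take the argmax of a
Gaussian-kernel-smoothed ratio density (unweighted and IVW-weighted),
bandwidth 0.9·min(sd, MAD)·n^(−1/5) times a multiplier φ (default 1).
Standard errors for both come from a parametric bootstrap (default 1000
draws, seeded) resampling β̂ˣ and β̂ʸ from their sampling distributions.

**Instrument filters.** p < 5×10⁻⁸ with 5×10⁻⁶ fallback; greedy clumping
keeps the lowest-p SNP of every cluster with pairwise r² > 0.001 inside a
closed 10,000 kb window (ranking on exposure p, ties broken by SNP id);
MAF > 0.01 strictly (SNPs missing EAF pass with a warning and use the
sample-size R² formula); per-SNP F ≥ 10 with R² from the EAF formula when
EAF is available. Palindromic SNPs are dropped when either trait's EAF
lies in (0.42, 0.58) — the conventional ambiguity band, configurable —
or is missing; outside the band they are oriented by frequency agreement.
The MAF filter is applied on the exposure side (configurable).

## Screening cascade

Positive calls require the gating estimate (IVW) at p < α = 0.05 *and* no
detected directional pleiotropy (Egger-intercept p ≥ α_pleio = 0.05,
testable only with ≥3 instruments). Heterogeneity switches the IVW model
between fixed and random effects but is not itself a gate. Stage-2
double-positivity requires participation in at least one *significant*
(IVW p < α) cross-class MR among same-disease stage-1 positives — the
pleiotropy exclusion is reserved for the disease-facing screens where the
causal claim is made. Stage 3 re-screens double-positives against the
disease. Screening is nominal (no multiplicity correction) by default,
matching batch-screening practice; Bonferroni/Benjamini-Hochberg can be
enabled per stage-1 family.

**Power structure.** Each disease-facing screen of a genuinely causal,
pleiotropy-free pair passes with probability ≈ 0.95: IVW power is ~1 at
the bench conditions, but the Egger-intercept gate is an exact 5%-level
test and fires on 5% of clean nulls. A planted chain must clear two such
gates (its immune cell and its inflammatory factor), bounding unique
recovery at ≈ 0.95² ≈ 0.90 before decoy false-survival (~2–3% at nominal
α with five decoy panels) is subtracted; the realized unique-recovery
rate is therefore ≈ 0.87–0.90, and single-screen positive rates ≈ 0.95.
Tightening α_pleio raises recovery at the cost of pleiotropy-detection
power; the defaults keep both tests at the conventional 5%.

## Mediation decomposition

β_all from exposure→outcome MR; β₁ from exposure→mediator; β₂ from
mediator→outcome using the mediator's instruments minus every SNP in the
β₁ instrument set, so the two coefficients rest on distinct instruments.
The indirect effect β₁₂ = β₁β₂ carries the first-order delta-method
variance β₁²se₂² + β₂²se₁² (the covariance term vanishes under the
distinct-instrument two-sample design); β_dir = β_all − β₁₂ by the
difference method, making the decomposition identity exact by
construction; Z = β₁₂/β_all with var(Z) = var(β₁₂)/β_all² +
β₁₂²·var(β_all)/β_all⁴. Z is reported even outside [0, 1], flagged as
inconsistent mediation. Verdicts: IVW and Egger both significant →
*supported*; IVW alone → *ivw_only* (IVW is the final judgment when the
methods disagree); neither, but both decomposition steps significant in
both methods → *stepwise_direction* with sign(β₁)·sign(β₂); otherwise
*rejected*.

**Reverse causation.** The default gate runs outcome→exposure MR on the
outcome's instruments *excluding* the forward instrument set and requires
p ≥ 0.05. The exclusion matters: in a true causal chain the exposure's
SNPs are outcome-associated through the chain, and reusing them would
flag every genuine forward effect as reverse-causal. A Steiger-style
gate (forward instruments must explain more exposure variance than
reverse instruments explain outcome variance) is available as a stricter
option.

## Synthetic data

The simulator emits summary statistics directly — two-sample MR consumes
only marginals, so no individual-level genotypes are generated — with
exposure, mediator and outcome samples independent (no overlap).
Per-SNP exposure effects have magnitudes uniform on (0.05, 0.12) with
random signs (strong instruments: the weakest SNP at MAF 0.1 and
n = 100,000 has z ≈ 6.7); EAF is uniform on the configured MAF range
(default 0.1–0.5); the standard error is 1/√(2n·EAF·(1−EAF)); the
observed beta is the true beta plus Gaussian noise with that sd. Mediator
effects are β_xm times the exposure effect for exposure instruments;
mediator-specific SNPs (a separate block, default equal in number) carry
their own effects and are what makes the distinct-instrument step of the
mediation satisfiable. Outcome effects follow the chain
β_my·(mediator effect) + β_xy_direct·(exposure effect). Directional
pleiotropy adds a constant to outcome effects *in the orientation with
positive exposure effect* (the frame Egger fits in); balanced pleiotropy
adds zero-mean Gaussian terms. LD is block-constant: genotype correlation
ρ within consecutive blocks (noise correlated at ρ, reference r² = ρ²),
zero between blocks, with blocks placed 20 Mb apart so clumping windows
never span blocks. Defaults are the chain β_xm = 0.3, β_my = 0.5,
β_xy_direct = 0.1 (total 0.25, mediated proportion 0.6), 100 + 100
instruments, n = 100,000 per GWAS.

The multi-panel generator (`simulate_panel_universe`) builds many factor
panels on one shared SNP universe — each trait owns a disjoint
instrument block, all cross-trait couplings null except one optionally
planted chain — because cascade screening harmonizes arbitrary panel
pairs. The planted-chain recovery experiments use complete mediation
(direct effect 0, β_xm = β_my = 0.5, n = 500,000, 4 immune + 3
inflammatory panels of 20 SNPs each): with a nonzero direct path the
mediator's disease screen faces genuine horizontal pleiotropy and the
Egger gate correctly rejects it, which is realistic but defeats a
recovery oracle.

What the simulator does **not** emulate: realistic human LD maps,
allele-frequency/effect-size coupling, sample overlap, case-control
ascertainment, winner's-curse–free replication panels, or polygenic
confounding. Passing tests therefore demonstrate correctness of the
estimators and the screening logic under the stated generative model,
not robustness to every failure mode of real GWAS data.

## qPCR and group statistics

2^−ΔΔCt: ΔCt = target Ct − reference-gene Ct per replicate, ΔΔCt = ΔCt −
calibrator ΔCt, fold change 2^−ΔΔCt. Group comparisons use the
equal-variance pooled two-sample t (the published p-values back-calculate
to the t(n₁+n₂−2) reference, not Welch); printed "0.000" p-values are
read as < 0.0005. LSD-t uses the one-way-ANOVA pooled mean-square error
across all groups with df = Σ(nᵢ−1) and no multiplicity correction, and
reduces exactly to the pooled t for two groups. Published group rows
whose printed t cannot be reproduced from their printed mean ± SD
(rounding beyond ±0.01, and one row inconsistent with any two-sample t)
are documented and excluded from the reproduction set.

## Numerical choices

All p-values are two-sided, clamped to (0, 1]. Simulated p-values are
floored at 1e-320 to stay in the valid domain. The MAF boundary test uses
a 1e-12 tolerance so that EAF 0.99 is excluded at min_maf 0.01 despite
float representation. Wald ratios use the first-order se σʸ/|β̂ˣ|
(adequate within 5% of the exact sd when the instrument z-score exceeds
10). Bootstrap and simulation seeds always flow from caller-supplied
seeds; identical seeds give byte-identical outputs. Degenerate inputs:
zero instruments yield explicit "no instruments" states rather than
errors; zero pooled variance with equal means gives t = 0, p = 1;
β_all ≈ 0 leaves the mediated proportion undefined with a reason.

## Known limitations

No MR-PRESSO outlier correction, multivariable MR, or
contamination-mixture models; the direct effect uses the difference
method only; the LD reference is always supplied (no reference-panel
computation); binary-trait betas are treated as log-odds without
liability-scale conversion.
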