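import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrcascade import (
    LdReference,
    SimulationConfig,
    clump,
    filter_maf,
    harmonize,
    instrument_strength,
    select_by_pvalue,
    select_instruments,
    simulate_chain,
)

from conftest import make_panel


# ---------------------------------------------------------------- p threshold
def test_primary_threshold_no_fallback(small_panel):
    subset, fallback = select_by_pvalue(small_panel)
    assert len(subset) == 3 and not fallback


def test_fallback_threshold_engaged():
    panel = make_panel([{"pval": 1e-7}, {"pval": 4e-6}, {"pval": 0.2}])
    subset, fallback = select_by_pvalue(panel)
    assert fallback and len(subset) == 2


def test_no_instruments_at_either_threshold():
    panel = make_panel([{"pval": 1e-3}, {"pval": 0.5}])
    subset, fallback = select_by_pvalue(panel)
    assert subset.empty and not fallback


def test_threshold_ordering_enforced(small_panel):
    with pytest.raises(ValueError):
        select_by_pvalue(small_panel, primary_p=1e-5, fallback_p=1e-8)


# -------------------------------------------------------------------- clumping
def test_linked_pair_keeps_lower_p():
    panel = make_panel(
        [{"snp_id": "rs_a", "pval": 1e-9, "pos": 1000},
         {"snp_id": "rs_b", "pval": 1e-8, "pos": 2000}]
    )
    ld = LdReference.from_pairs({("rs_a", "rs_b"): 1.0})
    kept = clump(panel.data, ld)
    assert list(kept.snp_id) == ["rs_a"]


def test_different_chromosomes_never_clumped():
    panel = make_panel(
        [{"snp_id": "rs_a", "chrom": "1", "pval": 1e-9, "pos": 1000},
         {"snp_id": "rs_b", "chrom": "2", "pval": 1e-8, "pos": 1000}]
    )
    ld = LdReference.from_pairs({("rs_a", "rs_b"): 1.0})
    assert len(clump(panel.data, ld)) == 2


def test_window_semantics_closed_interval():
    # 10,000 kb apart exactly: still inside the closed window -> clumped
    panel = make_panel(
        [{"snp_id": "rs_a", "pval": 1e-9, "pos": 1},
         {"snp_id": "rs_b", "pval": 1e-8, "pos": 1 + 10_000_000},
         {"snp_id": "rs_c", "pval": 1e-8, "pos": 2 + 10_000_000}]
    )
    ld = LdReference.from_pairs({("rs_a", "rs_b"): 1.0, ("rs_a", "rs_c"): 1.0})
    kept = clump(panel.data, ld)
    assert list(kept.snp_id) == ["rs_a", "rs_c"]


def _greedy_oracle(df, ld, clump_r2=0.001, window_bp=1e7):
    """Independent restatement of the clumping rule: a SNP survives iff no
    surviving SNP with smaller (p, snp_id) conflicts with it."""
    rows = sorted(df.itertuples(index=False), key=lambda r: (r.pval, r.snp_id))
    surviving = []
    for r in rows:
        conflict = any(
            s.chrom == r.chrom
            and abs(int(s.pos) - int(r.pos)) <= window_bp
            and ld.r2(s.snp_id, r.snp_id) > clump_r2
            for s in surviving
        )
        if not conflict:
            surviving.append(r)
    return [s.snp_id for s in surviving]


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_clump_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 50
    rows = []
    for i in range(n):
        rows.append(
            {
                "snp_id": f"rs{i:03d}",
                "chrom": str(rng.integers(1, 3)),
                "pos": int(rng.integers(1, 3e7)),
                "pval": float(rng.uniform(1e-12, 1e-6)),
            }
        )
    panel = make_panel(rows)
    ld = LdReference()
    ids = panel.data.snp_id.tolist()
    for _ in range(120):
        a, b = rng.choice(ids, 2, replace=False)
        ld.set_r2(a, b, float(rng.uniform(0, 1)))
    kept = clump(panel.data, ld)
    assert list(kept.snp_id) == _greedy_oracle(panel.data, ld)


# ------------------------------------------------------------------ MAF filter
@pytest.mark.parametrize(
    "eaf,retained",
    [(0.005, False), (0.99, False), (0.01, False), (0.3, True), (0.011, True)],
)
def test_maf_filter_boundaries(eaf, retained):
    panel = make_panel([{"eaf": eaf}])
    assert (len(filter_maf(panel.data)) == 1) == retained


def test_missing_eaf_passes_maf_filter():
    panel = make_panel([{"eaf": np.nan}])
    assert len(filter_maf(panel.data)) == 1


# ---------------------------------------------------------- instrument strength
def test_strength_eaf_closed_form():
    rec = instrument_strength("rs1", beta=1.0, se=0.1, n=102, eaf=0.5)
    assert rec.r2_formula_used == "eaf_based"
    assert rec.r2_explained == pytest.approx(0.5)
    assert rec.f_stat == pytest.approx(100.0)


def test_strength_n_based_hand_arithmetic():
    rec = instrument_strength("rs1", beta=0.1, se=0.01, n=10_000, eaf=None)
    assert rec.r2_formula_used == "n_based"
    assert rec.r2_explained == pytest.approx(0.01 / (0.01 + 0.0001 * 10_000))
    expected_f = rec.r2_explained * 9998 / (1 - rec.r2_explained)
    assert rec.f_stat == pytest.approx(expected_f)
    # R^2 = 1/101 exactly, so F = (1/101)*9998/(100/101) = 99.98
    assert rec.f_stat == pytest.approx(99.98, abs=0.01)


def test_zero_beta_zero_f():
    rec = instrument_strength("rs1", beta=0.0, se=0.01, n=1000, eaf=0.3)
    assert rec.r2_explained == 0.0 and rec.f_stat == 0.0


def test_unstandardized_betas_flagged_invalid():
    rec = instrument_strength("rs1", beta=5.0, se=0.1, n=1000, eaf=0.5)
    assert not rec.valid


@given(
    beta=st.floats(0.01, 0.5),
    se=st.floats(0.001, 0.1),
    n=st.integers(1000, 500_000),
    eaf=st.floats(0.01, 0.99),
)
@settings(max_examples=50, deadline=None)
def test_f_consistent_with_r2(beta, se, n, eaf):
    rec = instrument_strength("rs1", beta, se, n, eaf)
    if rec.valid:
        assert rec.f_stat == pytest.approx(
            rec.r2_explained * (n - 2) / (1 - rec.r2_explained), abs=1e-9
        )


# ---------------------------------------------------------------- harmonization
def _exposure_df():
    return make_panel(
        [
            {"snp_id": "rs1", "effect_allele": "A", "other_allele": "G",
             "eaf": 0.3, "beta": 0.1},
            {"snp_id": "rs2", "effect_allele": "C", "other_allele": "T",
             "eaf": 0.2, "beta": 0.2},
        ],
        trait_class="immune_cell",
    ).data


def test_swapped_alleles_flip_outcome_beta():
    outcome = make_panel(
        [{"snp_id": "rs1", "effect_allele": "G", "other_allele": "A",
          "eaf": 0.7, "beta": 0.2},
         {"snp_id": "rs2", "effect_allele": "C", "other_allele": "T",
          "eaf": 0.2, "beta": 0.05}]
    )
    rec, audit = harmonize(_exposure_df(), outcome)
    assert rec.set_index("snp_id").loc["rs1", "beta_out"] == pytest.approx(-0.2)
    assert rec.set_index("snp_id").loc["rs2", "beta_out"] == pytest.approx(0.05)


def test_palindromic_ambiguous_dropped():
    exposure = make_panel(
        [{"snp_id": "rs1", "effect_allele": "A", "other_allele": "T", "eaf": 0.50}]
    ).data
    outcome = make_panel(
        [{"snp_id": "rs1", "effect_allele": "A", "other_allele": "T", "eaf": 0.50}]
    )
    rec, audit = harmonize(exposure, outcome)
    assert rec.empty and audit["palindromic_ambiguous"] == 1


def test_palindromic_outside_band_retained():
    exposure = make_panel(
        [{"snp_id": "rs1", "effect_allele": "A", "other_allele": "T", "eaf": 0.10}]
    ).data
    outcome = make_panel(
        [{"snp_id": "rs1", "effect_allele": "A", "other_allele": "T",
          "eaf": 0.12, "beta": 0.3}]
    )
    rec, _ = harmonize(exposure, outcome)
    assert len(rec) == 1 and rec.beta_out.iloc[0] == pytest.approx(0.3)


def test_identity_outcome_panel_is_noop():
    exposure = _exposure_df()
    outcome = make_panel(exposure.to_dict("records"))
    rec, audit = harmonize(exposure, outcome)
    assert np.allclose(rec.beta_out, exposure.set_index("snp_id").loc[rec.snp_id].beta)
    assert sum(audit.values()) == 0


def test_complementary_strand_coding_resolved():
    exposure = _exposure_df()  # rs1: A/G
    outcome = make_panel(
        [{"snp_id": "rs1", "effect_allele": "T", "other_allele": "C",
          "eaf": 0.3, "beta": 0.15},
         {"snp_id": "rs2", "effect_allele": "A", "other_allele": "G",
          "eaf": 0.8, "beta": 0.15}]
    )
    rec, audit = harmonize(exposure, outcome)
    by = rec.set_index("snp_id").beta_out
    assert by.loc["rs1"] == pytest.approx(0.15)  # same orientation via complement
    assert by.loc["rs2"] == pytest.approx(-0.15)  # complement gives swapped -> flip
    assert audit["allele_mismatch"] == 0


def test_mismatched_loci_dropped():
    outcome = make_panel(
        [{"snp_id": "rs1", "effect_allele": "A", "other_allele": "C", "beta": 0.1}]
    )
    rec, audit = harmonize(_exposure_df(), outcome)
    assert audit["allele_mismatch"] == 1


# --------------------------------------------------------------- full pipeline
def test_full_pipeline_invariants(chain_study):
    hset = select_instruments(chain_study.exposure, chain_study.outcome, chain_study.ld)
    rec = hset.records
    assert not hset.no_instruments
    assert (rec.f_stat >= 10).all()
    maf = np.minimum(rec.eaf_exp, 1 - rec.eaf_exp)
    assert (maf > 0.01).all()
    assert (rec.pval_exp < 5e-8).all()
    for i in range(len(rec)):
        for j in range(i + 1, len(rec)):
            assert chain_study.ld.r2(rec.snp_id[i], rec.snp_id[j]) <= 0.001


def test_audit_conservation(chain_study):
    hset = select_instruments(chain_study.exposure, chain_study.outcome, chain_study.ld)
    a = hset.audit
    removed = (
        a["below_p_threshold"] + a["clumped_away"] + a["maf_filtered"]
        + a["weak_or_invalid_f"] + a["absent_in_outcome"]
        + a["palindromic_ambiguous"] + a["allele_mismatch"]
    )
    assert a["input"] == removed + a["retained"]


def test_row_order_invariance(chain_study):
    from mrcascade import TraitPanel

    shuffled = TraitPanel(
        chain_study.exposure.trait_id,
        chain_study.exposure.trait_class,
        chain_study.exposure.data.sample(frac=1.0, random_state=1),
    )
    a = select_instruments(chain_study.exposure, chain_study.outcome, chain_study.ld)
    b = select_instruments(shuffled, chain_study.outcome, chain_study.ld)
    assert list(a.records.snp_id) == list(b.records.snp_id)


def test_strand_flip_invariance(chain_study):
    """Recoding the outcome panel to the complementary strand changes nothing."""
    from mrcascade import TraitPanel
    from mrcascade.instruments import COMPLEMENT

    flipped_df = chain_study.outcome.data.copy()
    flipped_df["effect_allele"] = flipped_df.effect_allele.map(COMPLEMENT)
    flipped_df["other_allele"] = flipped_df.other_allele.map(COMPLEMENT)
    flipped = TraitPanel("sim_outcome", "disease", flipped_df)
    a = select_instruments(chain_study.exposure, chain_study.outcome, chain_study.ld)
    b = select_instruments(chain_study.exposure, flipped, chain_study.ld)
    assert list(a.records.snp_id) == list(b.records.snp_id)
    assert np.allclose(a.records.beta_out, b.records.beta_out)


def test_palindromes_removed_from_pipeline():
    study = simulate_chain(SimulationConfig(seed=21, n_palindromic=8))
    hset = select_instruments(study.exposure, study.outcome, study.ld)
    rec = hset.records
    assert hset.audit["palindromic_ambiguous"] > 0
    exp = study.exposure.data.set_index("snp_id")
    for snp in rec.snp_id:
        pair = {exp.loc[snp].effect_allele, exp.loc[snp].other_allele}
        assert pair not in ({"A", "T"}, {"G", "C"})


def test_block_ld_prunes_to_one_per_block():
    study = simulate_chain(
        SimulationConfig(seed=22, n_snps=30, n_mediator_snps=0,
                         ld_block_size=5, ld_rho=0.95)
    )
    hset = select_instruments(study.exposure, study.outcome, study.ld)
    # 30 SNPs in 6 blocks of 5 at r2 = 0.9 > 0.001 -> at most one SNP per block
    blocks = hset.records.snp_id.str.slice(2).astype(int).apply(
        lambda i: (i - 100000) // 5
    )
    assert blocks.is_unique
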