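import numpy as np
import pandas as pd
import pytest

from mrcascade import SimulationConfig, TraitPanel, simulate_chain


@pytest.fixture(scope="session")
def chain_study():
    """One simulated X -> M -> Y study at the default study conditions."""
    return simulate_chain(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def null_study():
    """Relevant exposure instruments, but no causal path to the outcome."""
    from mrcascade import null_config

    return simulate_chain(null_config(seed=12, n_snps=30))


def make_panel(rows, trait_id="trait", trait_class="disease") -> TraitPanel:
    """Panel from a list of dicts; omitted fields get sensible defaults."""
    defaults = dict(
        chrom="1",
        pos=1000,
        effect_allele="A",
        other_allele="G",
        eaf=0.3,
        beta=0.1,
        se=0.01,
        pval=1e-9,
        n=50_000,
    )
    records = []
    for i, row in enumerate(rows):
        rec = dict(defaults, snp_id=f"rs{i}", pos=1000 + 20_000_000 * i)
        rec.update(row)
        records.append(rec)
    return TraitPanel(trait_id, trait_class, pd.DataFrame(records))


@pytest.fixture
def small_panel():
    return make_panel(
        [
            {"snp_id": "rs1", "beta": 0.08, "pval": 1e-12},
            {"snp_id": "rs2", "beta": 0.06, "pval": 1e-10},
            {"snp_id": "rs3", "beta": 0.07, "pval": 1e-11},
        ],
        trait_id="exposure",
        trait_class="immune_cell",
    )
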