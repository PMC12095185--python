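"""Assemble accepted mediation triples into a pathway network and export it.

Builds the published 8 + 12 = 20 pathway structure from its printed labels
(no estimation involved) and a small estimated network from simulated
mediation results, then exports both.
"""

from pathlib import Path

from mrcascade import (
    SimulationConfig,
    build_network,
    export_network,
    mediate,
    network_from_labels,
    simulate_chain,
)

out = Path("scratch/example_network")

# estimated network from one simulated triple
study = simulate_chain(SimulationConfig(seed=5))
m = mediate(study.exposure, study.mediator, study.outcome, study.ld)
classes = {
    "sim_exposure": "immune_cell",
    "sim_mediator": "inflammatory_factor",
    "sim_outcome": "disease",
}
net = build_network([m], classes)
export_network(net, out / "estimated.tsv", "tsv")
export_network(net, out / "estimated.graphml", "graphml")
print(f"estimated network: {len(net)} edge(s), counts {net.per_disease_counts}")

# structural twin of the published tables
rows_fwd = [("FSC-A on Natural Killer T", "LIF", "AA"),
            ("CCR7 on naive CD8+ T cell", "HGF", "MDS")]
rows_rev = [("TSLP", "CD11b on basophil", "AML")]
fwd = network_from_labels(rows_fwd, "immune_to_inflam_to_disease")
rev = network_from_labels(rows_rev, "inflam_to_immune_to_disease")
fwd.edges = fwd.edges + rev.edges
print(f"label-only network: {len(fwd)} edges, per-disease {fwd.per_disease_counts}")
print(f"exports written under {out}/")
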