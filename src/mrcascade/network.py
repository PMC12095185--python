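"""Assembly and export of exposure→mediator→disease pathway networks.

Each accepted mediation triple becomes one directed two-hop pathway edge;
the network tallies pathways per disease and per direction pattern
(immune cell → inflammatory factor → disease, or the reverse ordering of
the two factor classes).  Node identity is the accession-like trait_id —
display names of similar cell subsets collide, accessions do not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .mediation import MediationResult

DIRECTION_PATTERNS = {
    ("immune_cell", "inflammatory_factor"): "immune_to_inflam_to_disease",
    ("inflammatory_factor", "immune_cell"): "inflam_to_immune_to_disease",
}

EDGE_COLUMNS = [
    "source_id",
    "source_class",
    "mediator_id",
    "mediator_class",
    "disease_id",
    "direction_pattern",
    "beta_all",
    "beta12",
    "beta_dir",
    "z",
    "verdict",
]


@dataclass(frozen=True)
class PathwayEdge:
    """One two-hop causal pathway source → mediator → disease."""

    source_id: str
    source_class: str
    mediator_id: str
    mediator_class: str
    disease_id: str
    direction_pattern: str
    beta_all: float
    beta12: float
    beta_dir: float
    z: float | None
    verdict: str


@dataclass
class PathwayNetwork:
    """Deduplicated, deterministically ordered pathway edges with tallies."""

    edges: list[PathwayEdge] = field(default_factory=list)

    @property
    def per_disease_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.edges:
            counts[e.disease_id] = counts.get(e.disease_id, 0) + 1
        return counts

    @property
    def per_direction_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.edges:
            counts[e.direction_pattern] = counts.get(e.direction_pattern, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.edges], columns=EDGE_COLUMNS)

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for e in self.edges:
            g.add_node(e.source_id, trait_class=e.source_class)
            g.add_node(e.mediator_id, trait_class=e.mediator_class)
            g.add_node(e.disease_id, trait_class="disease")
            g.add_edge(e.source_id, e.mediator_id, disease=e.disease_id)
            g.add_edge(e.mediator_id, e.disease_id, disease=e.disease_id)
        return g


def build_network(
    mediations: list[MediationResult],
    classes: dict[str, str],
) -> PathwayNetwork:
    """Assemble accepted (verdict ≠ rejected) mediation triples into a network.

    ``classes`` maps trait_id → trait_class; triples whose source/mediator
    classes coincide or are unknown are rejected with a warning entry.
    """
    edges: dict[tuple, PathwayEdge] = {}
    for m in mediations:
        if m.verdict == "rejected":
            continue
        s_cls = classes.get(m.exposure_id)
        m_cls = classes.get(m.mediator_id)
        pattern = DIRECTION_PATTERNS.get((s_cls, m_cls))
        if pattern is None:
            import logging

            logging.getLogger(__name__).warning(
                "edge %s->%s->%s rejected: class labels (%s, %s) invalid",
                m.exposure_id,
                m.mediator_id,
                m.outcome_id,
                s_cls,
                m_cls,
            )
            continue
        key = (m.exposure_id, m.mediator_id, m.outcome_id)
        edges[key] = PathwayEdge(
            m.exposure_id,
            s_cls,
            m.mediator_id,
            m_cls,
            m.outcome_id,
            pattern,
            m.beta_all.beta,
            m.beta12.beta,
            m.beta_dir.beta,
            m.z,
            m.verdict,
        )
    ordered = [edges[k] for k in sorted(edges)]
    return PathwayNetwork(ordered)


def network_from_labels(
    rows: list[tuple[str, str, str]], direction: str
) -> PathwayNetwork:
    """Build a label-only network from printed (source, mediator, disease)
    rows — structural ingestion with no estimation (effect fields are NaN)."""
    if direction not in DIRECTION_PATTERNS.values():
        raise ValueError(f"unknown direction pattern {direction!r}")
    s_cls, m_cls = next(
        k for k, v in DIRECTION_PATTERNS.items() if v == direction
    )
    edges = [
        PathwayEdge(s, s_cls, m, m_cls, d, direction, float("nan"), float("nan"),
                    float("nan"), None, "supported")
        for s, m, d in rows
    ]
    return PathwayNetwork(edges)


def export_network(net: PathwayNetwork, path: str | Path, format: str = "tsv") -> None:
    """Write the network as tsv, json, or graphml (lossless for edge fields)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        net.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")
    elif format == "json":
        payload = {
            "edges": [e.__dict__ for e in net.edges],
            "per_disease_counts": net.per_disease_counts,
            "per_direction_counts": net.per_direction_counts,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "graphml":
        nx.write_graphml(net.to_graph(), path)
    else:
        raise ValueError(f"unknown network export format {format!r}")


def import_network(path: str | Path, format: str = "tsv") -> PathwayNetwork:
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        rows = df.to_dict("records")
    elif format == "json":
        rows = json.loads(path.read_text())["edges"]
    else:
        raise ValueError(f"unknown network import format {format!r}")
    edges = []
    for r in rows:
        z = r.get("z")
        z = None if z is None or (isinstance(z, float) and pd.isna(z)) else float(z)
        edges.append(
            PathwayEdge(
                r["source_id"],
                r["source_class"],
                r["mediator_id"],
                r["mediator_class"],
                r["disease_id"],
                r["direction_pattern"],
                float(r["beta_all"]),
                float(r["beta12"]),
                float(r["beta_dir"]),
                z,
                r["verdict"],
            )
        )
    return PathwayNetwork(edges)
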