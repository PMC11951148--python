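"""Sequence similarity network construction and clustering.

The expensive step — all-vs-all optimal local alignment — is done once
into an :class:`EdgeTable` holding every unordered pair with positive
alignment score AS = -log10(E).  Networks at any threshold are then
cheap to rebuild: keep edges with AS >= threshold, take connected
components, and call components of size 1 singletons.  Every retained
sequence is a node (no representative-sequence collapsing), because
singleton counting at full resolution is the point of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import networkx as nx
import pandas as pd

from ssnmine.align import ScoringScheme, align_local, alignment_score
from ssnmine.seqio import SeqRecord


@dataclass
class EdgeTable:
    """All-vs-all alignment scores between retained sequences.

    ``frame`` columns: ``id_a``, ``id_b``, ``alignment_score``,
    ``percent_identity``; one row per unordered pair with AS > 0,
    ``id_a < id_b``, rows sorted lexicographically.  ``roster`` lists
    every node id, including sequences isolated at every threshold.
    """

    frame: pd.DataFrame
    roster: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        roster_set = set(self.roster)
        for col in ("id_a", "id_b"):
            missing = set(self.frame[col]) - roster_set
            if missing:
                raise ValueError(f"edge ids missing from roster: {sorted(missing)[:3]}")
        if (self.frame["id_a"] >= self.frame["id_b"]).any():
            raise ValueError("edge rows must satisfy id_a < id_b (no self-pairs)")
        if (self.frame["alignment_score"] < 0).any():
            raise ValueError("alignment scores must be >= 0")
        if self.frame.duplicated(subset=["id_a", "id_b"]).any():
            raise ValueError("duplicate unordered pair in edge table")

    @property
    def max_score(self) -> float:
        return float(self.frame["alignment_score"].max()) if len(self.frame) else 0.0

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, roster: Optional[Sequence[str]] = None) -> "EdgeTable":
        frame = pd.read_csv(path, sep="\t")
        if roster is None:
            roster = sorted(set(frame["id_a"]) | set(frame["id_b"]))
        return cls(frame=frame, roster=list(roster))


@dataclass
class Network:
    """An SSN at a fixed alignment-score threshold."""

    threshold: float
    graph: nx.Graph
    components: List[frozenset]
    singletons: List[str]

    @property
    def nodes(self) -> List[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ClusterSummary:
    """Composition of one connected component."""

    component_id: int
    size: int
    members: List[str]
    reference_count: int
    label_composition: Dict[str, int]
    clade_composition: Dict[str, int]
    purity: Optional[float]


def compute_edges(
    records: Sequence[SeqRecord], scheme: Optional[ScoringScheme] = None
) -> EdgeTable:
    """Align all N(N-1)/2 unordered pairs and tabulate AS > 0 edges.

    Deterministic; rows are emitted in lexicographic (id_a, id_b)
    order.  This is the pipeline's dominant cost (quadratic in N).
    """
    if not records:
        raise ValueError("at least one record is required")
    scheme = scheme or ScoringScheme()
    recs = sorted(records, key=lambda r: r.id)
    rows = []
    for i, a in enumerate(recs):
        for b in recs[i + 1 :]:
            res = align_local(a, b, scheme)
            as_score = alignment_score(res)
            if as_score > 0:
                rows.append(
                    {
                        "id_a": a.id,
                        "id_b": b.id,
                        "alignment_score": as_score,
                        "percent_identity": res.percent_identity,
                    }
                )
    frame = pd.DataFrame(rows, columns=["id_a", "id_b", "alignment_score", "percent_identity"])
    return EdgeTable(frame=frame, roster=[r.id for r in recs])


def build_network(edges: EdgeTable, threshold: float) -> Network:
    """Threshold the edge table and extract connected components.

    Keeps edges with AS >= threshold; nodes with no surviving edge are
    singletons.  Components are sorted by size descending, ties by
    smallest member id, so output order is deterministic.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    g = nx.Graph()
    g.add_nodes_from(edges.roster)
    kept = edges.frame[edges.frame["alignment_score"] >= threshold]
    for row in kept.itertuples(index=False):
        g.add_edge(row.id_a, row.id_b, alignment_score=row.alignment_score,
                   percent_identity=row.percent_identity)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    singletons = sorted(n for c in comps if len(c) == 1 for n in c)
    return Network(threshold=threshold, graph=g, components=comps, singletons=singletons)


def summarize_clusters(
    net: Network, records: Sequence[SeqRecord], top_k: int = 4
) -> tuple[List[ClusterSummary], Dict[str, float]]:
    """Per-component composition plus global coverage statistics.

    Returns one :class:`ClusterSummary` per component (size
    descending) and a dict of global statistics: the fraction of all
    nodes, and of reference nodes, contained in the ``top_k`` largest
    clusters, plus singleton counts.
    """
    by_id = {r.id: r for r in records}
    summaries = []
    for ci, comp in enumerate(net.components):
        members = sorted(comp)
        labels: Dict[str, int] = {}
        clades: Dict[str, int] = {}
        for m in members:
            rec = by_id.get(m)
            if rec is None:
                continue
            if rec.label is not None:
                labels[rec.label] = labels.get(rec.label, 0) + 1
            clade = rec.clade if rec.clade is not None else "unassigned"
            clades[clade] = clades.get(clade, 0) + 1
        ref_count = sum(labels.values())
        purity = max(labels.values()) / ref_count if ref_count else None
        summaries.append(
            ClusterSummary(
                component_id=ci,
                size=len(members),
                members=members,
                reference_count=ref_count,
                label_composition=dict(sorted(labels.items())),
                clade_composition=dict(sorted(clades.items())),
                purity=purity,
            )
        )
    n_nodes = sum(s.size for s in summaries)
    n_refs = sum(s.reference_count for s in summaries)
    top = summaries[:top_k]
    stats = {
        "n_nodes": float(n_nodes),
        "n_components": float(len(summaries)),
        "n_singletons": float(len(net.singletons)),
        "frac_nodes_in_top_clusters": (sum(s.size for s in top) / n_nodes) if n_nodes else 0.0,
        "frac_references_in_top_clusters": (
            sum(s.reference_count for s in top) / n_refs if n_refs else 0.0
        ),
    }
    return summaries, stats


def clade_cluster_table(
    net: Network, records: Sequence[SeqRecord]
) -> pd.DataFrame:
    """Per-clade node counts per component (long format)."""
    by_id = {r.id: r for r in records}
    rows = []
    for ci, comp in enumerate(net.components):
        counts: Dict[str, int] = {}
        for m in sorted(comp):
            rec = by_id.get(m)
            clade = rec.clade if rec is not None and rec.clade else "unassigned"
            counts[clade] = counts.get(clade, 0) + 1
        for clade, n in sorted(counts.items()):
            rows.append({"component_id": ci, "clade": clade, "count": n})
    return pd.DataFrame(rows, columns=["component_id", "clade", "count"])


def export_graphml(net: Network, records: Sequence[SeqRecord], path: str | Path) -> None:
    """Write the thresholded network as GraphML with node metadata."""
    by_id = {r.id: r for r in records}
    g = nx.Graph()
    for node in sorted(net.graph.nodes):
        rec = by_id.get(node)
        attrs = {}
        if rec is not None:
            attrs = {
                "label": rec.label or "",
                "clade": rec.clade or "",
                "species": rec.species or "",
                "is_reference": rec.is_reference,
                "length": rec.length,
            }
        g.add_node(node, **attrs)
    for a, b, data in sorted(net.graph.edges(data=True)):
        g.add_edge(a, b, **data)
    nx.write_graphml(g, str(path))


def export_node_edge_tsv(
    net: Network, records: Sequence[SeqRecord], node_path: str | Path, edge_path: str | Path
) -> None:
    """Spreadsheet-friendly two-file export of the thresholded network."""
    by_id = {r.id: r for r in records}
    comp_of = {n: ci for ci, comp in enumerate(net.components) for n in comp}
    node_rows = []
    for node in sorted(net.graph.nodes):
        rec = by_id.get(node)
        node_rows.append(
            {
                "id": node,
                "component_id": comp_of[node],
                "degree": net.graph.degree(node),
                "label": (rec.label or "") if rec else "",
                "clade": (rec.clade or "") if rec else "",
                "species": (rec.species or "") if rec else "",
                "is_reference": rec.is_reference if rec else False,
            }
        )
    pd.DataFrame(node_rows).to_csv(node_path, sep="\t", index=False)
    edge_rows = [
        {"id_a": a, "id_b": b, **data} for a, b, data in sorted(net.graph.edges(data=True))
    ]
    pd.DataFrame(edge_rows, columns=["id_a", "id_b", "alignment_score", "percent_identity"]).to_csv(
        edge_path, sep="\t", index=False, float_format="%.6g"
    )
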