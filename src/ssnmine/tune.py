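"""Reference-guided alignment-score threshold selection.

An SSN threshold that is too low merges enzymes with different
products into one cluster (functional mixing); one that is too high
splits isofunctional enzymes into lineage-specific clusters
(phylogenetic fragmentation).  This module formalises that trade-off
over the labelled reference nodes:

* ``functional_mixing`` M(t): fraction of different-label reference
  pairs that share a component at threshold t.  Component-based on
  purpose: two families can merge through unlabelled intermediates
  without a single direct cross-label edge, and a cluster containing
  two products is exactly the failure mode being guarded against.
  Nonincreasing in t; 0 when no cross-label pair exists.
* ``edge_mixing``: the edge-level variant (fraction of surviving
  reference-reference edges joining different labels); reported for
  diagnostics, NaN when no reference edge survives.
* ``same_label_cohesion`` C(t): fraction of same-label reference pairs
  that land in the same component; nonincreasing in t.
* ``phylo_fragmentation`` F(t): fraction of labels whose references
  are split over more than one component (reported, not optimised —
  C already penalises splitting).

``select_threshold`` picks, among thresholds with mixing at or below
the tolerance, the one with maximal cohesion, breaking ties toward the
smaller threshold.  With the default tolerance 0 this returns the
smallest threshold at which no cluster mixes two product labels.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Optional, Sequence

import pandas as pd

from ssnmine.seqio import SeqRecord
from ssnmine.ssn import EdgeTable, build_network


def sweep(
    edges: EdgeTable, records: Sequence[SeqRecord], thresholds: Sequence[float]
) -> pd.DataFrame:
    """Evaluate network statistics at each threshold.

    One row per threshold with columns ``threshold``, ``n_edges``,
    ``n_components``, ``n_singletons``, ``functional_mixing``,
    ``edge_mixing``, ``same_label_cohesion``, ``phylo_fragmentation``.
    ``edge_mixing`` is NaN where no reference-reference edge survives.
    Requires at least one labelled reference among *records*.
    """
    if not len(thresholds):
        raise ValueError("thresholds must be nonempty")
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    label_of = {r.id: r.label for r in records if r.label is not None and r.id in set(edges.roster)}
    if not label_of:
        raise ValueError("no reference (labelled) nodes: sweep metrics are undefined")
    labels = sorted(set(label_of.values()))
    ref_ids = sorted(label_of)
    same_label_pairs = [
        (a, b) for a, b in combinations(ref_ids, 2) if label_of[a] == label_of[b]
    ]
    cross_label_pairs = [
        (a, b) for a, b in combinations(ref_ids, 2) if label_of[a] != label_of[b]
    ]

    rows = []
    for t in thresholds:
        net = build_network(edges, t)
        comp_of = {n: ci for ci, comp in enumerate(net.components) for n in comp}
        if cross_label_pairs:
            mixing = sum(
                1 for a, b in cross_label_pairs if comp_of[a] == comp_of[b]
            ) / len(cross_label_pairs)
        else:
            mixing = 0.0
        ref_edges = [
            (a, b) for a, b in net.graph.edges if a in label_of and b in label_of
        ]
        if ref_edges:
            edge_mixing = sum(
                1 for a, b in ref_edges if label_of[a] != label_of[b]
            ) / len(ref_edges)
        else:
            edge_mixing = math.nan
        if same_label_pairs:
            cohesion = sum(
                1 for a, b in same_label_pairs if comp_of[a] == comp_of[b]
            ) / len(same_label_pairs)
        else:
            cohesion = 0.0
        split = 0
        for lab in labels:
            comps = {comp_of[i] for i, l in label_of.items() if l == lab}
            if len(comps) > 1:
                split += 1
        rows.append(
            {
                "threshold": t,
                "n_edges": net.n_edges,
                "n_components": len(net.components),
                "n_singletons": len(net.singletons),
                "functional_mixing": mixing,
                "edge_mixing": edge_mixing,
                "same_label_cohesion": cohesion,
                "phylo_fragmentation": split / len(labels),
            }
        )
    return pd.DataFrame(rows)


def select_threshold(metrics: pd.DataFrame, mixing_tolerance: float = 0.0) -> float:
    """Pick the operating threshold from sweep metrics.

    Feasible thresholds have functional mixing at or below
    ``mixing_tolerance`` (an undefined mixing — no reference edges —
    counts as no observed mixing).  Among feasible thresholds the one
    with maximal cohesion wins; ties go to the smaller threshold.
    Raises if no threshold is feasible, reporting the best achievable
    mixing.
    """
    m = metrics["functional_mixing"]
    feasible = metrics[m.isna() | (m <= mixing_tolerance)]
    if feasible.empty:
        raise ValueError(
            "no threshold satisfies the mixing tolerance "
            f"{mixing_tolerance}; minimum achieved mixing is {m.min():.4f}"
        )
    best_cohesion = feasible["same_label_cohesion"].max()
    winners = feasible[feasible["same_label_cohesion"] == best_cohesion]
    return float(winners["threshold"].iloc[0])
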