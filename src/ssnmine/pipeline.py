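"""End-to-end pipeline orchestration.

Runs harvest -> all-vs-all edges -> threshold sweep/selection ->
network build -> cluster summaries -> candidate ranking, writing every
intermediate artifact plus a run manifest (config echo, input
checksums, per-stage row counts) into an output directory.  The
pipeline proper contains no randomness: identical inputs and
configuration produce byte-identical outputs.  A ``.partial`` marker
file is present in the output directory while a run is incomplete.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from ssnmine import __version__
from ssnmine.align import ScoringScheme
from ssnmine.harvest import HarvestConfig, run_harvest
from ssnmine.novelty import (
    DEFAULT_MOTIFS,
    candidates_to_frame,
    clade_stats,
    load_motif_table,
    rank_candidates,
)
from ssnmine.phmm import load_hmm
from ssnmine.seqio import MetadataTable, attach_metadata, read_fasta, write_fasta
from ssnmine.ssn import (
    build_network,
    clade_cluster_table,
    compute_edges,
    export_graphml,
    export_node_edge_tsv,
    summarize_clusters,
)
from ssnmine.tune import select_threshold, sweep

logger = logging.getLogger("ssnmine")


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run.

    ``thresholds`` is the sweep grid; if ``fixed_threshold`` is set the
    sweep is skipped and that value used directly.  An empty
    ``thresholds`` with no fixed threshold means: sweep 20 evenly
    spaced values over the observed alignment-score range.
    """

    database: Path
    baits: Path
    outdir: Path
    metadata: Optional[Path] = None
    hmm_files: List[Path] = field(default_factory=list)
    motif_file: Optional[Path] = None
    harvest: HarvestConfig = field(default_factory=HarvestConfig)
    thresholds: List[float] = field(default_factory=list)
    fixed_threshold: Optional[float] = None
    mixing_tolerance: float = 0.0
    clade_allowlist: Optional[set] = None
    top_k_clusters: int = 4

    def validate(self) -> None:
        for p in [self.database, self.baits, self.metadata, self.motif_file, *self.hmm_files]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    """Read a plain-text ``key = value`` config file with sections.

    Sections: ``[paths]`` (database, baits, metadata, outdir, hmms —
    comma-separated, motifs), ``[harvest]``, ``[ssn]``, ``[tune]``,
    ``[novelty]``.  Unknown keys are rejected to catch typos.
    """
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    paths = parser["paths"]
    base = Path(path).parent

    def _p(key):
        val = paths.get(key)
        if val is None or not val.strip():
            return None
        p = Path(val.strip())
        return p if p.is_absolute() else base / p

    known_harvest = {
        "similarity_evalue_cutoff": float, "psi_iterations": int,
        "hmm_evalue_cutoff": float, "min_length": int, "strategies": str,
        "psi_pseudocount_weight": float, "combine": str, "hmm_bit_cutoff": float,
    }
    hkw = {}
    if parser.has_section("harvest"):
        for key, raw in parser["harvest"].items():
            if key not in known_harvest:
                raise ValueError(f"unknown [harvest] key: {key}")
            if key == "strategies":
                hkw[key] = tuple(s.strip() for s in raw.split(",") if s.strip())
            else:
                hkw[key] = known_harvest[key](raw)
    cfg = PipelineConfig(
        database=_p("database"),
        baits=_p("baits"),
        outdir=_p("outdir") or base / "out",
        metadata=_p("metadata"),
        hmm_files=[
            (Path(s.strip()) if Path(s.strip()).is_absolute() else base / s.strip())
            for s in paths.get("hmms", "").split(",") if s.strip()
        ],
        motif_file=_p("motifs"),
        harvest=HarvestConfig(**hkw),
    )
    if parser.has_section("ssn"):
        ssn_sec = parser["ssn"]
        if "thresholds" in ssn_sec:
            cfg.thresholds = [float(s) for s in ssn_sec["thresholds"].split(",") if s.strip()]
        if "fixed_threshold" in ssn_sec:
            cfg.fixed_threshold = float(ssn_sec["fixed_threshold"])
    if parser.has_section("tune"):
        cfg.mixing_tolerance = parser["tune"].getfloat("mixing_tolerance", 0.0)
    if parser.has_section("novelty"):
        allow = parser["novelty"].get("clade_allowlist", "").strip()
        if allow:
            cfg.clade_allowlist = {s.strip() for s in allow.split(",")}
    return cfg


def run_pipeline(config: PipelineConfig, scheme: Optional[ScoringScheme] = None) -> dict:
    """Execute every stage and write artifacts to ``config.outdir``.

    Returns the manifest dict (also written as ``manifest.json``).
    Raises on the first failing stage, leaving the ``.partial`` marker
    in place so interrupted runs are recognisable.
    """
    config.validate()
    scheme = scheme or ScoringScheme()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / ".partial"
    marker.write_text("run in progress or aborted\n")

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest = {
        "version": __version__,
        "inputs": {},
        "config": {
            "harvest": {
                "similarity_evalue_cutoff": config.harvest.similarity_evalue_cutoff,
                "psi_iterations": config.harvest.psi_iterations,
                "hmm_evalue_cutoff": config.harvest.hmm_evalue_cutoff,
                "min_length": config.harvest.min_length,
                "strategies": list(config.harvest.strategies),
                "combine": config.harvest.combine,
            },
            "thresholds": config.thresholds,
            "fixed_threshold": config.fixed_threshold,
            "mixing_tolerance": config.mixing_tolerance,
            "clade_allowlist": sorted(config.clade_allowlist) if config.clade_allowlist else None,
        },
        "stages": {},
    }
    try:
        stage = "load"
        for name, p in [("database", config.database), ("baits", config.baits),
                        ("metadata", config.metadata)]:
            if p is not None:
                manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}
        database = read_fasta(config.database)
        baits = read_fasta(config.baits)
        if config.metadata is not None:
            table = MetadataTable.from_tsv(config.metadata)
            database = attach_metadata(database, table)
            baits = attach_metadata(baits, table)
        hmms = [load_hmm(p) for p in config.hmm_files]
        motifs = list(DEFAULT_MOTIFS)
        if config.motif_file is not None:
            motifs = load_motif_table(config.motif_file)
        logger.info("loaded %d database, %d bait, %d HMM inputs",
                    len(database), len(baits), len(hmms))

        stage = "harvest"
        hconfig = config.harvest
        if not hmms and "domain" in hconfig.strategies:
            from dataclasses import replace as _replace
            hconfig = _replace(
                hconfig,
                strategies=tuple(s for s in hconfig.strategies if s != "domain"),
            )
            logger.warning("no HMMs supplied; domain strategy disabled")
        result = run_harvest(hconfig, baits, database, hmms or None, scheme)
        by_id = {r.id: r for r in database}
        retained = [by_id[i] for i in result.retained_ids]
        write_fasta(retained, outdir / "retained.fasta")
        result.membership.reset_index().to_csv(outdir / "membership.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(result.venn.items()), columns=["strategies", "count"]
        ).to_csv(outdir / "venn.tsv", sep="\t", index=False)
        manifest["stages"]["harvest"] = {
            "hits": len(result.hit_ids),
            "retained": len(result.retained_ids),
            "too_short": sum(1 for s in result.status.values() if s == "too_short"),
            "venn": result.venn,
            "bait_length_range": list(result.bait_length_range),
        }
        logger.info("harvest: %d hits, %d retained", len(result.hit_ids),
                    len(result.retained_ids))

        stage = "edges"
        # references not already in the database join the network as nodes
        node_records = list(retained)
        node_ids = {r.id for r in node_records}
        for b in baits:
            if b.id not in node_ids:
                node_records.append(b)
                node_ids.add(b.id)
        edges = compute_edges(node_records, scheme)
        edges.to_tsv(outdir / "edges.tsv")
        manifest["stages"]["edges"] = {"nodes": len(edges.roster), "rows": len(edges.frame)}

        stage = "tune"
        if config.fixed_threshold is not None:
            threshold = float(config.fixed_threshold)
            manifest["stages"]["tune"] = {"mode": "fixed", "threshold": threshold}
        else:
            grid = config.thresholds
            if not grid:
                top = edges.max_score
                grid = list(np.round(np.linspace(0.0, top, 21)[1:], 6))
            metrics = sweep(edges, node_records, sorted(grid))
            metrics.to_csv(outdir / "sweep.tsv", sep="\t", index=False,
                           float_format="%.6g")
            threshold = select_threshold(metrics, config.mixing_tolerance)
            row = metrics[metrics["threshold"] == threshold].iloc[0].to_dict()
            manifest["stages"]["tune"] = {"mode": "sweep", "threshold": threshold,
                                          "selected_row": {k: (None if pd.isna(v) else v)
                                                           for k, v in row.items()}}
            logger.info("selected alignment-score threshold %.3f", threshold)

        stage = "network"
        net = build_network(edges, threshold)
        export_graphml(net, node_records, outdir / "network.graphml")
        export_node_edge_tsv(net, node_records, outdir / "nodes.tsv",
                             outdir / "network_edges.tsv")
        summaries, stats = summarize_clusters(net, node_records, config.top_k_clusters)
        pd.DataFrame(
            [
                {
                    "component_id": s.component_id,
                    "size": s.size,
                    "reference_count": s.reference_count,
                    "purity": "" if s.purity is None else round(s.purity, 6),
                    "labels": ";".join(f"{k}:{v}" for k, v in s.label_composition.items()),
                    "clades": ";".join(f"{k}:{v}" for k, v in s.clade_composition.items()),
                }
                for s in summaries
            ]
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        clade_cluster_table(net, node_records).to_csv(
            outdir / "clade_clusters.tsv", sep="\t", index=False)
        manifest["stages"]["network"] = {
            "threshold": threshold,
            "edges": net.n_edges,
            "components": len(net.components),
            "singletons": len(net.singletons),
            **{k: round(v, 6) for k, v in stats.items()},
        }

        stage = "candidates"
        references = [r for r in node_records if r.is_reference]
        reports, summary = rank_candidates(
            set(net.singletons), node_records, references, scheme,
            clade_allowlist=config.clade_allowlist, motifs=motifs,
        )
        candidates_to_frame(reports).to_csv(outdir / "candidates.tsv", sep="\t",
                                            index=False, float_format="%.6g")
        clade_stats(node_records).to_csv(outdir / "clade_stats.tsv", sep="\t",
                                         index=False, float_format="%.6g")
        singleton_records = [r for r in node_records if r.id in set(net.singletons)]
        if singleton_records:
            clade_stats(singleton_records).to_csv(
                outdir / "clade_stats_singletons.tsv", sep="\t", index=False,
                float_format="%.6g")
        manifest["stages"]["candidates"] = dict(summary)
        logger.info(
            "%d singletons: %d reference, %d uncharacterized",
            summary["singletons"], summary["reference_singletons"],
            summary["uncharacterized"],
        )

        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        marker.unlink()
        return manifest
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
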