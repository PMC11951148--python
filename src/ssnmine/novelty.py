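"""Singleton-based novelty candidate ranking.

Singletons — nodes unconnected at the chosen alignment-score threshold
— are the prime candidates for functional novelty.  This module turns
them into a ranked report: distance to the nearest characterised
reference (percent identity; lower = more novel), optional clade
filtering, conserved-motif anomaly checks, and per-clade descriptive
statistics that expose lineage overrepresentation among singletons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set

import pandas as pd

from ssnmine.align import ScoringScheme, align_local, alignment_score
from ssnmine.seqio import SeqRecord


@dataclass(frozen=True)
class MotifSpec:
    """A short conserved motif to screen candidates against.

    ``max_mismatches`` is the largest number of substitutions in the
    best-matching window before the motif is reported as not found.
    """

    name: str
    consensus: str
    max_mismatches: int = 2

    def __post_init__(self) -> None:
        if not (3 <= len(self.consensus) <= 30):
            raise ValueError("motif consensus must be 3-30 residues")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


#: The one motif named in the source material for oxidosqualene
#: cyclases; users supply their own catalogue for other families.
DEFAULT_MOTIFS = (MotifSpec(name="MWCYCR", consensus="MWCYCR", max_mismatches=2),)


@dataclass(frozen=True)
class MotifAnomaly:
    """Deviation of a candidate's best motif window from the consensus."""

    motif_name: str
    expected: str
    observed: Optional[str]
    offset: Optional[int]  # 1-based start of the best window
    substitutions: tuple  # of "C3Y"-style strings (consensus pos within motif)
    found: bool


@dataclass
class CandidateReport:
    """Novelty evidence for one singleton."""

    id: str
    clade: Optional[str]
    max_ref_identity: float
    nearest_ref: Optional[str]
    max_ref_alignment_score: float
    motif_anomalies: List[MotifAnomaly] = field(default_factory=list)
    passes_clade_filter: bool = True
    rank: int = 0


def motif_check(candidate: SeqRecord, motifs: Iterable[MotifSpec]) -> List[MotifAnomaly]:
    """Locate each motif's best-matching window and report deviations.

    The window with the fewest mismatches wins (ties -> leftmost); if
    even the best window exceeds ``max_mismatches`` the motif is
    reported as not found.  An exact match yields an anomaly record
    with an empty substitution list.  Position-independent: prepending
    residues shifts the reported offset and nothing else.
    """
    out = []
    seq = candidate.residues
    for motif in motifs:
        k = len(motif.consensus)
        if len(seq) < k:
            out.append(MotifAnomaly(motif.name, motif.consensus, None, None, (), False))
            continue
        best_mm, best_pos = k + 1, None
        for pos in range(len(seq) - k + 1):
            mm = sum(1 for a, b in zip(motif.consensus, seq[pos : pos + k]) if a != b)
            if mm < best_mm:
                best_mm, best_pos = mm, pos
                if mm == 0:
                    break
        if best_mm > motif.max_mismatches:
            out.append(MotifAnomaly(motif.name, motif.consensus, None, None, (), False))
            continue
        window = seq[best_pos : best_pos + k]
        subs = tuple(
            f"{a}{i + 1}{b}" for i, (a, b) in enumerate(zip(motif.consensus, window)) if a != b
        )
        out.append(
            MotifAnomaly(motif.name, motif.consensus, window, best_pos + 1, subs, True)
        )
    return out


def load_motif_table(path: str | Path) -> List[MotifSpec]:
    """Read motif specs from a TSV with columns name, consensus, max_mismatches."""
    frame = pd.read_csv(path, sep="\t")
    return [
        MotifSpec(str(r["name"]), str(r["consensus"]), int(r.get("max_mismatches", 2)))
        for _, r in frame.iterrows()
    ]


def rank_candidates(
    singletons: Set[str],
    records: Sequence[SeqRecord],
    references: Sequence[SeqRecord],
    scheme: Optional[ScoringScheme] = None,
    clade_allowlist: Optional[Set[str]] = None,
    motifs: Iterable[MotifSpec] = DEFAULT_MOTIFS,
) -> tuple[List[CandidateReport], Dict[str, int]]:
    """Rank uncharacterised singletons by distance to the references.

    Singletons that are themselves references are dropped from the
    report but counted in the returned summary
    (``{"singletons": n, "reference_singletons": r,
    "uncharacterized": n - r}``).  Candidates are ranked ascending by
    maximum percent identity to any reference — the most novel first —
    with ties broken by id.  A clade allowlist, if given, restricts
    the report to those clades.
    """
    if not references:
        raise ValueError("reference set must be nonempty")
    scheme = scheme or ScoringScheme()
    by_id = {r.id: r for r in records}
    ref_ids = {r.id for r in references}
    singleton_ids = sorted(singletons)
    n_ref_singletons = sum(1 for s in singleton_ids if s in ref_ids)
    summary = {
        "singletons": len(singleton_ids),
        "reference_singletons": n_ref_singletons,
        "uncharacterized": len(singleton_ids) - n_ref_singletons,
    }

    reports: List[CandidateReport] = []
    for sid in singleton_ids:
        if sid in ref_ids:
            continue
        rec = by_id.get(sid)
        if rec is None:
            warnings.warn(f"singleton {sid!r} has no sequence record; skipped", stacklevel=2)
            continue
        if clade_allowlist is not None and rec.clade not in clade_allowlist:
            continue
        best_pid, best_as, best_ref = 0.0, 0.0, None
        for ref in references:
            res = align_local(rec, ref, scheme)
            if res.percent_identity > best_pid or best_ref is None:
                best_pid, best_ref = res.percent_identity, ref.id
            best_as = max(best_as, alignment_score(res))
        reports.append(
            CandidateReport(
                id=sid,
                clade=rec.clade,
                max_ref_identity=best_pid,
                nearest_ref=best_ref,
                max_ref_alignment_score=best_as,
                motif_anomalies=motif_check(rec, motifs),
                passes_clade_filter=True,
            )
        )
    reports.sort(key=lambda r: (r.max_ref_identity, r.id))
    for i, rep in enumerate(reports):
        rep.rank = i + 1
    return reports, summary


def candidates_to_frame(reports: Sequence[CandidateReport]) -> pd.DataFrame:
    """Flatten candidate reports for TSV export."""
    rows = []
    for r in reports:
        anomalies = ";".join(
            f"{a.motif_name}:{','.join(a.substitutions) or 'exact'}" if a.found
            else f"{a.motif_name}:not_found"
            for a in r.motif_anomalies
        )
        rows.append(
            {
                "rank": r.rank,
                "id": r.id,
                "clade": r.clade or "",
                "max_ref_identity": r.max_ref_identity,
                "nearest_ref": r.nearest_ref or "",
                "max_ref_alignment_score": r.max_ref_alignment_score,
                "motif_anomalies": anomalies,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank", "id", "clade", "max_ref_identity", "nearest_ref",
            "max_ref_alignment_score", "motif_anomalies",
        ],
    )


def clade_stats(records: Sequence[SeqRecord]) -> pd.DataFrame:
    """Per-clade sequence counts, species counts and sequences/species.

    Records without a clade are counted under ``unassigned`` with a
    warning.  Row counts sum to the number of input records.  Run on
    the full set and again on the singleton subset to expose lineage
    overrepresentation among singletons.
    """
    n_missing = sum(1 for r in records if not r.clade)
    if n_missing:
        warnings.warn(f"{n_missing} record(s) without clade counted as 'unassigned'",
                      stacklevel=2)
    per_clade: Dict[str, Dict] = {}
    for rec in records:
        clade = rec.clade or "unassigned"
        entry = per_clade.setdefault(clade, {"sequences": 0, "species": set()})
        entry["sequences"] += 1
        if rec.species:
            entry["species"].add(rec.species)
    rows = []
    for clade in sorted(per_clade):
        n_seq = per_clade[clade]["sequences"]
        n_sp = len(per_clade[clade]["species"])
        rows.append(
            {
                "clade": clade,
                "sequences": n_seq,
                "species": n_sp,
                "sequences_per_species": (n_seq / n_sp) if n_sp else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["clade", "sequences", "species", "sequences_per_species"])
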