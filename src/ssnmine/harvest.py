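"""Dual-strategy sequence harvesting with fragment filtering.

Mines a sequence database for family members by combining up to three
search strategies and taking their union:

* ``similarity`` — pairwise local alignment against every bait; a
  database sequence is a hit iff its best E-value against any bait is
  at or below the cutoff.
* ``profile_similarity`` — PSI-style iterated search: each round
  builds, per bait, a position-specific scoring matrix from the
  bait-anchored alignments of the current hits (observed counts mixed
  with BLOSUM-derived pseudocounts) and rescreens the database with
  the same local-alignment machinery.  More sensitive to divergent
  family members than single-query search.
* ``domain`` — profile-HMM presence calls for each supplied domain
  model.

Hits shorter than ``min_length`` are excluded as fragments after the
union; the boundary is inclusive (a hit of exactly ``min_length``
residues is retained).  The per-strategy overlap is reported as a Venn
summary whose cells partition the union of hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Set

import numpy as np
import pandas as pd

from ssnmine.align import (
    ScoringScheme,
    align_local,
    anchored_residues,
    blosum_conditional,
    log10_evalue,
    residue_indices,
    sw_score_positional,
)
from ssnmine.phmm import ProfileHMM, domain_present
from ssnmine.seqio import ALPHABET, AMINO20, SeqRecord

STRATEGIES = ("similarity", "profile_similarity", "domain")


@dataclass(frozen=True)
class HarvestConfig:
    """Cutoffs and strategy selection for a harvest run.

    ``similarity_evalue_cutoff`` and ``hmm_evalue_cutoff`` default to
    1e-100 and 1e-30 respectively; ``min_length`` (default 700)
    excludes truncated transcript-derived fragments.  These defaults
    suit full-length multi-domain enzymes of ~730-790 residues; for
    shorter proteins scale them down together with the reference
    length range the run report prints.
    """

    similarity_evalue_cutoff: float = 1e-100
    psi_iterations: int = 1
    hmm_evalue_cutoff: float = 1e-30
    min_length: int = 700
    strategies: tuple = ("similarity", "profile_similarity", "domain")
    psi_pseudocount_weight: float = 0.5
    hmm_bit_cutoff: Optional[float] = None
    combine: str = "union"

    def __post_init__(self) -> None:
        if self.similarity_evalue_cutoff <= 0 or self.hmm_evalue_cutoff <= 0:
            raise ValueError("E-value cutoffs must be positive")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.psi_iterations < 0:
            raise ValueError("psi_iterations must be >= 0")
        bad = [s for s in self.strategies if s not in STRATEGIES]
        if bad:
            raise ValueError(f"unknown strategies: {bad}")
        if not self.strategies:
            raise ValueError("at least one strategy must be enabled")
        if self.combine not in ("union", "intersection"):
            raise ValueError("combine must be 'union' or 'intersection'")


@dataclass
class HarvestResult:
    """Outcome of a harvest run.

    ``membership`` is a boolean DataFrame (index = every database id
    that hit at least one strategy, one column per enabled strategy).
    ``status`` maps every database id to ``retained``, ``too_short``
    or ``no_hit``.  ``venn`` counts hits per strategy combination and
    partitions the union.  ``bait_length_range`` is the (min, max)
    bait length, reported so users can justify ``min_length``.
    """

    membership: pd.DataFrame
    status: Dict[str, str]
    retained_ids: list
    venn: Dict[str, int]
    bait_length_range: tuple
    best_evalue: Dict[str, float] = field(default_factory=dict)
    best_bait: Dict[str, str] = field(default_factory=dict)

    @property
    def hit_ids(self) -> Set[str]:
        return set(self.membership.index)


def similarity_search(
    baits: Sequence[SeqRecord],
    database: Sequence[SeqRecord],
    scheme: Optional[ScoringScheme] = None,
    evalue_cutoff: float = 1e-100,
) -> Dict[str, tuple]:
    """Pairwise-similarity hits: id -> (best bait id, best E-value).

    A database sequence is a hit iff the minimum over baits of the
    local-alignment E-value is <= ``evalue_cutoff``.  Loosening the
    cutoff can only grow the hit set.
    """
    if not baits:
        raise ValueError("bait set must be nonempty")
    scheme = scheme or ScoringScheme()
    hits: Dict[str, tuple] = {}
    for rec in database:
        best_lg, best_bait = math.inf, None
        for bait in baits:
            lg = align_local(bait, rec, scheme).log10_evalue
            if lg < best_lg:
                best_lg, best_bait = lg, bait.id
        if best_lg <= math.log10(evalue_cutoff):
            hits[rec.id] = (best_bait, 10.0 ** best_lg)
    return hits


def _bait_profile(
    bait: SeqRecord,
    hit_records: Sequence[SeqRecord],
    scheme: ScoringScheme,
    pseudocount_weight: float,
) -> np.ndarray:
    """Position-specific scoring matrix anchored on the bait.

    Aligns every hit to the bait and projects aligned residues onto
    bait coordinates; column probabilities are observed counts mixed
    with BLOSUM-derived pseudocounts, converted to log-odds scores on
    the Karlin-Altschul scale of the scheme (so the scheme's lambda
    and kappa remain approximately applicable).  X column scores 0.
    """
    from ssnmine.align import BACKGROUND_FREQS

    m = bait.length
    counts = np.zeros((m, 20))
    aa_index = {a: i for i, a in enumerate(AMINO20)}
    # the bait always supports its own profile
    for pos, c in enumerate(bait.residues):
        if c in aa_index:
            counts[pos, aa_index[c]] += 1.0
    for rec in hit_records:
        if rec.id == bait.id:
            continue
        for pos, c in enumerate(anchored_residues(bait, rec, scheme)):
            if c is not None and c in aa_index:
                counts[pos, aa_index[c]] += 1.0
    bg = np.array([BACKGROUND_FREQS[a] for a in AMINO20])
    cond = blosum_conditional()
    w = pseudocount_weight
    pssm = np.zeros((m, len(ALPHABET)))
    for pos in range(m):
        n_obs = counts[pos].sum()
        if n_obs == 0:
            continue
        freq = counts[pos] / n_obs
        pseudo = freq @ cond  # BLOSUM-implied neighbour distribution
        q = (counts[pos] + w * n_obs * pseudo) / (n_obs + w * n_obs)
        q = np.maximum(q, 1e-9)
        pssm[pos, :20] = np.log(q / bg) / scheme.ka_lambda
    return pssm


def profile_search(
    baits: Sequence[SeqRecord],
    database: Sequence[SeqRecord],
    scheme: Optional[ScoringScheme] = None,
    evalue_cutoff: float = 1e-100,
    iterations: int = 1,
    pseudocount_weight: float = 0.5,
) -> Set[str]:
    """PSI-style iterated profile search.

    Round 0 is :func:`similarity_search`; each later round rebuilds a
    per-bait PSSM from the current hits and rescreens the database.
    The returned hit set is by construction a superset of round 0 and
    grows monotonically with ``iterations``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    scheme = scheme or ScoringScheme()
    db_by_id = {r.id: r for r in database}
    hits = set(similarity_search(baits, database, scheme, evalue_cutoff))
    log_cutoff = math.log10(evalue_cutoff)
    db_indices = {r.id: residue_indices(r.residues) for r in database}
    for _ in range(iterations):
        hit_records = [db_by_id[i] for i in sorted(hits)]
        new_hits = set(hits)
        for bait in baits:
            pssm = _bait_profile(bait, hit_records, scheme, pseudocount_weight)
            for rec in database:
                if rec.id in new_hits:
                    continue
                raw = sw_score_positional(
                    pssm, db_indices[rec.id], scheme.gap_open, scheme.gap_extend
                )
                if log10_evalue(max(raw, 0.0), bait.length, rec.length, scheme) <= log_cutoff:
                    new_hits.add(rec.id)
        if new_hits == hits:
            break
        hits = new_hits
    return hits


def domain_search(
    hmms: Sequence[ProfileHMM],
    database: Sequence[SeqRecord],
    evalue_cutoff: Optional[float] = 1e-30,
    bit_cutoff: Optional[float] = None,
    similarity_hits: Optional[Set[str]] = None,
) -> tuple:
    """Per-HMM domain presence over the database.

    Returns ``(per_hmm_hits, lacking)`` where ``per_hmm_hits`` maps
    HMM name -> id set and ``lacking`` accounts, over
    ``similarity_hits`` (or the whole database if not given), how many
    sequences lack each individual domain and how many lack all.
    """
    if not hmms:
        raise ValueError("at least one HMM is required")
    per_hmm: Dict[str, Set[str]] = {}
    for hmm in hmms:
        present = set()
        for rec in database:
            hit = domain_present(hmm, rec, evalue_cutoff=evalue_cutoff, bit_cutoff=bit_cutoff)
            if hit.present:
                present.add(rec.id)
        per_hmm[hmm.name] = present
    pool = similarity_hits if similarity_hits is not None else {r.id for r in database}
    lacking = {f"lacking_{name}": len(pool - ids) for name, ids in per_hmm.items()}
    lacking["lacking_all"] = len(pool - set.union(*per_hmm.values()))
    return per_hmm, lacking


def _venn(membership: pd.DataFrame) -> Dict[str, int]:
    cells: Dict[str, int] = {}
    strategies = list(membership.columns)
    for _, row in membership.iterrows():
        combo = "+".join(s for s in strategies if row[s])
        cells[combo] = cells.get(combo, 0) + 1
    return cells


def run_harvest(
    config: HarvestConfig,
    baits: Sequence[SeqRecord],
    database: Sequence[SeqRecord],
    hmms: Optional[Sequence[ProfileHMM]] = None,
    scheme: Optional[ScoringScheme] = None,
) -> HarvestResult:
    """Execute the enabled strategies, combine hits and filter fragments.

    Candidates are the union of strategy hits by default
    (``config.combine = 'intersection'`` restricts to sequences found
    by every enabled strategy); the length filter then removes hits
    shorter than ``config.min_length``.  Deterministic given inputs.
    """
    scheme = scheme or ScoringScheme()
    if "domain" in config.strategies and not hmms:
        raise ValueError("domain strategy enabled but no HMMs supplied")
    enabled = [s for s in config.strategies]

    per_strategy: Dict[str, Set[str]] = {}
    best_ev: Dict[str, float] = {}
    best_bait: Dict[str, str] = {}
    if "similarity" in enabled:
        sim = similarity_search(baits, database, scheme, config.similarity_evalue_cutoff)
        per_strategy["similarity"] = set(sim)
        for i, (b, e) in sim.items():
            best_bait[i], best_ev[i] = b, e
    if "profile_similarity" in enabled:
        per_strategy["profile_similarity"] = profile_search(
            baits,
            database,
            scheme,
            config.similarity_evalue_cutoff,
            max(config.psi_iterations, 1),
            config.psi_pseudocount_weight,
        )
    if "domain" in enabled:
        per_hmm, _ = domain_search(
            hmms,
            database,
            evalue_cutoff=None if config.hmm_bit_cutoff is not None else config.hmm_evalue_cutoff,
            bit_cutoff=config.hmm_bit_cutoff,
        )
        per_strategy["domain"] = set.union(*per_hmm.values()) if per_hmm else set()

    if config.combine == "union":
        pool = set.union(*per_strategy.values())
    else:
        pool = set.intersection(*per_strategy.values())

    hit_ids = sorted(set.union(*per_strategy.values()))
    membership = pd.DataFrame(
        {s: [i in per_strategy[s] for i in hit_ids] for s in per_strategy},
        index=pd.Index(hit_ids, name="id"),
    )

    length_of = {r.id: r.length for r in database}
    status: Dict[str, str] = {}
    retained = []
    for rec in database:
        if rec.id not in pool:
            status[rec.id] = "no_hit"
        elif length_of[rec.id] < config.min_length:
            status[rec.id] = "too_short"
        else:
            status[rec.id] = "retained"
            retained.append(rec.id)

    bait_lengths = [b.length for b in baits] or [0]
    return HarvestResult(
        membership=membership,
        status=status,
        retained_ids=retained,
        venn=_venn(membership),
        bait_length_range=(min(bait_lengths), max(bait_lengths)),
        best_evalue=best_ev,
        best_bait=best_bait,
    )


def cutoff_sweep(
    cutoffs: Iterable[float],
    config: HarvestConfig,
    baits: Sequence[SeqRecord],
    database: Sequence[SeqRecord],
    hmms: Optional[Sequence[ProfileHMM]] = None,
    scheme: Optional[ScoringScheme] = None,
) -> pd.DataFrame:
    """Sensitivity of the harvest to the similarity E-value cutoff.

    One row per cutoff: number of hits (pre-filter) and number
    retained after the length filter.  Loosening the cutoff never
    shrinks either count.
    """
    from dataclasses import replace as _replace

    rows = []
    for cutoff in cutoffs:
        res = run_harvest(
            _replace(config, similarity_evalue_cutoff=cutoff), baits, database, hmms, scheme
        )
        rows.append(
            {
                "evalue_cutoff": cutoff,
                "hits": int(len([s for s in res.status.values() if s != "no_hit"])),
                "retained": len(res.retained_ids),
            }
        )
    return pd.DataFrame(rows)
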