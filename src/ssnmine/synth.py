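"""Synthetic protein-superfamily generator with full ground truth.

Emulates the statistical structure the mining pipeline assumes in a
transcriptome-derived enzyme pool:

* several divergent **subfamilies** of one superfamily: a root
  ancestor is drawn from background residue frequencies, per-family
  ancestors descend from it, and members descend independently from
  their family ancestor (star topology) — giving high within-family
  and lower between-family identity;
* **fragments**: random contiguous truncations of family members,
  short enough to fall below the pipeline's length filter;
* **novel singletons**: heavily diverged direct descendants of the
  root, related to every family only distantly — the planted analogue
  of uncharacterised enzymes awaiting discovery.

Substitutions follow the conditional model implied by BLOSUM62
(drawing a replacement residue given the current one), so diverged
sequences keep realistic residue preferences and back-substitution is
possible; realized identities are therefore checked against the
generator's own Monte-Carlo expectation, not a naive ``1 - rate``
formula.  Indels are geometric-length insertions/deletions.  All
randomness flows from a single mandatory seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ssnmine.align import (
    BACKGROUND_FREQS,
    ScoringScheme,
    align_local,
    alignment_score,
    blosum_conditional,
)
from ssnmine.seqio import AMINO20, MetadataTable, SeqRecord

_BG = np.array([BACKGROUND_FREQS[a] for a in AMINO20])
_BG = _BG / _BG.sum()

#: product-category labels cycled over families
_DEFAULT_LABELS = (
    "cycloartenol", "beta-amyrin", "lupeol", "lanosterol",
    "cucurbitadienol", "taraxerol", "friedelin", "thalianol",
)
_DEFAULT_CLADES = ("angiosperms", "gymnosperms", "ferns", "bryophytes", "algae")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic dataset.

    ``within_family_sub_rate`` and ``singleton_divergence`` are
    substitution-event probabilities per site along one lineage;
    ``between_family_identity_target`` is the desired percent identity
    between members of different families, from which the
    family-ancestor divergence is derived.  ``ancestor_length`` 750
    matches the length scale of full-length multi-domain enzymes, and
    the fragment bound sits below the default 700-residue filter.
    """

    seed: int
    n_families: int = 5
    family_size: int = 8
    ancestor_length: int = 750
    within_family_sub_rate: float = 0.15
    between_family_identity_target: float = 30.0
    indel_rate: float = 0.01
    mean_indel_length: float = 2.0
    fragment_fraction: float = 0.1
    fragment_max_length: int = 650
    n_novel_singletons: int = 3
    singleton_divergence: float = 0.6
    n_references_per_family: int = 2
    labels: tuple = _DEFAULT_LABELS
    clades: tuple = _DEFAULT_CLADES
    singleton_clade: str = "angiosperms"

    def __post_init__(self) -> None:
        for name in ("within_family_sub_rate", "indel_rate", "fragment_fraction",
                     "singleton_divergence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ancestor_length < 1 or self.fragment_max_length < 1:
            raise ValueError("lengths must be positive")
        if self.n_families < 1 or self.family_size < 1:
            raise ValueError("need at least one family with one member")
        if self.n_references_per_family > self.family_size:
            raise ValueError("more references than family members")
        within_expect = 100.0 * (1.0 - self.within_family_sub_rate) ** 2
        if within_expect <= self.between_family_identity_target:
            raise ValueError(
                "infeasible identity targets: expected within-family identity "
                f"{within_expect:.1f}% does not exceed the between-family target "
                f"{self.between_family_identity_target:.1f}%"
            )

    @property
    def family_ancestor_divergence(self) -> float:
        """Per-lineage root->family substitution rate implied by the
        between-family identity target."""
        retain = math.sqrt(self.between_family_identity_target / 100.0)
        member_retain = 1.0 - self.within_family_sub_rate
        needed = retain / member_retain
        if needed >= 1.0:
            return 0.0
        return 1.0 - needed


def _conditional_no_identity() -> np.ndarray:
    cond = blosum_conditional().copy()
    np.fill_diagonal(cond, 0.0)
    return cond / cond.sum(axis=1, keepdims=True)


def _draw_ancestor(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(20, size=length, p=_BG)


def _substitute(seq: np.ndarray, rate: float, rng: np.random.Generator,
                cond: np.ndarray) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hit):
        out[i] = rng.choice(20, p=cond[seq[i]])
    return out


def _indels(seq: np.ndarray, rate: float, mean_len: float,
            rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq
    n_events = rng.binomial(len(seq), rate)
    out = seq
    for _ in range(n_events):
        if len(out) < 10:
            break
        pos = int(rng.integers(0, len(out)))
        length = int(rng.geometric(1.0 / max(mean_len, 1.0)))
        if rng.random() < 0.5:  # deletion
            out = np.concatenate([out[:pos], out[pos + length:]])
        else:  # insertion of background residues
            ins = rng.choice(20, size=length, p=_BG)
            out = np.concatenate([out[:pos], ins, out[pos:]])
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(AMINO20[i] for i in seq)


def generate(config: SynthConfig) -> Tuple[List[SeqRecord], MetadataTable, pd.DataFrame]:
    """Generate sequences, metadata and ground truth.

    Returns ``(records, metadata, truth)``: the database records
    (family members, fragments, novel singletons), a metadata table
    assigning species/clade to every sequence and product labels to
    the per-family references, and a truth table with one row per
    emitted sequence (``family_<i>``, ``fragment_of:<id>`` or
    ``novel_singleton``).  Byte-identical output for identical seeds.
    """
    rng = np.random.default_rng(config.seed)
    cond = _conditional_no_identity()
    root = _draw_ancestor(rng, config.ancestor_length)
    fam_rate = config.family_ancestor_divergence

    records: List[SeqRecord] = []
    meta_rows: List[Dict] = []
    truth_rows: List[Dict] = []
    members_by_family: List[List[SeqRecord]] = []

    for f in range(config.n_families):
        fam_anc = _substitute(root, fam_rate, rng, cond)
        label = config.labels[f % len(config.labels)]
        clade = config.clades[f % len(config.clades)]
        fam_members = []
        for m in range(config.family_size):
            seq = _substitute(fam_anc, config.within_family_sub_rate, rng, cond)
            seq = _indels(seq, config.indel_rate, config.mean_indel_length, rng)
            rid = f"F{f}_M{m}"
            species = f"sp_f{f}_{m % max(1, config.family_size // 2)}"
            rec = SeqRecord(id=rid, residues=_to_str(seq))
            records.append(rec)
            fam_members.append(rec)
            meta_rows.append(
                {
                    "id": rid,
                    "species": species,
                    "clade": clade,
                    "label": label if m < config.n_references_per_family else "",
                }
            )
            truth_rows.append({"id": rid, "truth": f"family_{f}", "label": label})
        members_by_family.append(fam_members)

    # fragments: truncations of randomly chosen members
    n_members = config.n_families * config.family_size
    n_fragments = int(round(config.fragment_fraction * n_members))
    all_members = [r for fam in members_by_family for r in fam]
    for i in range(n_fragments):
        src = all_members[int(rng.integers(0, len(all_members)))]
        max_len = min(config.fragment_max_length, src.length - 1)
        frag_len = int(rng.integers(max(30, max_len // 2), max_len + 1))
        start = int(rng.integers(0, src.length - frag_len + 1))
        rid = f"{src.id}_frag{i}"
        records.append(SeqRecord(id=rid, residues=src.residues[start : start + frag_len]))
        src_meta = next(m for m in meta_rows if m["id"] == src.id)
        meta_rows.append(
            {"id": rid, "species": src_meta["species"], "clade": src_meta["clade"], "label": ""}
        )
        truth_rows.append({"id": rid, "truth": f"fragment_of:{src.id}", "label": ""})

    # novel singletons: heavily diverged direct descendants of the root
    for i in range(config.n_novel_singletons):
        seq = _substitute(root, config.singleton_divergence, rng, cond)
        seq = _indels(seq, config.indel_rate, config.mean_indel_length, rng)
        rid = f"NOV{i}"
        records.append(SeqRecord(id=rid, residues=_to_str(seq)))
        meta_rows.append(
            {"id": rid, "species": f"sp_nov{i}", "clade": config.singleton_clade, "label": ""}
        )
        truth_rows.append({"id": rid, "truth": "novel_singleton", "label": ""})

    metadata = MetadataTable(
        pd.DataFrame(meta_rows, columns=["id", "species", "clade", "label"]).replace({"": None})
    )
    truth = pd.DataFrame(truth_rows, columns=["id", "truth", "label"])
    return records, metadata, truth


def truth_partition(truth: pd.DataFrame) -> Dict[str, str]:
    """Ground-truth cluster assignment for partition comparisons.

    Family members map to their family; each novel singleton is its
    own cluster (the type tag ``novel_singleton`` is shared, the
    cluster is not); fragments map to their source member's family.
    """
    out: Dict[str, str] = {}
    fam_of = dict(zip(truth["id"], truth["truth"]))
    for rid, t in fam_of.items():
        if t == "novel_singleton":
            out[rid] = rid
        elif t.startswith("fragment_of:"):
            out[rid] = fam_of[t.split(":", 1)[1]]
        else:
            out[rid] = t
    return out


def expected_pairwise_identity(
    rate: float, length: int = 200, n_pairs: int = 200, seed: int = 0
) -> float:
    """Monte-Carlo expectation of percent identity between two
    independent descendants of one ancestor at the given substitution
    rate (no indels).  This is the generator's own oracle for realized
    within-family identity, accounting for back-substitution."""
    rng = np.random.default_rng(seed)
    cond = _conditional_no_identity()
    total = 0.0
    for _ in range(n_pairs):
        anc = _draw_ancestor(rng, length)
        a = _substitute(anc, rate, rng, cond)
        b = _substitute(anc, rate, rng, cond)
        total += float((a == b).mean())
    return 100.0 * total / n_pairs


def measure_as_bands(
    config: SynthConfig,
    scheme: Optional[ScoringScheme] = None,
    n_pairs: int = 50,
) -> Dict[str, float]:
    """Sample within-family and cross-class alignment-score bands.

    Generates the dataset for ``config`` and measures AS on up to
    ``n_pairs`` sampled within-family pairs and cross pairs (between
    families, and singleton vs family member).  Returns the band
    edges; a usable planted gap has ``min_within > max_cross``.
    """
    scheme = scheme or ScoringScheme()
    records, _, truth = generate(config)
    by_id = {r.id: r for r in records}
    fam_of = dict(zip(truth["id"], truth["truth"]))
    members = [r for r in records if fam_of[r.id].startswith("family_")]
    singles = [r for r in records if fam_of[r.id] == "novel_singleton"]
    rng = np.random.default_rng(config.seed + 777)

    within, cross = [], []
    fams: Dict[str, List[SeqRecord]] = {}
    for r in members:
        fams.setdefault(fam_of[r.id], []).append(r)
    fam_keys = sorted(fams)
    for _ in range(n_pairs):
        fk = fam_keys[int(rng.integers(0, len(fam_keys)))]
        if len(fams[fk]) >= 2:
            i, j = rng.choice(len(fams[fk]), size=2, replace=False)
            within.append(
                alignment_score(align_local(fams[fk][int(i)], fams[fk][int(j)], scheme))
            )
    for _ in range(n_pairs):
        if len(fam_keys) >= 2:
            fa, fb = rng.choice(len(fam_keys), size=2, replace=False)
            a = fams[fam_keys[int(fa)]][int(rng.integers(0, len(fams[fam_keys[int(fa)]])))]
            b = fams[fam_keys[int(fb)]][int(rng.integers(0, len(fams[fam_keys[int(fb)]])))]
            cross.append(alignment_score(align_local(a, b, scheme)))
    for s in singles:
        for _ in range(max(1, n_pairs // max(1, len(singles) * 2))):
            m = members[int(rng.integers(0, len(members)))]
            cross.append(alignment_score(align_local(s, m, scheme)))

    return {
        "min_within": min(within) if within else float("nan"),
        "max_within": max(within) if within else float("nan"),
        "min_cross": min(cross) if cross else 0.0,
        "max_cross": max(cross) if cross else 0.0,
    }


def plant_as_gap(
    config: SynthConfig,
    scheme: Optional[ScoringScheme] = None,
    n_pairs: int = 50,
    gap_margin: float = 5.0,
    max_adjustments: int = 5,
) -> SynthConfig:
    """Return a config whose within- and cross-class AS bands are
    disjoint, verified by sampling.

    A config that already separates (minimum within-family AS exceeds
    the maximum cross-class AS by at least ``gap_margin``) is returned
    unchanged.  Otherwise the within-family substitution rate is
    lowered (raising within-family AS) and the singleton divergence
    raised (lowering cross AS) and the check repeated; if separation
    cannot be achieved the function raises with the measured bands.
    """
    scheme = scheme or ScoringScheme()
    current = config
    for _ in range(max_adjustments + 1):
        bands = measure_as_bands(current, scheme, n_pairs)
        if (
            not math.isnan(bands["min_within"])
            and bands["min_within"] > bands["max_cross"] + gap_margin
        ):
            return current
        current = replace(
            current,
            within_family_sub_rate=current.within_family_sub_rate * 0.75,
            singleton_divergence=min(0.95, current.singleton_divergence * 1.1),
        )
    raise ValueError(
        "cannot achieve a disjoint alignment-score gap within rate bounds; "
        f"last measured bands: {bands}"
    )
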