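"""Minimal profile hidden Markov models for domain presence calls.

Implements a plan7-style profile HMM (match/insert/delete states, the
seven core transition types) scored in **single-hit local** mode: an
alignment enters the model at a uniformly chosen (start position,
match state) pair (probability ``1/(M*L)``), every match state exits
with probability ``1/(M+1)`` (its core transitions scaled by the
complement), and the flanking sequence is emitted by the background
null model so it contributes nothing to the log-odds score.  Entry and
exit being proper distributions keeps the total path mass a
sub-probability, so a sequence emitted at background frequencies can
never score above 0 bits.  This is
deliberately simpler than a full HMMER profile (no multihit, no glocal
mode, no entry/exit priors): the only downstream use is a
presence/absence call at a threshold, for which single-hit local
scoring suffices.

Scores are log-odds in bits against the background null.  ``X``
residues emit at background frequency in every state (log-odds 0).

E-values, when a Gumbel calibration is available, use an effective
search-space size of 1 (per-sequence search):
``E = exp(-lambda_g * (bit_score - mu))``.  Cutoffs are therefore
per-sequence and independent of database size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from ssnmine.seqio import AMINO20 as AMINO
from ssnmine.seqio import SeqRecord

_AMINO_INDEX = {a: i for i, a in enumerate(AMINO)}

_NEG_INF = float("-inf")
_LN2 = math.log(2.0)

#: plan7 core transition types, per source state
TRANSITION_TYPES = ("mm", "mi", "md", "im", "ii", "dm", "dd")


@dataclass
class ProfileHMM:
    """A profile HMM over the amino-acid alphabet.

    Attributes
    ----------
    name : str
    M : int
        Number of match states.
    match_logodds : ndarray of shape (M, 20)
        Per-state match emission log-odds (natural log) against
        ``background``.
    insert_logodds : ndarray of shape (M, 20)
        Insert emission log-odds; zeros mean inserts emit at background.
    transitions : dict
        Natural-log transition probabilities keyed by
        :data:`TRANSITION_TYPES`; each value is an array of length M
        (entries beyond the last valid source state are ``-inf``).
    background : ndarray of shape (20,)
        Null-model residue frequencies (sums to 1).
    calibration : (mu, lambda_g) or None
        Gumbel location/scale for E-values; absent for uncalibrated
        models, in which case only bit-score cutoffs are usable.
    """

    name: str
    M: int
    match_logodds: np.ndarray
    insert_logodds: np.ndarray
    transitions: dict
    background: np.ndarray
    calibration: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        for key in TRANSITION_TYPES:
            if key not in self.transitions:
                raise ValueError(f"missing transition array {key!r}")
        self._check_transition_normalisation()

    def _check_transition_normalisation(self) -> None:
        t = self.transitions
        # source M_k (k = 1..M-1): MM + MI + MD must sum to 1
        for k in range(self.M - 1):
            mass = np.exp([t["mm"][k], t["mi"][k], t["md"][k]]).sum()
            if abs(mass - 1.0) > 1e-4:
                raise ValueError(f"match-state {k + 1} transitions sum to {mass:.8f}")
        # source I_k: IM + II
        for k in range(self.M - 1):
            if t["im"][k] == _NEG_INF and t["ii"][k] == _NEG_INF:
                continue
            mass = np.exp([t["im"][k], t["ii"][k]]).sum()
            if abs(mass - 1.0) > 1e-4:
                raise ValueError(f"insert-state {k + 1} transitions sum to {mass:.8f}")
        # source D_k: DM + DD
        for k in range(self.M - 1):
            if t["dm"][k] == _NEG_INF and t["dd"][k] == _NEG_INF:
                continue
            mass = np.exp([t["dm"][k], t["dd"][k]]).sum()
            if abs(mass - 1.0) > 1e-4:
                raise ValueError(f"delete-state {k + 1} transitions sum to {mass:.8f}")


@dataclass(frozen=True)
class DomainHit:
    """Presence/absence decision for one HMM against one sequence."""

    hmm_name: str
    bit_score: float
    evalue: Optional[float]
    present: bool


# ---------------------------------------------------------------------------
# HMMER3 ASCII subset reader
# ---------------------------------------------------------------------------

def _parse_logprob(token: str) -> float:
    """HMMER stores -ln(p); '*' means probability zero."""
    if token == "*":
        return _NEG_INF
    return -float(token)


def load_hmm(path: str | Path) -> ProfileHMM:
    """Read a profile HMM from a HMMER3 ASCII file (subset).

    Parses NAME, LENG, ALPH, the optional COMPO line (used as the
    background distribution; uniform if absent), per-state match and
    insert emissions and the seven core transitions, and a
    ``STATS LOCAL FORWARD`` line into the Gumbel calibration.  Emission
    values are converted from the file's negative-log space to log-odds
    against the background.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("HMMER3"):
        raise ValueError(f"{path}: not a HMMER3 file")
    name, leng, alph, calibration = None, None, None, None
    i = 1
    while i < len(lines) and not lines[i].startswith("HMM "):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        key = parts[0]
        if key == "NAME":
            name = parts[1]
        elif key == "LENG":
            leng = int(parts[1])
        elif key == "ALPH":
            alph = parts[1].lower()
        elif key == "STATS" and len(parts) >= 5 and parts[1] == "LOCAL" and parts[2] == "FORWARD":
            calibration = (float(parts[3]), float(parts[4]))
        i += 1
    if alph is not None and alph != "amino":
        raise ValueError(f"{path}: alphabet {alph!r} is not amino")
    if leng is None or name is None:
        raise ValueError(f"{path}: missing NAME or LENG")
    if i >= len(lines):
        raise ValueError(f"{path}: no HMM state section")
    file_alpha = lines[i].split()[1:]
    if len(file_alpha) != 20:
        raise ValueError(f"{path}: expected 20 emission columns, got {len(file_alpha)}")
    # column order in the file -> our AMINO order
    col_order = [file_alpha.index(a) for a in AMINO]
    i += 2  # skip the transition-name header line

    background = np.full(20, 1.0 / 20.0)
    if i < len(lines) and lines[i].split()[:1] == ["COMPO"]:
        vals = [_parse_logprob(t) for t in lines[i].split()[1:21]]
        probs = np.exp(np.array(vals)[col_order])
        background = probs / probs.sum()
        i += 1
    # node 0: insert-0 emissions and begin-state transitions (skipped —
    # single-hit local mode replaces entry transitions with uniform 1/M)
    node0 = 0
    while i < len(lines) and node0 < 2 and lines[i].split() and lines[i].split()[0] not in ("1", "//"):
        node0 += 1
        i += 1

    log_bg = np.log(background)
    match_lo = np.zeros((leng, 20))
    insert_lo = np.zeros((leng, 20))
    trans = {key: np.full(leng, _NEG_INF) for key in TRANSITION_TYPES}
    for k in range(1, leng + 1):
        block = lines[i : i + 3]
        if len(block) < 3 or block[0].strip().startswith("//"):
            raise ValueError(f"{path}: truncated state block at state {k}")
        mparts = block[0].split()
        if mparts[0] != str(k):
            raise ValueError(f"{path}: truncated state block at state {k}")
        mvals = np.array([_parse_logprob(t) for t in mparts[1:21]])[col_order]
        match_lo[k - 1] = mvals - log_bg
        ivals = np.array([_parse_logprob(t) for t in block[1].split()[:20]])[col_order]
        insert_lo[k - 1] = ivals - log_bg
        tvals = [_parse_logprob(t) for t in block[2].split()[:7]]
        for key, val in zip(TRANSITION_TYPES, tvals):
            trans[key][k - 1] = val
        i += 3
    # final state has no outgoing core transitions in our model
    for key in TRANSITION_TYPES:
        trans[key][leng - 1] = _NEG_INF
    return ProfileHMM(
        name=name,
        M=leng,
        match_logodds=match_lo,
        insert_logodds=insert_lo,
        transitions=trans,
        background=background,
        calibration=calibration,
    )


# ---------------------------------------------------------------------------
# HMM construction from an MSA
# ---------------------------------------------------------------------------

def build_hmm(
    msa: Sequence[SeqRecord],
    pseudocount_weight: float = 0.5,
    name: str = "msa_hmm",
    gap_chars: str = "-.",
) -> ProfileHMM:
    """Build a profile HMM from an aligned set of sequences.

    Columns with at most 50% gaps become match states; gappier columns
    are treated as insert columns; all-gap columns are skipped with a
    warning.  Match emissions are ``(counts + w * background)``
    normalised, where the background is the overall residue frequency
    of the MSA (gaps excluded, floored so every residue has nonzero
    probability).  Transitions are counted from each sequence's implied
    state path and Laplace-smoothed.  As ``pseudocount_weight`` grows,
    emissions converge to the background (log-odds 0 everywhere).
    """
    if len(msa) < 2:
        raise ValueError("an MSA of at least 2 sequences is required")
    width = len(msa[0].residues) if hasattr(msa[0], "residues") else len(msa[0])
    rows = []
    for rec in msa:
        seq = rec.residues if hasattr(rec, "residues") else str(rec)
        if len(seq) != width:
            raise ValueError("aligned sequences must have equal length")
        rows.append(seq.upper())
    n_seq = len(rows)

    gap_set = set(gap_chars)
    is_gap = np.array([[c in gap_set for c in row] for row in rows])
    all_gap = is_gap.all(axis=0)
    if all_gap.any():
        warnings.warn(f"{int(all_gap.sum())} all-gap column(s) skipped", stacklevel=2)
    keep = ~all_gap
    gap_frac = is_gap[:, keep].mean(axis=0)
    match_cols = np.flatnonzero(keep)[gap_frac <= 0.5]
    kept_cols = np.flatnonzero(keep)
    M = len(match_cols)
    if M == 0:
        raise ValueError("no match columns (every column is >50% gaps)")

    # background: overall residue frequencies, floored
    counts_bg = np.zeros(20)
    for row in rows:
        for c in row:
            if c in _AMINO_INDEX:
                counts_bg[_AMINO_INDEX[c]] += 1
    bg = counts_bg + 1e-3 * counts_bg.sum() / 20.0 + 1e-9
    background = bg / bg.sum()
    log_bg = np.log(background)

    w = float(pseudocount_weight)
    match_lo = np.zeros((M, 20))
    for mi, col in enumerate(match_cols):
        col_counts = np.zeros(20)
        for row in rows:
            c = row[col]
            if c in _AMINO_INDEX:
                col_counts[_AMINO_INDEX[c]] += 1
        p = col_counts + w * background
        p = p / p.sum()
        match_lo[mi] = np.log(p) - log_bg
    insert_lo = np.zeros((M, 20))  # inserts emit at background

    # state paths: walk the kept columns; match col + residue -> M,
    # match col + gap -> D, insert col + residue -> I (attached to the
    # preceding match state)
    match_col_set = set(match_cols.tolist())
    tcounts = {key: np.zeros(M) for key in TRANSITION_TYPES}
    for row in rows:
        prev = None  # (kind, match_index)
        m_idx = -1
        for col in kept_cols:
            if col in match_col_set:
                m_idx += 1
                state = ("m", m_idx) if row[col] not in gap_set else ("d", m_idx)
            else:
                if row[col] in gap_set:
                    continue
                state = ("i", m_idx)
            if prev is not None:
                pk, pidx = prev
                sk, _ = state
                key = pk + sk
                if key in ("mm", "mi", "md", "im", "ii", "dm", "dd") and 0 <= pidx < M:
                    tcounts[key][pidx] += 1
                # "id" paths (insert followed by delete) are rare and not a
                # plan7 transition; fold them into im for counting purposes
                elif key == "id" and 0 <= pidx < M:
                    tcounts["im"][pidx] += 1
            prev = state

    trans = {key: np.full(M, _NEG_INF) for key in TRANSITION_TYPES}
    for k in range(M - 1):
        mm, mi_, md = tcounts["mm"][k] + 1, tcounts["mi"][k] + 1, tcounts["md"][k] + 1
        tot = mm + mi_ + md
        trans["mm"][k], trans["mi"][k], trans["md"][k] = (
            math.log(mm / tot), math.log(mi_ / tot), math.log(md / tot))
        im, ii = tcounts["im"][k] + 1, tcounts["ii"][k] + 1
        trans["im"][k], trans["ii"][k] = math.log(im / (im + ii)), math.log(ii / (im + ii))
        dm, dd = tcounts["dm"][k] + 1, tcounts["dd"][k] + 1
        trans["dm"][k], trans["dd"][k] = math.log(dm / (dm + dd)), math.log(dd / (dm + dd))
    return ProfileHMM(
        name=name,
        M=M,
        match_logodds=match_lo,
        insert_logodds=insert_lo,
        transitions=trans,
        background=background,
        calibration=None,
    )


def star_msa(anchor: SeqRecord, others: Sequence[SeqRecord], scheme=None) -> list:
    """Anchor-coordinate multiple alignment for HMM construction.

    Aligns every sequence to *anchor* pairwise and projects it onto
    anchor coordinates (insertions relative to the anchor are
    dropped).  Adequate for building a detection HMM from a handful of
    related references; not a substitute for a true MSA when columns
    matter individually.
    """
    from ssnmine.align import anchored_residues

    rows = [SeqRecord(id=anchor.id, residues=anchor.residues)]
    for other in others:
        if other.id == anchor.id:
            continue
        projected = anchored_residues(anchor, other, scheme)
        aligned = "".join(c if c is not None else "-" for c in projected)
        rows.append(_AlignedRow(other.id, aligned))
    return rows


class _AlignedRow:
    """Gapped sequence row (bypasses SeqRecord's alphabet validation)."""

    __slots__ = ("id", "residues")

    def __init__(self, rec_id: str, residues: str) -> None:
        self.id = rec_id
        self.residues = residues


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _core_dp(hmm: ProfileHMM, seq: str, mode: str) -> float:
    """Shared forward/Viterbi recursion in log space.

    Paths enter at any match state (log 1/M), traverse the core, and
    exit from any match state (log 1/M); flanking residues are free
    (emitted by the null).  Returns the total log-odds in nats.

    The recursion is vectorised over states per sequence position; the
    within-column delete chain ``D_j -> D_{j+1} -> ...`` is a prefix
    combine over ``M->D`` entry points, computed with
    ``logaddexp.accumulate`` (forward) or ``maximum.accumulate``
    (Viterbi) after factoring out the cumulative ``D->D`` weight.
    """
    L = len(seq)
    M = hmm.M
    t = hmm.transitions
    # uniform over (start position, entry state); exit is a stopping
    # event with prob 1/(M+1), core match transitions scaled by the
    # complement — both proper distributions (see module docstring)
    entry = -math.log(M) - math.log(L)
    exit_ = -math.log(M + 1)
    stay = math.log(M / (M + 1))
    viterbi = mode == "viterbi"
    pair = np.maximum if viterbi else np.logaddexp

    mm, mi, md = t["mm"] + stay, t["mi"] + stay, t["md"] + stay
    im, ii = t["im"], t["ii"]
    dm, dd = t["dm"], t["dd"]
    # cumulative D->D weight; -inf tail entries never lie on a valid
    # path but would poison the cumulative sum, so they are clamped
    dd_safe = np.where(np.isfinite(dd), dd, -1e9)
    cum_dd = np.cumsum(dd_safe)

    seq_idx = np.array([_AMINO_INDEX.get(c, -1) for c in seq])
    fm_prev = np.full(M, _NEG_INF)
    fi_prev = np.full(M, _NEG_INF)
    fd_prev = np.full(M, _NEG_INF)
    total = _NEG_INF
    for i in range(L):
        ci = seq_idx[i]
        e_match = hmm.match_logodds[:, ci] if ci >= 0 else np.zeros(M)
        e_ins = hmm.insert_logodds[:, ci] if ci >= 0 else np.zeros(M)
        from_mm = np.concatenate(([_NEG_INF], fm_prev[:-1] + mm[:-1]))
        from_im = np.concatenate(([_NEG_INF], fi_prev[:-1] + im[:-1]))
        from_dm = np.concatenate(([_NEG_INF], fd_prev[:-1] + dm[:-1]))
        fm = e_match + pair(pair(np.full(M, entry), from_mm), pair(from_im, from_dm))
        fi = e_ins + pair(fm_prev + mi, fi_prev + ii)
        # delete chain within this column
        v = fm + md - cum_dd
        acc = np.maximum.accumulate(v) if viterbi else np.logaddexp.accumulate(v)
        fd = np.concatenate(([_NEG_INF], cum_dd[:-1] + acc[:-1]))
        col_end = float(np.max(fm)) if viterbi else float(logsumexp(fm))
        total = max(total, col_end + exit_) if viterbi else np.logaddexp(total, col_end + exit_)
        fm_prev, fi_prev, fd_prev = fm, fi, fd
    return float(total)


def forward_score(hmm: ProfileHMM, seq: SeqRecord) -> float:
    """Forward log-odds bit score (sum over all paths) of *seq*.

    Single-hit local mode; see the module docstring for the path model.
    """
    residues = seq.residues if hasattr(seq, "residues") else str(seq)
    if not residues:
        raise ValueError("cannot score empty sequence")
    return _core_dp(hmm, residues, "forward") / _LN2


def viterbi_score(hmm: ProfileHMM, seq: SeqRecord) -> float:
    """Best-single-path log-odds bit score; never exceeds the forward score."""
    residues = seq.residues if hasattr(seq, "residues") else str(seq)
    if not residues:
        raise ValueError("cannot score empty sequence")
    return _core_dp(hmm, residues, "viterbi") / _LN2


def hmm_evalue(hmm: ProfileHMM, bits: float) -> float:
    """Gumbel-tail E-value at effective search-space size 1."""
    if hmm.calibration is None:
        raise ValueError(
            f"HMM {hmm.name!r} is not calibrated; use a bit-score cutoff instead"
        )
    mu, lam = hmm.calibration
    return math.exp(-lam * (bits - mu))


def domain_present(
    hmm: ProfileHMM,
    seq: SeqRecord,
    evalue_cutoff: Optional[float] = None,
    bit_cutoff: Optional[float] = None,
) -> DomainHit:
    """Decide whether the domain modelled by *hmm* is present in *seq*.

    Exactly one cutoff must be given.  The E-value route requires a
    calibrated model; tightening either cutoff can only flip decisions
    from present to absent, never the reverse.
    """
    if (evalue_cutoff is None) == (bit_cutoff is None):
        raise ValueError("provide exactly one of evalue_cutoff, bit_cutoff")
    bits = forward_score(hmm, seq)
    if evalue_cutoff is not None:
        ev = hmm_evalue(hmm, bits)  # raises with guidance if uncalibrated
        return DomainHit(hmm.name, bits, ev, ev <= evalue_cutoff)
    ev = None
    if hmm.calibration is not None:
        ev = hmm_evalue(hmm, bits)
    return DomainHit(hmm.name, bits, ev, bits >= bit_cutoff)
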