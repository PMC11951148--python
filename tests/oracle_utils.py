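"""Independent oracles for property tests.

Each oracle is deliberately naive — exhaustive enumeration or boolean
closure — and shares no code path with the implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.special import logsumexp


def sw_oracle(a: str, b: str, score, gap_open: int, gap_extend: int) -> int:
    """Optimal local-alignment score by enumerating monotone matchings.

    A local alignment is a strictly increasing set of aligned residue
    pairs; residues of either sequence lying between consecutive
    aligned pairs form one gap run each, costing
    ``gap_open + length * gap_extend``.  The empty alignment scores 0.
    Exponential — lengths must stay tiny.
    """
    n, m = len(a), len(b)
    best = 0
    positions_a = list(range(n))
    positions_b = list(range(m))
    for k in range(1, min(n, m) + 1):
        for pa in combinations(positions_a, k):
            for pb in combinations(positions_b, k):
                total = 0
                for i in range(k):
                    total += score(a[pa[i]], b[pb[i]])
                    if i > 0:
                        da = pa[i] - pa[i - 1] - 1
                        db = pb[i] - pb[i - 1] - 1
                        if da > 0:
                            total -= gap_open + da * gap_extend
                        if db > 0:
                            total -= gap_open + db * gap_extend
                if total > best:
                    best = total
    return best


def hmm_path_oracle(hmm, seq: str, mode: str) -> float:
    """Log-odds by explicit enumeration of all single-hit local paths.

    Paths enter at a uniformly chosen (start position, match state)
    pair (weight 1/(M*L)), may traverse insert/delete chains, and exit
    from any match state with probability 1/(M+1) (match-state
    transitions carry the complement).
    Returns nats (max over paths for Viterbi, logsumexp for forward).
    """
    from ssnmine.phmm import _AMINO_INDEX

    M, L = hmm.M, len(seq)
    stay = math.log(M / (M + 1))
    t = {
        key: (hmm.transitions[key] + stay if key in ("mm", "mi", "md")
              else hmm.transitions[key])
        for key in hmm.transitions
    }
    idx = [_AMINO_INDEX.get(c, -1) for c in seq]
    entry = -math.log(M) - math.log(L)
    exit_w = -math.log(M + 1)

    def em(k, i):
        return 0.0 if idx[i] < 0 else float(hmm.match_logodds[k, idx[i]])

    def ei(k, i):
        return 0.0 if idx[i] < 0 else float(hmm.insert_logodds[k, idx[i]])

    scores = []

    def extend(k, i, acc):
        # a match at state k just consumed residue i-1 (i residues used)
        scores.append(acc + exit_w)
        if k >= M - 1:
            return
        if i < L:
            extend(k + 1, i + 1, acc + t["mm"][k] + em(k + 1, i))

        def ins_chain(kk, ii, acc2):
            if kk < M - 1 and ii < L:
                extend(kk + 1, ii + 1, acc2 + t["im"][kk] + em(kk + 1, ii))
            if ii < L:
                ins_chain(kk, ii + 1, acc2 + t["ii"][kk] + ei(kk, ii))

        if i < L:
            ins_chain(k, i + 1, acc + t["mi"][k] + ei(k, i))
        dacc = acc + t["md"][k]
        kk = k + 1  # now in delete state kk+1 (0-based index kk)
        while kk < M - 1:
            if i < L:
                extend(kk + 1, i + 1, dacc + t["dm"][kk] + em(kk + 1, i))
            dacc = dacc + t["dd"][kk]
            kk += 1

    for start in range(L):
        for k0 in range(M):
            extend(k0, start + 1, entry + em(k0, start))
    if not scores:
        return float("-inf")
    return max(scores) if mode == "viterbi" else float(logsumexp(scores))


def components_oracle(n_nodes: int, edge_list) -> list:
    """Connected components via boolean transitive closure."""
    adj = np.eye(n_nodes, dtype=bool)
    for i, j in edge_list:
        adj[i, j] = adj[j, i] = True
    closure = adj.copy()
    for _ in range(n_nodes):
        new = closure | (closure @ closure)
        if (new == closure).all():
            break
        closure = new
    seen, comps = set(), []
    for i in range(n_nodes):
        if i in seen:
            continue
        comp = frozenset(np.flatnonzero(closure[i]).tolist())
        seen |= set(comp)
        comps.append(comp)
    return comps
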