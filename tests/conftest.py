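import textwrap

import numpy as np
import pytest

from ssnmine.align import ScoringScheme
from ssnmine.phmm import TRANSITION_TYPES, ProfileHMM
from ssnmine.seqio import AMINO20


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


def random_profile_hmm(rng: np.random.Generator, M: int, calibration=None) -> ProfileHMM:
    """A fully random (but valid) profile HMM for property tests."""
    emissions = rng.dirichlet(np.ones(20), size=M)
    background = rng.dirichlet(np.ones(20) * 5)
    match_lo = np.log(emissions) - np.log(background)
    trans = {k: np.full(M, -np.inf) for k in TRANSITION_TYPES}
    for k in range(M - 1):
        p3 = rng.dirichlet(np.ones(3))
        trans["mm"][k], trans["mi"][k], trans["md"][k] = np.log(p3)
        p2 = rng.dirichlet(np.ones(2))
        trans["im"][k], trans["ii"][k] = np.log(p2)
        p2 = rng.dirichlet(np.ones(2))
        trans["dm"][k], trans["dd"][k] = np.log(p2)
    return ProfileHMM(
        name="toy", M=M, match_logodds=match_lo, insert_logodds=np.zeros((M, 20)),
        transitions=trans, background=background, calibration=calibration,
    )


def write_toy_hmm(path, M: int = 5, with_stats: bool = False, truncate_at: int = None,
                  alph: str = "amino", seed: int = 0) -> None:
    """Write a small, valid HMMER3 ASCII file."""
    rng = np.random.default_rng(seed)
    lines = [
        "HMMER3/f [3.4 | toy]",
        "NAME  toy%d" % M,
        "LENG  %d" % M,
        "ALPH  %s" % alph,
    ]
    if with_stats:
        lines.append("STATS LOCAL MSV      -9.0  0.7")
        lines.append("STATS LOCAL VITERBI  -9.5  0.7")
        lines.append("STATS LOCAL FORWARD  -3.2  0.7")
    lines.append("HMM          " + "        ".join(AMINO20))
    lines.append("            m->m     m->i     m->d     i->m     i->i     d->m     d->d")
    compo = rng.dirichlet(np.ones(20) * 10)
    lines.append("  COMPO   " + "  ".join(f"{-np.log(p):.5f}" for p in compo))
    insert0 = rng.dirichlet(np.ones(20) * 10)
    lines.append("          " + "  ".join(f"{-np.log(p):.5f}" for p in insert0))
    lines.append("          0.01005  5.29832  *  1.00000  0.00000  *  *")
    n_states = truncate_at if truncate_at is not None else M
    for k in range(1, n_states + 1):
        me = rng.dirichlet(np.ones(20))
        ie = rng.dirichlet(np.ones(20) * 10)
        lines.append(f"{k:7d}   " + "  ".join(f"{-np.log(p):.5f}" for p in me)
                     + f"   {k} - - -")
        lines.append("          " + "  ".join(f"{-np.log(p):.5f}" for p in ie))
        if k < M:
            p3 = rng.dirichlet(np.ones(3))
            p2a = rng.dirichlet(np.ones(2))
            p2b = rng.dirichlet(np.ones(2))
            vals = [*p3, *p2a, *p2b]
            lines.append("          " + "  ".join(f"{-np.log(p):.5f}" for p in vals))
        else:
            lines.append("          0.00990  4.62000  *  0.70000  0.70000  *  *")
    lines.append("//")
    path.write_text("\n".join(lines) + "\n")
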