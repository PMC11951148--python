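import math
import shutil
import subprocess

import numpy as np
import pytest

from conftest import random_profile_hmm, write_toy_hmm
from oracle_utils import hmm_path_oracle
from ssnmine.phmm import (
    ProfileHMM,
    build_hmm,
    domain_present,
    forward_score,
    hmm_evalue,
    load_hmm,
    star_msa,
    viterbi_score,
)
from ssnmine.seqio import AMINO20, SeqRecord

_LN2 = math.log(2.0)


class TestLoadHmm:
    def test_toy_file_parses(self, tmp_path):
        p = tmp_path / "toy.hmm"
        write_toy_hmm(p, M=5)
        hmm = load_hmm(p)
        assert hmm.M == 5
        assert hmm.name == "toy5"
        assert hmm.calibration is None
        assert hmm.match_logodds.shape == (5, 20)

    def test_stats_line_populates_calibration(self, tmp_path):
        p = tmp_path / "toy.hmm"
        write_toy_hmm(p, M=4, with_stats=True)
        hmm = load_hmm(p)
        assert hmm.calibration == (-3.2, 0.7)

    def test_truncated_state_block_names_state(self, tmp_path):
        p = tmp_path / "trunc.hmm"
        write_toy_hmm(p, M=5, truncate_at=4)
        with pytest.raises(ValueError, match="state 5"):
            load_hmm(p)

    def test_non_amino_alphabet_rejected(self, tmp_path):
        p = tmp_path / "dna.hmm"
        write_toy_hmm(p, M=3, alph="dna")
        with pytest.raises(ValueError, match="amino"):
            load_hmm(p)

    def test_not_hmmer3_rejected(self, tmp_path):
        p = tmp_path / "x.hmm"
        p.write_text("NAME foo\n")
        with pytest.raises(ValueError, match="HMMER3"):
            load_hmm(p)

    @pytest.mark.skipif(shutil.which("hmmbuild") is None, reason="hmmer not on PATH")
    def test_parses_real_hmmbuild_output(self, tmp_path):
        # hmmbuild as an independent format oracle: a model built from a
        # small family must parse and prefer family members over noise
        rng = np.random.default_rng(4)
        base = "".join(AMINO20[i] for i in rng.integers(0, 20, size=60))
        family = []
        for i in range(4):
            seq = list(base)
            for pos in rng.integers(0, 60, size=6):
                seq[pos] = AMINO20[int(rng.integers(0, 20))]
            family.append("".join(seq))
        msa = tmp_path / "msa.fa"
        msa.write_text("".join(f">s{i}\n{s}\n" for i, s in enumerate(family)))
        out = tmp_path / "fam.hmm"
        subprocess.run(["hmmbuild", "--amino", str(out), str(msa)],
                       check=True, capture_output=True)
        hmm = load_hmm(out)
        assert hmm.M > 0 and hmm.calibration is not None
        member = SeqRecord("m", family[0])
        noise = SeqRecord("n", "".join(AMINO20[i] for i in rng.integers(0, 20, size=60)))
        assert forward_score(hmm, member) > forward_score(hmm, noise) + 20


class TestBuildHmm:
    def test_identical_ungapped_sequences(self):
        msa = [SeqRecord(f"s{i}", "MKVW") for i in range(3)]
        hmm = build_hmm(msa)
        assert hmm.M == 4
        for state, residue in enumerate("MKVW"):
            assert np.argmax(hmm.match_logodds[state]) == AMINO20.index(residue)

    def test_majority_gap_column_becomes_insert(self):
        rows = ["MKVW", "MK-W", "MK-W", "MK-W", "MKVW"]
        # column 3 has 60% gaps -> insert column, M = 3
        msa = [_row(f"s{i}", r) for i, r in enumerate(rows)]
        hmm = build_hmm(msa)
        assert hmm.M == 3

    def test_half_gap_column_stays_match(self):
        rows = ["MKVW", "MK-W", "MKVW", "MK-W"]
        hmm = build_hmm([_row(f"s{i}", r) for i, r in enumerate(rows)])
        assert hmm.M == 4

    def test_infinite_pseudocount_limit_is_background(self):
        msa = [SeqRecord(f"s{i}", "MKVW") for i in range(3)]
        hmm = build_hmm(msa, pseudocount_weight=1e12)
        assert np.abs(hmm.match_logodds).max() < 1e-6

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_hmm([SeqRecord("s", "MKVW")])

    def test_all_gap_column_skipped_with_warning(self):
        rows = ["MK-W", "MK-W", "MK-W"]
        with pytest.warns(UserWarning, match="all-gap"):
            hmm = build_hmm([_row(f"s{i}", r) for i, r in enumerate(rows)])
        assert hmm.M == 3

    def test_model_built_from_copies_scores_its_sequence_positively(self):
        seq = "MWCYCRLMKV"
        hmm = build_hmm([SeqRecord(f"s{i}", seq) for i in range(5)])
        assert forward_score(hmm, SeqRecord("q", seq)) > 0


class TestScoringOracles:
    def test_forward_and_viterbi_match_path_enumeration(self):
        rng = np.random.default_rng(123)
        reduced = "ACDG"
        for _ in range(200):
            M = int(rng.integers(1, 4))
            L = int(rng.integers(1, 6))
            hmm = random_profile_hmm(rng, M)
            seq = "".join(reduced[i] for i in rng.integers(0, 4, size=L))
            rec = SeqRecord("s", seq)
            f = forward_score(hmm, rec) * _LN2
            v = viterbi_score(hmm, rec) * _LN2
            bf = hmm_path_oracle(hmm, seq, "forward")
            bv = hmm_path_oracle(hmm, seq, "viterbi")
            assert f == pytest.approx(bf, rel=1e-9, abs=1e-9)
            assert v == pytest.approx(bv, rel=1e-9, abs=1e-9)
            assert v <= f + 1e-12

    def test_x_sequence_scores_at_most_zero(self):
        rng = np.random.default_rng(7)
        hmm = random_profile_hmm(rng, 3)
        assert forward_score(hmm, SeqRecord("x", "XXXXX")) <= 0.0


class TestDomainPresent:
    def test_bit_score_at_gumbel_mu_gives_evalue_one(self):
        rng = np.random.default_rng(1)
        hmm = random_profile_hmm(rng, 2, calibration=(0.0, 0.7))
        bits = forward_score(hmm, SeqRecord("s", "MKVW"))
        mu_adjusted = (bits, 0.7)
        hmm.calibration = mu_adjusted  # place mu exactly at this score
        assert hmm_evalue(hmm, bits) == pytest.approx(1.0)
        assert domain_present(hmm, SeqRecord("s", "MKVW"), evalue_cutoff=1.0).present
        assert not domain_present(hmm, SeqRecord("s", "MKVW"), evalue_cutoff=0.5).present

    def test_uncalibrated_bit_cutoff(self):
        rng = np.random.default_rng(2)
        hmm = random_profile_hmm(rng, 2)
        hit = domain_present(hmm, SeqRecord("s", "MK"), bit_cutoff=-1e9)
        assert hit.present and hit.evalue is None

    def test_evalue_cutoff_on_uncalibrated_model_instructs_bit_cutoff(self):
        rng = np.random.default_rng(3)
        hmm = random_profile_hmm(rng, 2)
        with pytest.raises(ValueError, match="bit-score cutoff"):
            domain_present(hmm, SeqRecord("s", "MK"), evalue_cutoff=1e-3)

    def test_exactly_one_cutoff_required(self):
        rng = np.random.default_rng(4)
        hmm = random_profile_hmm(rng, 2)
        with pytest.raises(ValueError, match="exactly one"):
            domain_present(hmm, SeqRecord("s", "MK"))
        with pytest.raises(ValueError, match="exactly one"):
            domain_present(hmm, SeqRecord("s", "MK"), evalue_cutoff=1e-3, bit_cutoff=5)

    def test_tightening_cutoff_never_flips_absent_to_present(self):
        rng = np.random.default_rng(5)
        hmm = random_profile_hmm(rng, 3, calibration=(0.0, 0.7))
        seqs = [SeqRecord(f"s{i}", "".join(AMINO20[j] for j in rng.integers(0, 20, size=8)))
                for i in range(20)]
        for cut_loose, cut_tight in [(1e-3, 1e-30), (1.0, 1e-3)]:
            loose = {s.id for s in seqs if domain_present(hmm, s, evalue_cutoff=cut_loose).present}
            tight = {s.id for s in seqs if domain_present(hmm, s, evalue_cutoff=cut_tight).present}
            assert tight <= loose


def test_star_msa_rows_have_anchor_length(scheme):
    anchor = SeqRecord("a", "MKVWEDRLCH" * 4)
    other = SeqRecord("b", anchor.residues[:18] + anchor.residues[22:])
    rows = star_msa(anchor, [other], scheme)
    assert all(len(r.residues) == anchor.length for r in rows)
    hmm = build_hmm(rows)
    assert forward_score(hmm, anchor) > 0


class _Row:
    pass


def _row(rec_id, residues):
    from ssnmine.phmm import _AlignedRow

    return _AlignedRow(rec_id, residues)
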