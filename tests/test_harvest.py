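import numpy as np
import pytest

from conftest import random_profile_hmm
from ssnmine.align import align_local
from ssnmine.harvest import (
    HarvestConfig,
    cutoff_sweep,
    domain_search,
    profile_search,
    run_harvest,
    similarity_search,
)
from ssnmine.phmm import build_hmm
from ssnmine.seqio import AMINO20, SeqRecord
from ssnmine.synth import SynthConfig, generate


def _random_seq(rng, length):
    return "".join(AMINO20[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture(scope="module")
def family():
    """A bait, six close homologs, one distant relative and one decoy.

    The distant relative sits below the working cutoff against the
    bait alone but within profile reach of the bait-anchored PSSM.
    """
    from ssnmine.synth import _conditional_no_identity, _draw_ancestor, _substitute, _to_str

    rng = np.random.default_rng(5)
    cond = _conditional_no_identity()
    anc = _draw_ancestor(rng, 200)
    bait = SeqRecord("bait", _to_str(anc))
    hits = [SeqRecord(f"h{i}", _to_str(_substitute(anc, 0.12, rng, cond))) for i in range(6)]
    distant = SeqRecord(
        "dist", _to_str(_substitute(_substitute(anc, 0.30, rng, cond), 0.25, rng, cond))
    )
    decoy = SeqRecord("decoy", _to_str(_draw_ancestor(rng, 200)))
    return bait, hits, distant, decoy


class TestSimilaritySearch:
    def test_exact_bait_copy_always_hits(self, family, scheme):
        bait, hits, distant, decoy = family
        copy = SeqRecord("copy", bait.residues)
        self_e = align_local(bait, copy, scheme).evalue
        found = similarity_search([bait], [copy], scheme, evalue_cutoff=max(self_e, 1e-200))
        assert "copy" in found
        assert found["copy"][0] == "bait"

    def test_unrelated_random_database_empty_at_tight_cutoff(self, scheme):
        rng = np.random.default_rng(11)
        bait = SeqRecord("bait", _random_seq(rng, 150))
        db = [SeqRecord(f"r{i}", _random_seq(rng, 150)) for i in range(10)]
        assert similarity_search([bait], db, scheme, 1e-100) == {}

    def test_loosening_cutoff_grows_hit_set_monotonically(self, family, scheme):
        bait, hits, distant, decoy = family
        db = hits + [distant, decoy]
        previous = set()
        for cutoff in (1e-100, 1e-60, 1e-40, 1e-20, 1e-3):
            current = set(similarity_search([bait], db, scheme, cutoff))
            assert previous <= current
            previous = current

    def test_empty_bait_set_rejected(self, scheme):
        with pytest.raises(ValueError):
            similarity_search([], [SeqRecord("a", "MKV")], scheme, 1e-3)


class TestProfileSearch:
    def test_distant_member_recruited_only_by_profile_round(self, family, scheme):
        bait, hits, distant, decoy = family
        db = hits + [distant, decoy]
        cutoff = 1e-60
        round0 = set(similarity_search([bait], db, scheme, cutoff))
        assert "dist" not in round0
        profiled = profile_search([bait], db, scheme, cutoff, iterations=1)
        assert "dist" in profiled
        assert "decoy" not in profiled

    def test_result_is_superset_of_round_zero_for_every_iteration(self, family, scheme):
        bait, hits, distant, decoy = family
        db = hits + [distant, decoy]
        round0 = set(similarity_search([bait], db, scheme, 1e-60))
        prev = round0
        for k in (1, 2):
            cur = profile_search([bait], db, scheme, 1e-60, iterations=k)
            assert prev <= cur
            prev = cur

    def test_fixed_point_when_nothing_new(self, family, scheme):
        bait, hits, _, _ = family
        got = profile_search([bait], hits, scheme, 1e-3, iterations=1)
        assert got == set(similarity_search([bait], hits, scheme, 1e-3))


class TestDomainSearch:
    def test_bait_family_hmm_detects_copies(self, scheme):
        seq = "MWCYCRLMKVEDRH" * 5
        hmm = build_hmm([SeqRecord(f"s{i}", seq) for i in range(3)], name="fam")
        db = [SeqRecord("c1", seq), SeqRecord("c2", seq)]
        per_hmm, _ = domain_search([hmm], db, evalue_cutoff=None, bit_cutoff=10.0)
        assert per_hmm["fam"] == {"c1", "c2"}

    def test_random_sequence_absent(self, scheme):
        rng = np.random.default_rng(3)
        seq = "MWCYCRLMKVEDRH" * 5
        hmm = build_hmm([SeqRecord(f"s{i}", seq) for i in range(3)], name="fam")
        noise = SeqRecord("noise", _random_seq(rng, 70))
        per_hmm, _ = domain_search([hmm], [noise], evalue_cutoff=None, bit_cutoff=10.0)
        assert per_hmm["fam"] == set()

    def test_lacking_accounting(self):
        seq_a = "MWCYCRLMKVEDRH" * 4
        seq_b = "QNGSTPILFWYAHK" * 4
        hmm_a = build_hmm([SeqRecord(f"a{i}", seq_a) for i in range(3)], name="hmmA")
        hmm_b = build_hmm([SeqRecord(f"b{i}", seq_b) for i in range(3)], name="hmmB")
        db = [SeqRecord("onlyA", seq_a)]
        per_hmm, lacking = domain_search(
            [hmm_a, hmm_b], db, evalue_cutoff=None, bit_cutoff=10.0,
            similarity_hits={"onlyA"},
        )
        assert lacking == {"lacking_hmmA": 0, "lacking_hmmB": 1, "lacking_all": 0}


@pytest.fixture(scope="module")
def planted():
    cfg = SynthConfig(
        seed=21, n_families=2, family_size=5, ancestor_length=760,
        fragment_fraction=0.4, n_novel_singletons=0, indel_rate=0.0,
    )
    records, meta, truth = generate(cfg)
    from ssnmine.seqio import attach_metadata

    return attach_metadata(records, meta), truth


class TestRunHarvest:
    def test_full_length_retained_fragments_excluded(self, planted, scheme):
        records, truth = planted
        baits = [r for r in records if r.is_reference]
        config = HarvestConfig(
            similarity_evalue_cutoff=1e-20, strategies=("similarity",), min_length=700)
        res = run_harvest(config, baits, records, scheme=scheme)
        frags = {t for t in truth[truth["truth"].str.startswith("fragment")]["id"]}
        assert set(res.retained_ids) == {r.id for r in records} - frags
        assert {i for i, s in res.status.items() if s == "too_short"} == frags

    def test_min_length_zero_retains_union(self, planted, scheme):
        records, _ = planted
        baits = [r for r in records if r.is_reference]
        config = HarvestConfig(
            similarity_evalue_cutoff=1e-20, strategies=("similarity",), min_length=1)
        res = run_harvest(config, baits, records, scheme=scheme)
        assert set(res.retained_ids) == res.hit_ids

    def test_length_filter_boundary_is_inclusive(self, scheme):
        # lengths 650/699/700/733/785 with min_length 700 -> exactly 3 kept
        rng = np.random.default_rng(17)
        base = _random_seq(rng, 785)
        lengths = [650, 699, 700, 733, 785]
        db = [SeqRecord(f"len{n}", base[:n]) for n in lengths]
        bait = SeqRecord("bait", base)
        config = HarvestConfig(
            similarity_evalue_cutoff=1e-20, strategies=("similarity",), min_length=700)
        res = run_harvest(config, [bait], db, scheme=scheme)
        assert sorted(res.retained_ids) == ["len700", "len733", "len785"]

    def test_venn_cells_partition_union_of_hits(self, planted, scheme):
        records, _ = planted
        baits = [r for r in records if r.is_reference]
        hmm = build_hmm([SeqRecord(f"c{i}", baits[0].residues) for i in range(2)],
                        name="ref_hmm")
        config = HarvestConfig(
            similarity_evalue_cutoff=1e-20, strategies=("similarity", "domain"),
            hmm_bit_cutoff=25.0, min_length=700)
        res = run_harvest(config, baits, records, hmms=[hmm], scheme=scheme)
        assert sum(res.venn.values()) == len(res.hit_ids)

    def test_all_strategies_disabled_is_config_error(self):
        with pytest.raises(ValueError):
            HarvestConfig(strategies=())

    def test_domain_strategy_without_hmms_rejected(self, planted, scheme):
        records, _ = planted
        baits = [r for r in records if r.is_reference]
        config = HarvestConfig(strategies=("domain",))
        with pytest.raises(ValueError, match="no HMMs"):
            run_harvest(config, baits, records, scheme=scheme)

    def test_bait_length_range_reported(self, planted, scheme):
        records, _ = planted
        baits = [r for r in records if r.is_reference]
        config = HarvestConfig(strategies=("similarity",), similarity_evalue_cutoff=1e-20)
        res = run_harvest(config, baits, records, scheme=scheme)
        lo, hi = res.bait_length_range
        assert lo == min(b.length for b in baits)
        assert hi == max(b.length for b in baits)


def test_cutoff_sweep_is_monotone(family, scheme):
    bait, hits, distant, decoy = family
    db = hits + [distant, decoy]
    config = HarvestConfig(strategies=("similarity",), min_length=1)
    table = cutoff_sweep([1e-100, 1e-60, 1e-40, 1e-10], config, [bait], db, scheme=scheme)
    assert (table["retained"].diff().dropna() >= 0).all()
    assert (table["hits"].diff().dropna() >= 0).all()
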