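import itertools

import numpy as np
import pytest

from conftest import oracle_consensus, oracle_match, random_chopping
from tedkit.consensus import (
    consensus_assign,
    domain_iou,
    match_choppings,
    summarize_targets,
)
from tedkit.io_formats import parse_chopping


def rs(text):
    return parse_chopping(text).residue_sets()


class TestDomainIoU:
    def test_identical(self):
        assert domain_iou(range(1, 101), range(1, 101)) == 1.0

    def test_half_overlap(self):
        assert domain_iou(range(1, 101), range(51, 151)) == pytest.approx(50 / 150)

    def test_discontinuous(self):
        a = set(range(1, 51)) | set(range(120, 181))
        b = set(range(1, 61))
        assert domain_iou(a, b) == pytest.approx(50 / 121)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            domain_iou(set(), {1})


class TestMatchChoppings:
    def test_identical_choppings(self):
        c = parse_chopping("1-100,101-200,201-260")
        assert match_choppings(c, c) == [(0, 0), (1, 1), (2, 2)]

    def test_split_below_threshold(self):
        x = parse_chopping("1-100,101-200")
        y = parse_chopping("1-200")
        assert match_choppings(x, y, iou_min=0.7) == []

    def test_split_above_threshold(self):
        x = parse_chopping("1-100,101-200")
        y = parse_chopping("1-200")
        assert match_choppings(x, y, iou_min=0.4) in ([(0, 0)], [(1, 0)])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_assignment(self, seed):
        rng = np.random.default_rng(seed)
        x = random_chopping(rng)
        y = random_chopping(rng)
        got = match_choppings(x, y, iou_min=0.3)
        want, want_total = oracle_match(x.residue_sets(), y.residue_sets(), 0.3)
        sx, sy = x.residue_sets(), y.residue_sets()
        got_total = sum(
            len(sx[i] & sy[j]) / len(sx[i] | sy[j]) for i, j in got
        )
        assert got_total == pytest.approx(want_total, abs=1e-9)
        assert sorted(got) == want

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(99)
        x, y = random_chopping(rng), random_chopping(rng)
        fwd = match_choppings(x, y, iou_min=0.3)
        rev = match_choppings(y, x, iou_min=0.3)
        assert sorted((j, i) for i, j in fwd) == sorted(rev)


class TestConsensusAssign:
    def test_three_identical(self):
        c = parse_chopping("1-100,101-200")
        res = consensus_assign(c, c, c)
        assert res.n_domains == 2
        assert all(d.confidence == "high" for d in res.domains)
        assert res.ndr_residues == frozenset()

    def test_boundary_vote(self):
        # residues kept iff assigned by >= 2 of the 3 supporting methods
        m1 = parse_chopping("1-100")
        m2 = parse_chopping("3-98")
        m3 = parse_chopping("5-103")
        res = consensus_assign(m1, m2, m3)
        assert res.n_domains == 1
        dom = res.domains[0]
        assert dom.confidence == "high"
        assert dom.residues == frozenset(range(3, 101))
        assert res.ndr_residues == frozenset({1, 2, 101, 102, 103})

    def test_two_method_agreement_is_medium(self):
        m1 = parse_chopping("1-100,101-200")
        m2 = parse_chopping("1-100,101-200")
        m3 = parse_chopping("1-200")
        res = consensus_assign(m1, m2, m3)
        assert res.n_domains == 2
        assert all(d.confidence == "medium" for d in res.domains)
        assert {min(d.residues) for d in res.domains} == {1, 101}

    def test_min_len_discards_into_ndr(self):
        c = parse_chopping("1-20")
        res = consensus_assign(c, c, c, min_len=25)
        assert res.n_domains == 0
        assert res.ndr_residues == frozenset(range(1, 21))

    def test_mismatched_chain_residues_rejected(self):
        c = parse_chopping("1-100")
        with pytest.raises(ValueError):
            consensus_assign(c, c, c, chain_residues=range(1, 51))

    @pytest.mark.parametrize("seed", range(40))
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(1000 + seed)
        chops = [random_chopping(rng, source=f"m{i}") for i in range(3)]
        res = consensus_assign(*chops, iou_min=0.5, min_len=25)
        got = {(d.confidence, d.residues) for d in res.domains}
        assert got == oracle_consensus(chops, iou_min=0.5, min_len=25)

    @pytest.mark.parametrize("seed", range(10))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(2000 + seed)
        chops = [random_chopping(rng, source=f"m{i}") for i in range(3)]
        base = consensus_assign(*chops)
        base_desc = [(d.confidence, d.residues) for d in base.domains]
        for perm in itertools.permutations(chops):
            res = consensus_assign(*perm)
            assert [(d.confidence, d.residues) for d in res.domains] == base_desc
            assert res.ndr_residues == base.ndr_residues

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_property(self, seed):
        rng = np.random.default_rng(3000 + seed)
        chops = [random_chopping(rng) for _ in range(3)]
        res = consensus_assign(*chops)
        union = set(res.ndr_residues)
        total = len(res.ndr_residues)
        for d in res.domains:
            union |= d.residues
            total += len(d.residues)
        all_res = set()
        for c in chops:
            all_res |= c.all_residues()
        assert union == all_res
        assert total == len(all_res)  # no residue counted twice

    @pytest.mark.parametrize("seed", range(10))
    def test_agreement_monotonicity(self, seed):
        rng = np.random.default_rng(4000 + seed)
        chops = [random_chopping(rng) for _ in range(3)]
        counts = [
            consensus_assign(*chops, iou_min=t).n_domains for t in (0.5, 0.7, 0.9)
        ]
        assert counts[0] >= counts[1] >= counts[2]


class TestSummarize:
    def test_all_single(self):
        c = parse_chopping("1-100")
        results = [consensus_assign(c, c, c, chain_id=str(i)) for i in range(10)]
        s = summarize_targets(results)
        assert s["frac_single"] == 1.0 and s["n_single"] == 10

    def test_equal_thirds(self):
        zero = consensus_assign(
            parse_chopping("1-100"), parse_chopping("101-200"),
            parse_chopping("201-300"))
        one = consensus_assign(*[parse_chopping("1-100")] * 3)
        two = consensus_assign(*[parse_chopping("1-100,101-200")] * 3)
        s = summarize_targets([zero, one, two])
        assert (s["frac_none"], s["frac_single"], s["frac_multi"]) == (
            pytest.approx(1 / 3), pytest.approx(1 / 3), pytest.approx(1 / 3))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_targets([])
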