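import itertools

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from tedkit.classification import CathCode, DomainLabel
from tedkit.consensus import ConsensusDomain, ConsensusResult
from tedkit.geometry import Transform
from tedkit.interactions import (
    ISPInstance,
    ISPSummary,
    cio,
    classify_hub,
    compare_isp_sets,
    detect_contact,
    enrichment,
    export_interaction_graph,
    extract_isps,
    inter_domain_pae,
    isp_key,
    summarize_isps,
)
from tedkit.io_formats import PAEMatrix, ResidueChain
from tedkit.synthetic import make_chain, make_isp_ensemble, make_pae


class TestDetectContact:
    def test_far_apart(self):
        a = np.random.default_rng(0).normal(size=(20, 3))
        b = a + np.array([40.0, 0, 0])
        ok, mind = detect_contact(a, b)
        assert not ok
        assert mind == pytest.approx(40.0, abs=5.0)

    def test_packed_pair_counts(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(30, 3)) * 4
        b = rng.normal(size=(30, 3)) * 4 + np.array([6.0, 0, 0])
        ok, mind = detect_contact(a, b, dist_max=8.0, min_pairs=3)
        n_pairs = (np.linalg.norm(a[:, None] - b[None], axis=2) <= 8.0).sum()
        assert ok == (n_pairs >= 3)
        assert mind < 8.0

    def test_single_touching_pair_boundary(self):
        a = np.array([[0.0, 0, 0], [0, 100, 0], [0, 0, 100]])
        b = np.array([[7.9, 0, 0], [200.0, 200, 200], [300.0, 300, 300]])
        ok, mind = detect_contact(a, b, dist_max=8.0, min_pairs=1)
        assert ok and mind == pytest.approx(7.9, abs=1e-9)


class TestInterDomainPAE:
    def test_constant(self):
        pae = PAEMatrix(np.full((10, 10), 5.0))
        assert inter_domain_pae(pae, range(1, 6), range(6, 11)) == 5.0

    def test_asymmetric_blocks_average(self):
        v = np.zeros((4, 4))
        v[:2, 2:] = 4.0
        v[2:, :2] = 8.0
        assert inter_domain_pae(PAEMatrix(v), {1, 2}, {3, 4}) == 6.0

    def test_synthetic_two_domain(self):
        pae = make_pae([30, 40], intra_level=3.0, inter_level=15.0)
        assert inter_domain_pae(pae, range(1, 31), range(31, 71)) == 15.0

    def test_overlap_rejected(self):
        pae = PAEMatrix(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            inter_domain_pae(pae, {1, 2, 3}, {3, 4})

    def test_out_of_range_rejected(self):
        pae = PAEMatrix(np.zeros((5, 5)))
        with pytest.raises(KeyError):
            inter_domain_pae(pae, {1, 2}, {6})


def two_domain_input(inter_pae_level, seed=5, dom_len=40):
    ens = make_isp_ensemble(1, kappa=np.inf, seed=seed, dom_len=dom_len)
    chain, cons, labels, _ = ens["chains"][0]
    pae = make_pae([dom_len, dom_len], intra_level=3.0,
                   inter_level=inter_pae_level)
    return chain, cons, labels, pae


class TestExtractISPs:
    def test_contacting_pair_with_good_pae(self):
        inst = extract_isps([two_domain_input(6.0)], pae_max=10.0)
        assert len(inst) == 1
        assert inst[0].inter_pae == pytest.approx(6.0, abs=1e-9)

    def test_bad_pae_filters_out(self):
        assert extract_isps([two_domain_input(18.0)], pae_max=10.0) == []

    def test_unlabelled_domain_skipped(self):
        chain, cons, labels, pae = two_domain_input(6.0)
        labels = dict(labels)
        first = sorted(labels)[0]
        labels[first] = DomainLabel(first, "none", None, "")
        assert extract_isps([(chain, cons, labels, pae)]) == []

    def test_missing_pae_rejected(self):
        chain, cons, labels, _ = two_domain_input(6.0)
        with pytest.raises(ValueError):
            extract_isps([(chain, cons, labels, None)], pae_max=10.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_all_pairs(self, seed):
        # chains of up to 6 domains; no PAE filter so geometry decides
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        chain, truth = make_chain([40] * k, seed=seed, chain_id=f"C{seed}")
        sets = truth.residue_sets()
        cons = ConsensusResult(
            chain_id=chain.chain_id,
            domains=[ConsensusDomain(s, "high", frozenset({"m1", "m2", "m3"}))
                     for s in sets],
            ndr_residues=chain.residue_set - frozenset().union(*sets),
        )
        labels = {}
        for i in range(k):
            did = f"{chain.chain_id}_{i + 1:02d}"
            labels[did] = DomainLabel(did, "H", CathCode(1, 10, 8, 10 + i),
                                      "structure_search")
        got = extract_isps([(chain, cons, labels, None)], pae_max=None)
        got_pairs = {(x.domain_a_id, x.domain_b_id) for x in got}
        want = set()
        for i, j in itertools.combinations(range(k), 2):
            ok, _ = detect_contact(chain.coords_for(sets[i]),
                                   chain.coords_for(sets[j]))
            if ok:
                want.add((f"{chain.chain_id}_{i + 1:02d}",
                          f"{chain.chain_id}_{j + 1:02d}"))
        assert got_pairs == want


class TestCIO:
    def test_identical_instances_give_one(self):
        ens = make_isp_ensemble(8, kappa=np.inf, seed=2)
        inst = extract_isps(ens["chains"])
        res = cio(inst, ens["domain_coords"])
        assert res.cio == pytest.approx(1.0, abs=1e-9)
        assert res.n == 8

    def test_antipodal_pair_gives_zero(self):
        base, _ = make_chain([40], seed=9)
        A = base.ca_coords
        insts, coords = [], {}
        for i, sign in enumerate((1.0, -1.0)):
            B = A + sign * np.array([15.0, 0, 0])
            ra, rb = f"i{i}_a", f"i{i}_b"
            coords[ra], coords[rb] = A, B
            insts.append(ISPInstance(
                chain_id=f"i{i}", domain_a_id=ra, domain_b_id=rb,
                code_a=CathCode(1, 10, 10, 10), code_b=CathCode(3, 40, 50, 300),
                min_ca_dist=5.0, inter_pae=5.0,
                com_a=A.mean(axis=0), com_b=B.mean(axis=0)))
        res = cio(insts, coords)
        assert res.cio == pytest.approx(0.0, abs=1e-9)

    def test_uniform_orientations_low_cio(self):
        ens = make_isp_ensemble(400, kappa=0.0, seed=3)
        inst = extract_isps(ens["chains"])
        res = cio(inst, ens["domain_coords"])
        # mean resultant length of n uniform directions ~ 1/sqrt(n)
        assert res.cio < 0.15

    def test_concentration_monotonicity(self):
        vals = []
        for kappa in (0.0, 5.0, 50.0):
            ens = make_isp_ensemble(200, kappa=kappa, seed=4)
            inst = extract_isps(ens["chains"])
            vals.append(cio(inst, ens["domain_coords"]).cio)
        assert vals[0] < vals[1] < vals[2]

    def test_rigid_motion_invariance(self, rng):
        ens = make_isp_ensemble(20, kappa=5.0, seed=6)
        inst = extract_isps(ens["chains"])
        base = cio(inst, ens["domain_coords"]).cio
        R = special_ortho_group.rvs(3, random_state=rng)
        tr = Transform(R, np.array([11.0, -4.0, 2.0]))
        moved = {k: tr.apply(v) for k, v in ens["domain_coords"].items()}
        assert cio(inst, moved).cio == pytest.approx(base, abs=1e-6)

    def test_instance_order_invariance(self):
        ens = make_isp_ensemble(10, kappa=2.0, seed=7)
        inst = extract_isps(ens["chains"])
        a = cio(inst, ens["domain_coords"]).cio
        b = cio(list(reversed(inst)), ens["domain_coords"]).cio
        assert a == pytest.approx(b, abs=1e-12)

    def test_fewer_than_two_rejected(self):
        ens = make_isp_ensemble(1, kappa=np.inf, seed=8)
        inst = extract_isps(ens["chains"])
        with pytest.raises(ValueError):
            cio(inst, ens["domain_coords"])


class TestEnrichment:
    def test_examples(self):
        assert enrichment(8, 2) == 2.0
        assert enrichment(5, 5) == 0.0

    def test_overall_instance_totals(self):
        assert enrichment(27_280_057, 196_234) == pytest.approx(7.119, abs=0.005)

    def test_antisymmetric(self):
        assert enrichment(12, 3) == -enrichment(3, 12)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            enrichment(0, 5)


class TestHubs:
    @pytest.mark.parametrize(
        "n, cls", [(0, "small"), (3, "small"), (4, "medium"), (7, "medium"),
                   (8, "large"), (9, "large")])
    def test_classes(self, n, cls):
        assert classify_hub(n) == cls

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_hub(-1)


class TestCompareSets:
    def test_identical(self):
        s = {("1.1.1.1", "2.2.2.2")}
        out = compare_isp_sets(s, s)
        assert out["n_only_a"] == out["n_only_b"] == 0

    def test_unordered_equality(self):
        out = compare_isp_sets({("A", "B")}, {("B", "A")})
        assert out["n_common"] == 1

    def test_printed_set_arithmetic(self):
        # 13,771 pairs of which 10,701 unique to the first set; the second
        # set holds the 3,070 shared pairs plus its own unique ones (5,111)
        ted = {(f"t{i}", f"t{i}'") for i in range(13_771)}
        shared = set(itertools.islice(ted, 13_771 - 10_701))
        cath = shared | {(f"c{i}", f"c{i}'") for i in range(5_111 - len(shared))}
        out = compare_isp_sets(ted, cath)
        assert out["n_common"] == 3_070
        assert out["n_only_b"] == 2_041
        assert out["n_only_a"] == 10_701


class TestGraphExport:
    def test_single_isp(self):
        g, edges, nodes = export_interaction_graph(
            [ISPSummary(isp_key(CathCode(1, 1, 1, 1), CathCode(2, 2, 2, 2)), 5, False)])
        assert len(edges) == 1
        assert all(n["hub_class"] == "small" for n in nodes)

    def test_star_hub_is_large(self):
        hub = CathCode(1, 1, 1, 1)
        summaries = [
            ISPSummary(isp_key(hub, CathCode(2, 2, 2, i)), 1, False)
            for i in range(1, 10)
        ]
        _, _, nodes = export_interaction_graph(summaries)
        by_code = {n["code"]: n for n in nodes}
        assert by_code["1.1.1.1"]["hub_class"] == "large"
        assert by_code["1.1.1.1"]["n_partners"] == 9

    def test_degrees_match_generator(self, rng):
        codes = [CathCode(1, 1, 1, i) for i in range(12)]
        pairs = set()
        while len(pairs) < 15:
            i, j = rng.integers(0, 12, size=2)
            if i != j:
                pairs.add(isp_key(codes[min(i, j)], codes[max(i, j)]))
        summaries = [ISPSummary(p, 1, False) for p in sorted(pairs)]
        _, edges, nodes = export_interaction_graph(summaries)
        degree = {}
        for a, b in pairs:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        assert {n["code"]: n["n_partners"] for n in nodes} == degree
        assert len(edges) == len(pairs)


def test_summarize_isps_groups_and_counts():
    ens = make_isp_ensemble(5, kappa=np.inf, seed=10)
    inst = extract_isps(ens["chains"])
    summ = summarize_isps(inst)
    assert len(summ) == 1
    assert summ[0].n_instances == 5
    assert not summ[0].homotypic
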