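import pytest

from tedkit.classification import (
    CathCode,
    ClusterRecord,
    DomainLabel,
    assign_label,
    plddt_bin,
    propagate_cluster_labels,
    validate_with_hmm,
)


def hit(code, score, kind="structure_search"):
    return {"target_code": code, "score": score, "kind": kind}


class TestCathCode:
    def test_parse_and_str(self):
        assert str(CathCode.parse("3.40.50.300")) == "3.40.50.300"
        assert CathCode.parse("3.40.50").level == "T"
        assert CathCode.parse("3.40.50.300").level == "H"
        assert CathCode.parse("3.40.50.300").topology() == CathCode(3, 40, 50)

    @pytest.mark.parametrize("bad", ["3.40", "3.40.50.300.1", "a.b.c", ""])
    def test_malformed(self, bad):
        with pytest.raises(ValueError):
            CathCode.parse(bad)


class TestAssignLabel:
    def test_no_hits(self):
        lab = assign_label("d1", [])
        assert lab.level == "none" and lab.code is None

    def test_structure_hit_gives_h(self):
        lab = assign_label("d1", [hit("3.40.50.300", 0.9)])
        assert lab.level == "H" and str(lab.code) == "3.40.50.300"
        assert lab.source == "structure_search"

    def test_nearest_neighbour_is_topology_level(self):
        lab = assign_label("d1", [hit("3.40.50.300", 0.9, "nearest_neighbour")])
        assert lab.level == "T"
        assert str(lab.code) == "3.40.50"

    def test_below_score_min_falls_through(self):
        lab = assign_label("d1", [hit("3.40.50.300", 0.2)], score_min=0.5)
        assert lab.level == "none"

    def test_topology_hit_gives_t(self):
        lab = assign_label("d1", [hit("3.40.50", 0.8)])
        assert lab.level == "T" and str(lab.code) == "3.40.50"

    def test_equal_score_tie_breaks_lexicographically(self):
        lab = assign_label(
            "d1", [hit("1.10.8.10", 0.8), hit("1.10.10.10", 0.8)])
        assert str(lab.code) == "1.10.10.10"

    def test_higher_score_wins(self):
        lab = assign_label(
            "d1", [hit("1.10.8.10", 0.9), hit("1.10.10.10", 0.8)])
        assert str(lab.code) == "1.10.8.10"

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            assign_label("d1", [hit("1.10.8.10", 0.9, "blast")])

    def test_nn_label_invariant(self):
        with pytest.raises(ValueError):
            DomainLabel("d", "H", CathCode.parse("1.2.3.4"), "nearest_neighbour")


class TestPropagate:
    def make(self, pattern):
        clusters, labels = [], {}
        for i, labelled in enumerate(pattern):
            members = [f"c{i}_m{j}" for j in range(3)]
            clusters.append(ClusterRecord(f"cl{i}", members))
            for j, m in enumerate(members):
                if labelled and j == 0:
                    labels[m] = DomainLabel(m, "H", CathCode.parse("1.10.10.10"),
                                            "structure_search")
                else:
                    labels[m] = DomainLabel(m, "none", None, "")
        return clusters, labels

    def test_one_labelled_member_suffices(self):
        clusters, labels = self.make([True])
        assert propagate_cluster_labels(clusters, labels)["n_labelled"] == 1

    def test_all_none_is_unlabelled(self):
        clusters, labels = self.make([False])
        part = propagate_cluster_labels(clusters, labels)
        assert part["n_unlabelled"] == 1 and part["n_labelled"] == 0

    def test_known_pattern_recovered(self):
        clusters, labels = self.make([True] * 7 + [False] * 3)
        part = propagate_cluster_labels(clusters, labels)
        assert (part["n_labelled"], part["n_unlabelled"]) == (7, 3)

    def test_partition_completeness(self):
        clusters, labels = self.make([True, False, True, False])
        part = propagate_cluster_labels(clusters, labels)
        ids = sorted(
            c.cluster_id for c in part["labelled_clusters"] + part["unlabelled_clusters"]
        )
        assert ids == sorted(c.cluster_id for c in clusters)

    def test_unknown_member_rejected(self):
        clusters, labels = self.make([True])
        clusters[0].member_domain_ids.append("ghost")
        with pytest.raises(KeyError):
            propagate_cluster_labels(clusters, labels)


class TestValidateWithHmm:
    def lab(self, code):
        return DomainLabel("d", "H", CathCode.parse(code), "structure_search")

    @pytest.mark.parametrize(
        "struct, hmm, verdict",
        [
            ("3.40.50.300", "3.40.50.300", "confirmed_superfamily"),
            ("3.40.50.300", "3.40.50.720", "confirmed_fold"),
            ("3.40.50.300", "2.60.40.10", "unconfirmed"),
            ("3.40.50.300", None, "no_hmm_hit"),
            ("3.40.50.300", "3.40.50", "confirmed_fold"),
        ],
    )
    def test_verdicts(self, struct, hmm, verdict):
        hmm_code = None if hmm is None else CathCode.parse(hmm)
        assert validate_with_hmm(self.lab(struct), hmm_code) == verdict

    def test_fold_level_symmetric_in_h_digit(self):
        a = validate_with_hmm(self.lab("3.40.50.300"), CathCode.parse("3.40.50.720"))
        b = validate_with_hmm(self.lab("3.40.50.720"), CathCode.parse("3.40.50.300"))
        assert a == b == "confirmed_fold"

    def test_unlabelled_rejected(self):
        with pytest.raises(ValueError):
            validate_with_hmm(DomainLabel("d", "none", None, ""), None)


class TestPlddtBin:
    @pytest.mark.parametrize(
        "value, bin_",
        [
            (92.0, "very_high"),
            (90.0, "very_high"),
            (70.0, "high"),
            (89.99, "high"),
            (50.0, "low"),
            (69.99, "low"),
            (49.99, "very_low"),
            (0.0, "very_low"),
            (100.0, "very_high"),
        ],
    )
    def test_bins(self, value, bin_):
        assert plddt_bin(value) == bin_

    def test_monotone_step_function(self):
        order = {"very_low": 0, "low": 1, "high": 2, "very_high": 3}
        values = [order[plddt_bin(v)] for v in [x / 2 for x in range(0, 201)]]
        assert values == sorted(values)

    @pytest.mark.parametrize("bad", [-0.1, 100.1])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            plddt_bin(bad)
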