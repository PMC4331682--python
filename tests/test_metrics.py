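import math

import numpy as np
import pytest

from csrwalign.consistency import CorrespondenceSet
from csrwalign.csrw_core import pair_correspondence
from csrwalign.metrics import (alignment_accuracy, class_metrics,
                               conserved_interactions, coverage_profile,
                               evaluate, expected_accuracy, filter_classes,
                               induced_pairs, mean_normalized_entropy)
from csrwalign.netio import Alignment, AnnotationMap, Network, NetworkSet


def ann_of(pairs):
    return AnnotationMap({key: lab for key, lab in pairs.items()})


TOY1_ALIGNMENT = Alignment([
    frozenset({("A", "u2"), ("B", "v2")}),
    frozenset({("A", "u1"), ("B", "v1"), ("A", "u3")}),
])


class TestAccuracy:
    def test_identical_alignments(self):
        assert alignment_accuracy(TOY1_ALIGNMENT, TOY1_ALIGNMENT) == 1.0

    def test_disjoint_pair_sets(self):
        a = Alignment([frozenset({("A", "u1"), ("B", "v1")})])
        b = Alignment([frozenset({("A", "u2"), ("B", "v2")})])
        assert alignment_accuracy(a, b) == 0.0

    def test_half_right(self):
        a = Alignment([frozenset({("A", "u1"), ("B", "v1")}),
                       frozenset({("A", "u2"), ("B", "v2")}),
                       frozenset({("A", "u3"), ("B", "v3")}),
                       frozenset({("A", "u4"), ("B", "v4")})])
        b = Alignment([frozenset({("A", "u1"), ("B", "v1")}),
                       frozenset({("A", "u2"), ("B", "v2")}),
                       frozenset({("A", "u3"), ("B", "v9")})])
        assert alignment_accuracy(a, b) == 0.5

    def test_empty_alignment(self):
        assert alignment_accuracy(Alignment([]), TOY1_ALIGNMENT) == 0.0

    def test_induced_pairs_are_cross_network_only(self):
        pairs = induced_pairs(TOY1_ALIGNMENT)
        # {u1,v1,u3}: u1-v1 and u3-v1 only (u1-u3 is same-network)
        assert len(pairs) == 3


class TestExpectedAccuracy:
    def test_single_class_on_toy1(self, toy1):
        net_a, net_b, sim = toy1
        chain, c = pair_correspondence(net_a, net_b, sim)
        cset = CorrespondenceSet({"A": net_a, "B": net_b})
        cset.set_pair("A", "B", chain.index, c, chain.lam)
        aln = Alignment([frozenset({("A", "u2"), ("B", "v2")})])
        assert expected_accuracy(aln, cset) == pytest.approx(0.5)

    def test_constant_scores_give_that_constant(self, toy1):
        net_a, net_b, sim = toy1
        chain, _ = pair_correspondence(net_a, net_b, sim)
        cset = CorrespondenceSet({"A": net_a, "B": net_b})
        cset.set_pair("A", "B", chain.index, np.full(3, 0.25), chain.lam)
        aln = Alignment([frozenset({("A", "u2"), ("B", "v2")}),
                         frozenset({("A", "u1"), ("B", "v1")})])
        assert expected_accuracy(aln, cset) == pytest.approx(0.25)

    def test_zero_score_pair_lowers_mean(self, toy1):
        net_a, net_b, sim = toy1
        chain, c = pair_correspondence(net_a, net_b, sim)
        cset = CorrespondenceSet({"A": net_a, "B": net_b})
        cset.set_pair("A", "B", chain.index, c, chain.lam)
        small = Alignment([frozenset({("A", "u2"), ("B", "v2")})])
        bigger = Alignment([frozenset({("A", "u2"), ("B", "v2"), ("A", "u3")})])
        assert expected_accuracy(bigger, cset) < expected_accuracy(small, cset)

    def test_no_pairs_is_error(self, toy1):
        net_a, net_b, sim = toy1
        chain, c = pair_correspondence(net_a, net_b, sim)
        cset = CorrespondenceSet({"A": net_a, "B": net_b})
        cset.set_pair("A", "B", chain.index, c, chain.lam)
        with pytest.raises(ValueError):
            expected_accuracy(Alignment([]), cset)


class TestFilterClasses:
    def test_single_network_class_removed(self):
        ann = ann_of({("A", "u1"): "F1", ("A", "u2"): "F1"})
        aln = Alignment([frozenset({("A", "u1"), ("A", "u2")})])
        assert filter_classes(aln, ann).classes == []

    def test_unannotated_shrink_then_removed(self):
        ann = ann_of({("A", "u1"): "F1"})
        aln = Alignment([frozenset({("A", "u1"), ("B", "v1")})])
        assert filter_classes(aln, ann).classes == []

    def test_fully_annotated_unchanged(self):
        ann = ann_of({("A", "u1"): "F1", ("B", "v1"): "F1", ("C", "w1"): "F2"})
        aln = Alignment([frozenset({("A", "u1"), ("B", "v1"), ("C", "w1")})])
        assert filter_classes(aln, ann) == aln

    def test_idempotent(self):
        ann = ann_of({("A", "u1"): "F1", ("B", "v1"): "F1", ("A", "u2"): "F2"})
        aln = Alignment([frozenset({("A", "u1"), ("B", "v1"), ("B", "zz")}),
                         frozenset({("A", "u2"), ("A", "u3")})])
        once = filter_classes(aln, ann)
        twice = filter_classes(once, ann)
        assert once == twice


class TestClassMetrics:
    def test_all_correct(self):
        ann = ann_of({("A", "u1"): "F1", ("B", "v1"): "F1",
                      ("A", "u2"): "F2", ("B", "v2"): "F2", ("C", "w2"): "F2"})
        aln = Alignment([frozenset({("A", "u1"), ("B", "v1")}),
                         frozenset({("A", "u2"), ("B", "v2"), ("C", "w2")})])
        cn, spe = class_metrics(aln, ann)
        assert cn == 5 and spe == 1.0

    def test_half_correct(self):
        ann = ann_of({("A", "u1"): "F1", ("B", "v1"): "F1",
                      ("A", "u2"): "F1", ("B", "v2"): "F2"})
        aln = Alignment([frozenset({("A", "u1"), ("B", "v1")}),
                         frozenset({("A", "u2"), ("B", "v2")})])
        cn, spe = class_metrics(aln, ann)
        assert cn == 2 and spe == 0.5

    def test_all_mixed(self):
        ann = ann_of({("A", "u1"): "F1", ("B", "v1"): "F2"})
        aln = Alignment([frozenset({("A", "u1"), ("B", "v1")})])
        cn, spe = class_metrics(aln, ann)
        assert cn == 0 and spe == 0.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            class_metrics(Alignment([]), AnnotationMap())


class TestMeanNormalizedEntropy:
    def test_max_entropy_class(self):
        ann = ann_of({("A", "u1"): "F1", ("B", "v1"): "F1",
                      ("A", "u2"): "F2", ("B", "v2"): "F2"})
        aln = Alignment([frozenset({("A", "u1"), ("B", "v1"),
                                    ("A", "u2"), ("B", "v2")})])
        assert mean_normalized_entropy(aln, ann) == pytest.approx(1.0)

    def test_pure_class_zero(self):
        ann = ann_of({("A", "u1"): "F1", ("B", "v1"): "F1"})
        aln = Alignment([frozenset({("A", "u1"), ("B", "v1")})])
        assert mean_normalized_entropy(aln, ann) == 0.0

    def test_three_to_one_split(self):
        ann = ann_of({("A", "u1"): "F1", ("B", "v1"): "F1",
                      ("A", "u2"): "F1", ("B", "v2"): "F2"})
        aln = Alignment([frozenset({("A", "u1"), ("B", "v1"),
                                    ("A", "u2"), ("B", "v2")})])
        expected = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25)) / math.log(2)
        assert mean_normalized_entropy(aln, ann) == pytest.approx(0.8113, abs=1e-4)
        assert mean_normalized_entropy(aln, ann) == pytest.approx(expected)

    def test_spe_one_iff_mne_zero(self, rng):
        # random annotated alignments: SPE == 1 exactly when MNE == 0
        for _ in range(20):
            n_classes = int(rng.integers(1, 5))
            classes, ann_pairs = [], {}
            for ci in range(n_classes):
                size = int(rng.integers(2, 5))
                members = {("A", f"u{ci}_{k}") if k % 2 else ("B", f"v{ci}_{k}")
                           for k in range(size)}
                for m in members:
                    ann_pairs[m] = f"F{rng.integers(1, 3)}"
                classes.append(frozenset(members))
            aln = filter_classes(Alignment(classes), ann_of(ann_pairs))
            if not aln.classes:
                continue
            ann = ann_of(ann_pairs)
            _, spe = class_metrics(aln, ann)
            mne = mean_normalized_entropy(aln, ann)
            assert (spe == 1.0) == (mne == 0.0)


class TestConservedInteractions:
    def test_single_network_support_not_conserved(self):
        net_a = Network("A", [("u1", "u2")])
        net_b = Network("B", nodes=["v1", "v2"])
        networks = NetworkSet([net_a, net_b])
        ann = ann_of({("A", "u1"): "F1", ("B", "v1"): "F1",
                      ("A", "u2"): "F2", ("B", "v2"): "F2"})
        aln = Alignment([frozenset({("A", "u1"), ("B", "v1")}),
                         frozenset({("A", "u2"), ("B", "v2")})])
        assert conserved_interactions(aln, networks, ann) == (0, 0)

    def test_toy1_ci_three(self, toy1, toy1_networks):
        ann = ann_of({("A", "u1"): "F1", ("B", "v1"): "F1", ("A", "u3"): "F1",
                      ("A", "u2"): "F2", ("B", "v2"): "F2"})
        ci, coi = conserved_interactions(TOY1_ALIGNMENT, toy1_networks, ann)
        assert ci == 3
        assert coi == 3  # both classes correct

    def test_coi_le_ci(self, toy1_networks):
        ann = ann_of({("A", "u1"): "F1", ("B", "v1"): "F9", ("A", "u3"): "F1",
                      ("A", "u2"): "F2", ("B", "v2"): "F2"})
        ci, coi = conserved_interactions(TOY1_ALIGNMENT, toy1_networks, ann)
        assert coi <= ci
        assert coi == 0  # mixed class breaks correctness

    def test_invariant_under_class_order(self, toy1_networks):
        ann = ann_of({("A", "u1"): "F1", ("B", "v1"): "F1", ("A", "u3"): "F1",
                      ("A", "u2"): "F2", ("B", "v2"): "F2"})
        reordered = Alignment(list(reversed(TOY1_ALIGNMENT.classes)))
        assert (conserved_interactions(TOY1_ALIGNMENT, toy1_networks, ann)
                == conserved_interactions(reordered, toy1_networks, ann))


class TestCoverage:
    def test_toy1_profile(self):
        class_cov, node_cov = coverage_profile(TOY1_ALIGNMENT)
        assert class_cov == {2: 2}
        assert node_cov == {2: 5}

    def test_all_span_all(self):
        aln = Alignment([frozenset({("A", "u1"), ("B", "v1"), ("C", "w1")})])
        class_cov, node_cov = coverage_profile(aln)
        assert class_cov == {3: 1} and node_cov == {3: 3}

    def test_node_coverage_partitions_members(self, rng):
        classes = [frozenset({("A", f"u{i}"), ("B", f"v{i}")}) for i in range(5)]
        classes.append(frozenset({("A", "x"), ("B", "y"), ("C", "z")}))
        aln = Alignment(classes)
        _, node_cov = coverage_profile(aln)
        assert sum(node_cov.values()) == len(aln.members())


class TestEvaluate:
    def test_full_report(self, toy1_networks):
        ann = ann_of({("A", "u1"): "F1", ("B", "v1"): "F1", ("A", "u3"): "F1",
                      ("A", "u2"): "F2", ("B", "v2"): "F2"})
        report = evaluate(TOY1_ALIGNMENT, toy1_networks, ann, TOY1_ALIGNMENT)
        assert report.cn == 5
        assert report.spe == 1.0
        assert report.mne == 0.0
        assert report.ci == 3
        assert report.accuracy == 1.0
        assert "SPE" in report.as_text()
        assert report.as_tsv().split("\t")[0] == "5"

    def test_nothing_survives_filtering(self, toy1_networks):
        with pytest.raises(ValueError):
            evaluate(TOY1_ALIGNMENT, toy1_networks, AnnotationMap())
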