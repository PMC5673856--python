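import itertools
import logging
import math

import numpy as np
import pytest

from treedelim.delimitation import (
    HaplogroupAssignment,
    av_mrca_tips,
    delimit_table,
    inter_and_closest,
    intra_distance,
    intra_inter_ratio,
    load_assignments,
    pid_estimate,
    records_from_frame,
    summarize_table,
    write_report,
)
from treedelim.treeio import parse_newick, patristic_matrix

from conftest import random_tree


def random_assignment(rng, tree, n_groups):
    labels = tree.tip_labels
    groups = [f"g{i}" for i in range(n_groups)]
    while True:
        mapping = {lab: groups[rng.integers(n_groups)] for lab in labels}
        if len(set(mapping.values())) == n_groups:
            return HaplogroupAssignment(mapping)


class TestLoadAssignments:
    def test_basic(self, tmp_path):
        path = tmp_path / "groups.tsv"
        path.write_text("a1\tA\na2\tA\nb1\tB\nb2\tB\n")
        asn = load_assignments(path)
        assert asn.haplogroups == ["A", "B"]
        assert asn.members("A") == ["a1", "a2"]

    def test_header_skipped(self, tmp_path):
        path = tmp_path / "groups.tsv"
        path.write_text("tip\thaplogroup\na1\tA\nb1\tB\n")
        assert len(load_assignments(path)) == 2

    def test_duplicate_same_group_deduplicated(self, tmp_path):
        path = tmp_path / "groups.tsv"
        path.write_text("a1\tA\na1\tA\nb1\tB\n")
        assert len(load_assignments(path)) == 2

    def test_conflicting_duplicate_is_error(self, tmp_path):
        path = tmp_path / "groups.tsv"
        path.write_text("a1\tA\na1\tB\n")
        with pytest.raises(ValueError, match="a1"):
            load_assignments(path)

    def test_unassigned_tree_tips_flagged(self):
        tree = parse_newick("((a1:1,a2:1):1,(b1:1,x:1):1);")
        asn = HaplogroupAssignment({"a1": "A", "a2": "A", "b1": "B"})
        assert asn.unassigned_tips(tree) == ["x"]


class TestIntraDistance:
    def test_singleton_is_na(self):
        tree = parse_newick("((a1:1,a2:1):1,b1:2);")
        asn = HaplogroupAssignment({"a1": "A", "a2": "A", "b1": "B"})
        assert intra_distance(tree, asn, "B") is None

    def test_two_member_group(self):
        tree = parse_newick("((a1:0.002,a2:0.002):1,b1:2);")
        asn = HaplogroupAssignment({"a1": "A", "a2": "A", "b1": "B"})
        assert intra_distance(tree, asn, "A") == pytest.approx(0.004)

    def test_unknown_group(self):
        tree = parse_newick("((a1:1,a2:1):1,b1:2);")
        asn = HaplogroupAssignment({"a1": "A", "a2": "A", "b1": "B"})
        with pytest.raises(KeyError):
            intra_distance(tree, asn, "Z")

    def test_matches_pair_enumeration_oracle(self, rng):
        tree = random_tree(rng, 12)
        members = tree.tip_labels[:5]
        mapping = {lab: ("F" if lab in members else "O")
                   for lab in tree.tip_labels}
        asn = HaplogroupAssignment(mapping)
        d = patristic_matrix(tree)
        expected = np.mean(
            [d.loc[a, b] for a, b in itertools.combinations(members, 2)]
        )
        assert len(list(itertools.combinations(members, 2))) == 10
        assert intra_distance(tree, asn, "F") == pytest.approx(expected)


class TestInterAndClosest:
    def test_four_tip_cross_mean(self):
        tree = parse_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        asn = HaplogroupAssignment(
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )
        closest, inter = inter_and_closest(tree, asn, "A")
        assert closest == "B"
        assert inter == pytest.approx(4.0)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(10):
            tree = random_tree(rng, 12)
            asn = random_assignment(rng, tree, 3)
            d = patristic_matrix(tree)
            for focal in asn.haplogroups:
                expected = min(
                    (
                        float(np.mean([
                            d.loc[a, b]
                            for a in asn.members(focal)
                            for b in asn.members(other)
                        ])),
                        other,
                    )
                    for other in asn.haplogroups
                    if other != focal
                )
                closest, inter = inter_and_closest(tree, asn, focal)
                assert inter == pytest.approx(expected[0])
                assert closest == expected[1]

    def test_tie_broken_lexicographically_with_warning(self, caplog):
        # B and C are mirror images: identical mean distance to A
        tree = parse_newick(
            "((a1:1,a2:1):1,((b1:1,b2:1):1,(c1:1,c2:1):1):1);"
        )
        asn = HaplogroupAssignment(
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B",
             "c1": "C", "c2": "C"}
        )
        with caplog.at_level(logging.WARNING):
            closest, _ = inter_and_closest(tree, asn, "A")
        assert closest == "B"
        assert any("tie" in rec.message for rec in caplog.records)


class TestIntraInterRatio:
    def test_printed_row(self):
        assert round(intra_inter_ratio(0.003, 0.156), 2) == 0.02

    def test_na_propagates(self):
        assert intra_inter_ratio(None, 0.069) is None

    def test_identity(self):
        assert intra_inter_ratio(0.37, 0.37) == pytest.approx(1.0)

    def test_nonpositive_inter_rejected(self):
        with pytest.raises(ValueError):
            intra_inter_ratio(0.1, 0.0)


class TestAvMrcaTips:
    def test_cherry(self):
        tree = parse_newick("((a1:0.7,a2:0.7):1,b1:2);")
        asn = HaplogroupAssignment({"a1": "A", "a2": "A", "b1": "B"})
        assert av_mrca_tips(tree, asn, "A") == pytest.approx(0.7)

    def test_singleton_is_na(self):
        tree = parse_newick("((a1:1,a2:1):1,b1:2);")
        asn = HaplogroupAssignment({"a1": "A", "a2": "A", "b1": "B"})
        assert av_mrca_tips(tree, asn, "B") is None

    def test_matches_path_oracle(self, rng):
        tree = random_tree(rng, 16)
        members = sorted(rng.choice(tree.tip_labels, 8, replace=False))
        mapping = {lab: ("F" if lab in members else "O")
                   for lab in tree.tip_labels}
        asn = HaplogroupAssignment(mapping)
        from treedelim.treeio import mrca

        anc = mrca(tree, members)
        expected = np.mean(
            [tree.tip(m).depth() - anc.depth() for m in members]
        )
        assert av_mrca_tips(tree, asn, "F") == pytest.approx(expected)


@pytest.fixture
def separated():
    """Tight focal clade, distant neighbor."""
    tree = parse_newick(
        "((a1:0.01,a2:0.01):5.0,(b1:0.01,b2:0.01):5.0);"
    )
    asn = HaplogroupAssignment(
        {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    )
    return tree, asn


class TestPidEstimate:
    def test_ci_sanity(self, separated):
        tree, asn = separated
        for mode in ("strict", "liberal"):
            est = pid_estimate(tree, asn, "A", mode, n_reps=500, seed=3)
            assert 0 <= est.low <= est.mean <= est.high <= 1

    def test_separation_limit_liberal_near_one(self, separated):
        tree, asn = separated
        est = pid_estimate(tree, asn, "A", "liberal", n_reps=2000, seed=1)
        assert est.mean > 0.99

    def test_singleton_strict_is_na_liberal_defined(self):
        tree = parse_newick("((a1:1,a2:1):1,b1:2);")
        asn = HaplogroupAssignment({"a1": "A", "a2": "A", "b1": "B"})
        assert pid_estimate(tree, asn, "B", "strict", 100, 0) is None
        est = pid_estimate(tree, asn, "B", "liberal", 500, 0)
        assert est is not None and 0 <= est.mean <= 1

    def test_seed_reproducible(self, separated):
        tree, asn = separated
        a = pid_estimate(tree, asn, "A", "strict", 500, seed=7)
        b = pid_estimate(tree, asn, "A", "strict", 500, seed=7)
        assert a == b

    def test_doubling_reps_stable(self, separated):
        tree, asn = separated
        a = pid_estimate(tree, asn, "A", "strict", 2000, seed=11)
        b = pid_estimate(tree, asn, "A", "strict", 4000, seed=12)
        se = math.sqrt(max(a.mean * (1 - a.mean), 1e-4) / 2000)
        assert abs(a.mean - b.mean) < 3 * se + 1e-9

    def test_invalid_args(self, separated):
        tree, asn = separated
        with pytest.raises(ValueError):
            pid_estimate(tree, asn, "A", "strict", 0, 0)
        with pytest.raises(ValueError):
            pid_estimate(tree, asn, "A", "both", 100, 0)

    def test_monotone_in_intra_inter_ratio(self):
        """Liberal P ID does not increase along a ratio ladder."""
        means = []
        ratios = []
        for a in (0.1, 0.3, 1.0, 3.0):
            tree = parse_newick(f"((a1:{a},a2:{a}):1.0,b1:{a + 1});")
            asn = HaplogroupAssignment({"a1": "A", "a2": "A", "b1": "B"})
            intra = intra_distance(tree, asn, "A")
            _, inter = inter_and_closest(tree, asn, "A")
            ratios.append(intra / inter)
            est = pid_estimate(tree, asn, "A", "liberal", 4000, seed=5)
            means.append(est.mean)
        assert all(x < y for x, y in zip(ratios, ratios[1:]))
        assert all(x >= y for x, y in zip(means, means[1:]))


class TestDelimitTable:
    tree = parse_newick(
        "(((a1:0.1,a2:0.1)90:1,(b1:0.1,b2:0.1)80:1)70:1,c1:3);"
    )
    asn = HaplogroupAssignment(
        {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}
    )

    def test_record_shape_and_na_rules(self):
        records = delimit_table(self.tree, self.asn, n_reps=200, seed=0)
        assert [r.focal for r in records] == ["A", "B", "C"]
        by = {r.focal: r for r in records}
        assert by["A"].support == 90
        assert by["A"].intra == pytest.approx(0.2)
        assert by["C"].intra is None
        assert by["C"].ratio is None
        assert by["C"].support is None
        assert by["C"].pid_strict is None
        assert by["C"].pid_liberal is not None
        assert by["C"].av_mrca_tips is None
        for r in records:
            assert r.inter > 0

    def test_permutation_invariance(self):
        rotated = parse_newick(
            "(c1:3,((b2:0.1,b1:0.1)80:1,(a2:0.1,a1:0.1)90:1)70:1);"
        )
        a = delimit_table(self.tree, self.asn, n_reps=300, seed=4)
        b = delimit_table(rotated, self.asn, n_reps=300, seed=4)
        for ra, rb in zip(a, b):
            assert ra == rb

    def test_intra_bounded_by_max_pair(self, rng):
        tree = random_tree(rng, 14)
        asn = random_assignment(rng, tree, 3)
        d = patristic_matrix(tree)
        for r in delimit_table(tree, asn, n_reps=50, seed=0):
            members = asn.members(r.focal)
            if r.intra is not None:
                pairs = [d.loc[a, b] for a, b in
                         itertools.combinations(members, 2)]
                assert r.intra <= max(pairs) + 1e-12
            closest = asn.members(r.closest)
            cross = [d.loc[a, b] for a in members for b in closest]
            assert r.inter >= min(cross) - 1e-12


class TestSummarize:
    def test_single_record_identity(self):
        tree = parse_newick("((a1:0.1,a2:0.1):1,(b1:0.1,b2:0.1):1);")
        asn = HaplogroupAssignment(
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )
        records = delimit_table(tree, asn, n_reps=100, seed=0)[:1]
        s = summarize_table(records)
        assert s.mean_intra == pytest.approx(records[0].intra)
        assert s.mean_inter == pytest.approx(records[0].inter)

    def test_na_excluded_not_imputed(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "focal": ["X", "Y"],
                "closest": ["Y", "X"],
                "support": [90, None],
                "intra": [0.2, None],
                "inter": [1.0, 2.0],
                "ratio": [0.2, None],
                "pid_strict_mean": [0.8, None],
                "pid_strict_low": [0.7, None],
                "pid_strict_high": [0.9, None],
                "pid_liberal_mean": [0.9, 0.7],
                "pid_liberal_low": [0.8, 0.6],
                "pid_liberal_high": [1.0, 0.8],
                "av_mrca_tips": [0.1, None],
            }
        )
        s = summarize_table(records_from_frame(frame))
        assert s.mean_intra == pytest.approx(0.2)
        assert s.mean_inter == pytest.approx(1.5)
        assert s.mean_pid_strict == pytest.approx(0.8)
        assert s.mean_pid_liberal == pytest.approx(0.8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_table([])


class TestReportWriter:
    def test_na_literal_and_columns(self, tmp_path):
        tree = parse_newick("((a1:0.1,a2:0.1):1,b1:2);")
        asn = HaplogroupAssignment({"a1": "A", "a2": "A", "b1": "B"})
        records = delimit_table(tree, asn, n_reps=100, seed=0)
        out = tmp_path / "report.tsv"
        write_report(records, out)
        lines = out.read_text().splitlines()
        header = lines[0].split("\t")
        assert header[:6] == ["focal", "closest", "support", "intra",
                              "inter", "ratio"]
        b_row = dict(zip(header, lines[2].split("\t")))
        assert b_row["intra"] == "NA"
        assert b_row["pid_strict_mean"] == "NA"
        assert b_row["pid_liberal_mean"] != "NA"
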