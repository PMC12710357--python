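"""Tree handling, congruence detection, and origin counting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cimsym.errors import InputConsistencyError, InvalidParameterError
from cimsym.origin_mapping import (
    AssociationTable,
    CoevolvingClade,
    count_origins,
    find_coevolving_clades,
    induced_subtree,
    leaf_labels,
    read_newick,
    rf_distance,
    write_newick,
)
from conftest import random_topology


def assoc_of(rows):
    return AssociationTable(
        pd.DataFrame(rows, columns=["strain_id", "host_id", "genus"])
    )


class TestNewick:
    def test_basic_parse(self):
        t = read_newick("(A,(B,C));")
        assert sorted(leaf_labels(t)) == ["A", "B", "C"]

    def test_round_trip_preserves_topology(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            nwk = random_topology(rng, [f"L{i}" for i in range(8)])
            t = read_newick(nwk)
            again = read_newick(write_newick(t))
            assert rf_distance(t, again) == 0

    def test_malformed_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            read_newick("(A,(B,C);")

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(InvalidParameterError):
            read_newick("(A,(A,B));")


class TestInducedSubtree:
    def test_cherry_restriction(self):
        t = read_newick("((A,B),(C,D));")
        sub = induced_subtree(t, ["A", "B"])
        assert write_newick(sub).replace(" ", "") == "(A,B);"

    def test_degree_two_suppression(self):
        t = read_newick("((A,B),(C,D));")
        sub = induced_subtree(t, ["A", "C", "D"])
        assert rf_distance(sub, read_newick("(A,(C,D));")) == 0

    def test_full_leafset_identity(self):
        t = read_newick("((A,B),((C,D),E));")
        sub = induced_subtree(t, ["A", "B", "C", "D", "E"])
        assert rf_distance(sub, t) == 0

    def test_unknown_leaf_named_in_error(self):
        t = read_newick("(A,(B,C));")
        with pytest.raises(InvalidParameterError, match="Z"):
            induced_subtree(t, ["A", "Z"])


def brute_force_rf(t1, t2) -> int:
    """Independent RF oracle: symmetric difference of the canonical
    non-trivial bipartition sets, computed by plain traversal."""
    def bipartitions(tree):
        labels = frozenset(leaf_labels(tree))
        splits = set()
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            other = labels - side
            if len(side) >= 2 and len(other) >= 2:
                splits.add(min(side, other, key=lambda s: sorted(s)))
        return splits
    return len(bipartitions(t1) ^ bipartitions(t2))


class TestRfDistance:
    def test_identical_trees_zero(self):
        t = read_newick("((A,B),(C,D));")
        assert rf_distance(t, read_newick("((B,A),(D,C));")) == 0

    def test_distinct_quartets_distance_two(self):
        quartets = ["((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));"]
        for n1, n2 in itertools.combinations(quartets, 2):
            assert rf_distance(read_newick(n1), read_newick(n2)) == 2

    def test_leafset_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            rf_distance(read_newick("(A,(B,C));"), read_newick("(A,(B,D));"))

    def test_matches_bipartition_oracle_on_random_pairs(self):
        """RF vs a from-scratch bipartition symmetric-difference oracle
        on 500 random 8-leaf tree pairs."""
        rng = np.random.default_rng(77)
        labels = [f"L{i}" for i in range(8)]
        for _ in range(500):
            t1 = read_newick(random_topology(rng, labels))
            t2 = read_newick(random_topology(rng, labels))
            assert rf_distance(t1, t2) == brute_force_rf(t1, t2)


HOST = "((h1,h2),((h3,h4),(h5,(h6,h7))));"


class TestCoevolvingClades:
    def make(self, genus_nwk, rows):
        return find_coevolving_clades(
            read_newick(genus_nwk), read_newick(HOST), assoc_of(rows)
        )

    def test_sister_pair_on_sister_hosts_qualifies(self):
        clades = self.make(
            "((s1,s2),s3);",
            [("s1", "h3", "G"), ("s2", "h4", "G"), ("s3", "h6", "G")],
        )
        assert len(clades) == 1
        assert clades[0].strain_ids == ("s1", "s2")
        assert clades[0].trivial

    def test_large_congruent_clade_detected_whole(self):
        # symbiont subtree mirrors the host clade ((h3,h4),(h5,(h6,h7)))
        clades = self.make(
            "(out,((s3,s4),(s5,(s6,s7))));",
            [("out", "h1", "G")] + [(f"s{i}", f"h{i}", "G") for i in range(3, 8)],
        )
        assert len(clades) == 1
        assert clades[0].strain_ids == ("s3", "s4", "s5", "s6", "s7")
        assert not clades[0].trivial

    def test_host_swap_decomposes_clade(self):
        # swapping two strains' hosts on the 5-leaf subtree breaks RF
        # congruence at the top; the clade decomposes into smaller
        # qualifying clades
        clades = self.make(
            "(out,((s3,s4),(s5,(s6,s7))));",
            [("out", "h1", "G"), ("s3", "h3", "G"), ("s4", "h4", "G"),
             ("s5", "h6", "G"), ("s6", "h5", "G"), ("s7", "h7", "G")],
        )
        assert sorted(c.strain_ids for c in clades) == [
            ("s3", "s4"), ("s5", "s6", "s7")
        ]

    def test_duplicate_hosts_block_clade(self):
        # two strains of one genus in one host cannot be one origin
        clades = self.make(
            "((s1,s2),s3);",
            [("s1", "h3", "G"), ("s2", "h3", "G"), ("s3", "h6", "G")],
        )
        assert clades == []

    def test_non_monophyletic_hosts_block_clade(self):
        # hosts h1 and h3 are not sisters in the host tree: a cherry of
        # their strains is not a codiversification signal
        clades = self.make(
            "((s1,s2),s3);",
            [("s1", "h1", "G"), ("s2", "h3", "G"), ("s3", "h6", "G")],
        )
        assert clades == []

    def test_unmapped_strain_named_in_error(self):
        with pytest.raises(InputConsistencyError, match="s9"):
            self.make("((s1,s9),s3);",
                      [("s1", "h1", "G"), ("s3", "h6", "G")])

    def test_permuting_hosts_usually_breaks_congruence(self):
        """Shuffling host assignments of a 5-strain congruent clade
        breaks congruence in the majority of permutations."""
        rng = np.random.default_rng(4)
        hosts = ["h3", "h4", "h5", "h6", "h7"]
        broken = 0
        n = 200
        for _ in range(n):
            perm = list(rng.permutation(hosts))
            rows = [("out", "h1", "G")] + [
                (f"s{i}", perm[i - 3], "G") for i in range(3, 8)
            ]
            clades = self.make("(out,((s3,s4),(s5,(s6,s7))));", rows)
            if not (len(clades) == 1 and clades[0].size == 5):
                broken += 1
        assert broken / n >= 0.5


class TestCountOrigins:
    rows = [("s1", "h3", "G"), ("s2", "h4", "G"), ("s3", "h6", "G"),
            ("t1", "h1", "T")]

    def test_no_clades_every_strain_an_origin(self):
        report = count_origins(assoc_of(self.rows), [])
        assert report.per_genus == {"G": 3, "T": 1}
        assert report.total == 4

    def test_clade_collapse_reduces_by_size_minus_one(self):
        clade = CoevolvingClade("G", ("s1", "s2"), ("h3", "h4"), trivial=True)
        report = count_origins(assoc_of(self.rows), [clade])
        assert report.per_genus == {"G": 2, "T": 1}
        assert report.total == 3

    def test_overlapping_clades_rejected(self):
        c1 = CoevolvingClade("G", ("s1", "s2"), ("h3", "h4"))
        c2 = CoevolvingClade("G", ("s2", "s3"), ("h4", "h6"))
        with pytest.raises(InputConsistencyError):
            count_origins(assoc_of(self.rows), [c1, c2])

    def test_bounds_genera_leq_total_leq_strains(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(2, 8))
            rows = [(f"s{i}", f"h{i}", ["A", "B"][int(rng.integers(2))])
                    for i in range(n)]
            assoc = assoc_of(rows)
            report = count_origins(assoc, [])
            assert len(assoc.genera) <= report.total <= n


class TestSurveyFixture:
    def test_association_accounting(self, survey_fixture):
        from cimsym.origin_mapping import association_summary
        _, _, assoc = survey_fixture
        summary = association_summary(assoc)
        assert summary["Wolbachia"]["n_strains"] == 14
        assert summary["Wolbachia"]["n_hosts"] == 11
        assert summary["Wolbachia"]["double_infection_hosts"] == ["C12", "C21", "C51"]

    def test_origin_breakdown(self, survey_fixture):
        host, genus_trees, assoc = survey_fixture
        clades = []
        for tree in genus_trees.values():
            clades.extend(find_coevolving_clades(tree, host, assoc))
        report = count_origins(assoc, clades)
        assert report.total == 16
        assert report.per_genus == {
            "Wolbachia": 8, "Symbiopectobacterium": 4, "Sodalis": 2,
            "Serratia": 1, "Tisiphia": 1,
        }
        sizes = sorted(c.size for c in report.clades)
        assert sizes == [2, 2, 7]
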