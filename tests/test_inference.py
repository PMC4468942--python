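"""Copy-number parsimony: the Sankoff DP against exhaustive enumeration,
the ambiguity rule, event classification, and tree building."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gvaccordion import inference as inf
from gvaccordion import simulate as sim
from gvaccordion.model import ConsistencyError, PhyloTree
from gvaccordion.stats import random_clock_tree
from conftest import make_genome


# ---------------------------------------------------------------- DP oracle
def enumerate_scenarios(profile, tree, max_copy):
    """Exhaustive minimum search over all ancestral copy assignments."""
    internals = [n.label for n in tree.postorder() if not n.is_leaf()]
    tips = {n.label: profile[n.label] for n in tree.postorder() if n.is_leaf()}
    edges = [
        (n.parent_node.label, n.label) for n in tree.preorder() if n.parent_node
    ]
    parent_of = {
        n.label: n.parent_node.label for n in tree.postorder() if n.is_leaf()
    }
    best, count = None, 0
    deltas = {t: set() for t in tips}
    for assign in itertools.product(range(max_copy + 1), repeat=len(internals)):
        st = dict(zip(internals, assign))
        st.update(tips)
        cost = sum(abs(st[c] - st[p]) for p, c in edges)
        if best is None or cost < best:
            best, count = cost, 1
            deltas = {t: {tips[t] - st[parent_of[t]]} for t in tips}
        elif cost == best:
            count += 1
            for t in tips:
                deltas[t].add(tips[t] - st[parent_of[t]])
    return best, count, {t: tuple(sorted(v)) for t, v in deltas.items()}


class TestMinCostScenarios:
    def test_constant_profile_needs_no_events(self, balanced4):
        sc = inf.min_cost_scenarios(dict.fromkeys("ABCD", 1), balanced4)
        assert sc.min_cost == 0
        assert sc.optimal_labelings == 1
        assert all(d == (0,) for d in sc.terminal_deltas.values())

    def test_single_tip_gain_is_unique_terminal_event(self, balanced4):
        sc = inf.min_cost_scenarios({"A": 1, "B": 0, "C": 0, "D": 0}, balanced4)
        assert sc.min_cost == 1
        assert sc.terminal_deltas["A"] == (1,)
        assert all(sc.terminal_deltas[t] == (0,) for t in "BCD")

    def test_two_tip_profile_is_ambiguous_both_ways(self):
        tree = PhyloTree.from_newick("(A:1,B:1);")
        sc = inf.min_cost_scenarios({"A": 1, "B": 0}, tree)
        assert sc.min_cost == 1
        assert sc.optimal_labelings == 2
        assert sc.terminal_deltas == {"A": (0, 1), "B": (-1, 0)}

    @pytest.mark.parametrize(
        "newick",
        [
            "((A:1,B:1):1,(C:1,D:1):1);",
            "(((A:1,B:1):1,C:1):1,D:1);",
            "((((A:1,B:1):1,C:1):1,D:1):1,E:1);",
        ],
    )
    def test_dp_equals_exhaustive_enumeration(self, newick):
        tree = PhyloTree.from_newick(newick)
        tips = sorted(tree.tip_labels)
        for values in itertools.product(range(3), repeat=len(tips)):
            profile = dict(zip(tips, values))
            sc = inf.min_cost_scenarios(profile, tree, max_copy=2)
            assert (
                sc.min_cost, sc.optimal_labelings, sc.terminal_deltas
            ) == enumerate_scenarios(profile, tree, 2), profile

    def test_missing_tip_rejected(self, balanced4):
        with pytest.raises(ConsistencyError):
            inf.min_cost_scenarios({"A": 1, "B": 0, "C": 0}, balanced4)

    def test_copy_number_above_cap_rejected(self, balanced4):
        profile = {"A": 25, "B": 0, "C": 0, "D": 0}
        with pytest.raises(ConsistencyError):
            inf.min_cost_scenarios(profile, balanced4, max_copy=20)

    def test_canonical_labeling_telescopes_to_tip_minus_root(self, balanced4):
        # gains minus losses along any root-to-tip path equals the tip
        # count minus the root count, under one co-optimal labeling
        rng = np.random.default_rng(3)
        for _ in range(50):
            profile = {t: int(rng.integers(0, 4)) for t in "ABCD"}
            sc = inf.min_cost_scenarios(profile, balanced4, max_copy=5)
            lab = dict(sc.canonical_labeling)
            lab.update(profile)
            for tip in "ABCD":
                node = balanced4.node(tip)
                path = 0
                while node.parent_node is not None:
                    path += lab[node.label] - lab[node.parent_node.label]
                    node = node.parent_node
                assert path == profile[tip] - lab[balanced4.root.label]


class TestBuildCopyMatrix:
    def test_counts_by_family(self):
        a = make_genome("a", [("X", 2), ("Y", 1)])
        b = make_genome("b", [("Y", 3)])
        m = inf.build_copy_matrix([a, b])
        assert m.counts.loc["X", "a"] == 2
        assert m.counts.loc["X", "b"] == 0
        assert m.counts.loc["Y", "b"] == 3

    def test_column_sums_equal_gene_counts_on_simulated_data(self):
        cfg = sim.preset("chlorella_like", seed=8)
        res = sim.simulate(cfg, random_clock_tree(4, seed=8))
        m = inf.build_copy_matrix(res.genomes.values())
        for tip, genome in res.genomes.items():
            assert m.counts[tip].sum() == len(genome.genes)

    def test_empty_genome_set_rejected(self):
        with pytest.raises(ConsistencyError):
            inf.build_copy_matrix([])

    def test_minority_flags_dropped_with_warning(self):
        a = make_genome("a", [("X", 3)])
        b = make_genome("b", [("X", 1, {"MGE"})])
        with pytest.warns(UserWarning, match="majority"):
            m = inf.build_copy_matrix([a, b])
        assert "MGE" not in m.meta["X"]


class TestClassification:
    def _infer(self, genomes, tree):
        matrix = inf.build_copy_matrix(genomes)
        scen = {
            f: inf.min_cost_scenarios(matrix.profile(f), tree, family_id=f)
            for f in matrix.families
        }
        return inf.classify_terminal_events(scen, matrix, tree), matrix

    def test_rule_table(self, balanced4):
        base = [("C1", 1), ("C2", 1), ("C3", 1)]
        genomes = [
            make_genome("A", base + [
                ("MGE1", 1, {"MGE"}),                      # gained MGE -> insertion
                ("L1", 1, {"donor_labelled"}, "Bacteria:X"),  # gained donor -> lgt
                ("O1", 1, {"orphan_candidate"}),           # gained orphan
                ("D1", 2),                                 # extra copy -> duplication
            ]),
            make_genome("B", base + [("D1", 1)]),
            make_genome("C", base + [("D1", 1), ("GONE", 1)]),
            make_genome("D", base + [("D1", 1), ("GONE", 1),
                                     ("MGE2", 1, {"MGE"})]),
        ]
        events, _ = self._infer(genomes, balanced4)
        by = {(e.branch, e.family_id): e.event_type for e in events}
        assert by[("A", "MGE1")] == "insertion"
        assert by[("A", "L1")] == "lgt"
        assert by[("A", "O1")] == "orphan"
        assert by[("A", "D1")] == "duplication"
        dup = next(e for e in events if e.family_id == "D1")
        assert not dup.in_paralog_family
        # GONE present in C and D (sister pair) but absent from A, B: a
        # single internal-branch loss explains it; no terminal event
        assert ("B", "GONE") not in by and ("A", "GONE") not in by
        # MGE2 lost nowhere, present only in D -> insertion on D
        assert by[("D", "MGE2")] == "insertion"

    def test_loss_vs_excision(self, balanced4):
        genomes = [
            make_genome("A", [("C1", 1), ("C2", 1)]),
            make_genome("B", [("C1", 1), ("C2", 1), ("M1", 1, {"MGE"}), ("S1", 1)]),
            make_genome("C", [("C1", 1), ("C2", 1), ("M1", 1, {"MGE"}), ("S1", 1)]),
            make_genome("D", [("C1", 1), ("C2", 1), ("M1", 1, {"MGE"}), ("S1", 1)]),
        ]
        events, _ = self._infer(genomes, balanced4)
        by = {(e.branch, e.family_id): e.event_type for e in events}
        assert by[("A", "M1")] == "excision"
        assert by[("A", "S1")] == "loss"

    def test_paralog_family_flag_requires_three_other_members(self, balanced4):
        genomes = [
            make_genome("A", [("C1", 1), ("BIG", 5)]),
            make_genome("B", [("C1", 1), ("BIG", 4)]),
            make_genome("C", [("C1", 1), ("BIG", 4)]),
            make_genome("D", [("C1", 1), ("BIG", 4)]),
        ]
        events, _ = self._infer(genomes, balanced4)
        dup = next(e for e in events if e.event_type == "duplication")
        assert dup.in_paralog_family

    def test_multi_copy_change_emits_one_record_per_unit(self, balanced4):
        genomes = [
            make_genome("A", [("C1", 1), ("X", 3)]),
            make_genome("B", [("C1", 1), ("X", 1)]),
            make_genome("C", [("C1", 1), ("X", 1)]),
            make_genome("D", [("C1", 1), ("X", 1)]),
        ]
        events, _ = self._infer(genomes, balanced4)
        dups = [e for e in events if e.event_type == "duplication"]
        assert len(dups) == 2 and all(e.branch == "A" for e in dups)

    def test_summary_from_hand_built_events(self, balanced4):
        genomes = [
            make_genome("A", [("C1", 1), ("D1", 2)]),
            make_genome("B", [("C1", 1), ("D1", 1), ("S1", 1)]),
            make_genome("C", [("C1", 1), ("D1", 1), ("S1", 1)]),
            make_genome("D", [("C1", 1), ("D1", 1), ("S1", 1)]),
        ]
        events, _ = self._infer(genomes, balanced4)
        rows = inf.summarize_terminal_events(events, genomes)
        row_a = next(r for r in rows if r.genome_id == "A")
        assert (row_a.total_gain, row_a.total_loss, row_a.genomic_events) == (1, 1, 2)
        assert row_a.violations() == []

    def test_no_events_gives_zero_rows(self, balanced4):
        genomes = [make_genome(t, [("C1", 1)]) for t in "ABCD"]
        events, _ = self._infer(genomes, balanced4)
        rows = inf.summarize_terminal_events(events, genomes)
        assert all(r.genomic_events == 0 for r in rows)


class TestGeneContentDistance:
    def test_identical_genomes_zero_distance(self):
        genomes = [make_genome(t, [("A", 1), ("B", 1)]) for t in "xyz"]
        m = inf.build_copy_matrix(genomes)
        d = inf.gene_content_distance(m)
        assert np.allclose(d.values, 0.0)

    def test_disjoint_families_and_saturated_markers(self):
        from gvaccordion.markers import MarkerAlignment

        a = make_genome("a", [("A1", 1), ("A2", 1)])
        b = make_genome("b", [("B1", 1), ("B2", 1)])
        m = inf.build_copy_matrix([a, b])
        al = MarkerAlignment(rows={"a": "ACGTACGT", "b": "CATGCATG"})
        d = inf.gene_content_distance(m, al, alpha=0.5)
        # Jaccard distance 1, marker p-distance 1 -> combined 1
        assert d.loc["a", "b"] == pytest.approx(0.5 * 1.0 + 0.5 * 1.0)

    def test_metric_properties_on_random_matrices(self, rng):
        for _ in range(100):
            counts = pd.DataFrame(
                rng.integers(0, 3, size=(8, 4)),
                index=[f"F{i}" for i in range(8)],
                columns=list("wxyz"),
            )
            m = inf.CopyNumberMatrix(counts=counts, meta={})
            d = inf.gene_content_distance(m).values
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0.0)
            for i, j, k in itertools.permutations(range(4), 3):
                assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestBuildRootedTree:
    def test_recovers_additive_tree(self):
        ids = list("ABCD")
        dist = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=ids, columns=ids, dtype=float,
        )
        tree = inf.build_rooted_tree(dist, outgroup="D")
        # path lengths on the NJ tree reproduce the additive input
        for a in ids:
            for b in ids:
                if a == b:
                    continue
                assert _path_len(tree, a, b) == pytest.approx(dist.loc[a, b])

    def test_outgroup_is_child_of_root(self):
        ids = list("ABCD")
        dist = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=ids, columns=ids, dtype=float,
        )
        tree = inf.build_rooted_tree(dist, outgroup="B")
        assert "B" in [c.label for c in tree.root.child_nodes()]
        assert tree.is_binary_rooted()

    def test_two_taxa_rejected(self):
        dist = pd.DataFrame([[0, 1], [1, 0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ConsistencyError):
            inf.build_rooted_tree(dist, "A")

    def test_missing_outgroup_rejected(self):
        ids = list("ABC")
        dist = pd.DataFrame(np.ones((3, 3)) - np.eye(3), index=ids, columns=ids)
        with pytest.raises(ConsistencyError):
            inf.build_rooted_tree(dist, "Z")


def _path_len(tree, a, b):
    na = tree.node(a)
    ancestors = []
    n = na
    while n is not None:
        ancestors.append(n.label)
        n = n.parent_node
    n, d = tree.node(b), 0.0
    while n.label not in ancestors:
        d += PhyloTree.branch_length(n)
        n = n.parent_node
    mrca = n.label
    n = na
    while n.label != mrca:
        d += PhyloTree.branch_length(n)
        n = n.parent_node
    return d
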