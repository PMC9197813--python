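"""Quartet scoring, species-tree search and branch-frequency tallies,
each checked against independent brute-force enumeration."""

import itertools

import numpy as np
import pytest

from phylodisco.discordance import (
    GeneTreeSet,
    branch_frequencies,
    classify_discordance,
    infer_species_tree,
    quartet_score,
    quartet_topology,
)
from phylodisco.simulate import sim_gene_trees, sim_species_tree
from phylodisco.treeops import (
    collapse_low_support,
    read_newick,
    rf_distance,
    write_newick,
)


def _oracle_quartet(tree, quad):
    """Brute-force induced quartet via leaf-set containment checks."""
    a, b, c, d = sorted(quad)
    clades = []
    for node in tree.postorder_internal_node_iter(exclude_seed_node=True):
        clades.append({lf.taxon.label for lf in node.leaf_iter()})
    full = {lf.taxon.label for lf in tree.leaf_node_iter()}
    for clade in clades + [full - cl for cl in clades]:
        inter = clade & {a, b, c, d}
        if len(inter) == 2:
            pair = tuple(sorted(inter))
            other = tuple(sorted({a, b, c, d} - inter))
            return "|".join(sorted([",".join(pair), ",".join(other)]))
    return "unresolved"


def _oracle_score(candidate, gene_trees):
    """Nested-loop quartet agreement count, no bitmask machinery."""
    cand_leaves = {lf.taxon.label for lf in candidate.leaf_node_iter()}
    score = 0
    for gt in gene_trees:
        gt_leaves = {lf.taxon.label for lf in gt.leaf_node_iter()}
        shared = sorted(cand_leaves & gt_leaves)
        for quad in itertools.combinations(shared, 4):
            tc = _oracle_quartet(candidate, quad)
            tg = _oracle_quartet(gt, quad)
            if tc != "unresolved" and tc == tg:
                score += 1
    return score


class TestQuartetTopology:
    def test_balanced_four(self):
        t = read_newick("((A,B),(C,D));")
        assert quartet_topology(t, "ABCD") == "A,B|C,D"

    def test_star_unresolved(self):
        t = read_newick("(A,B,C,D);")
        assert quartet_topology(t, "ABCD") == "unresolved"

    def test_caterpillar_restriction(self, caterpillar5):
        assert quartet_topology(caterpillar5, ["A", "C", "D", "E"]) == "A,C|D,E"

    def test_missing_taxon_error(self, caterpillar5):
        with pytest.raises(ValueError, match="not in tree"):
            quartet_topology(caterpillar5, ["A", "B", "C", "Z"])

    def test_matches_oracle_on_random_trees(self, rng):
        from tests_support import random_newick

        labels = list("ABCDEFG")
        for _ in range(10):
            t = read_newick(random_newick(labels, rng))
            quad = sorted(rng.choice(labels, size=4, replace=False))
            assert quartet_topology(t, quad) == _oracle_quartet(t, quad)


class TestQuartetScore:
    def test_identical_trees_count_all_quartets(self):
        nwk = "((((A,B),C),D),E);"
        gts = GeneTreeSet.from_newicks([nwk] * 10)
        cand = read_newick(nwk)
        assert quartet_score(cand, gts) == 10 * 5  # 10 trees x C(5,4)

    def test_missing_taxon_contributes_remaining_quartets(self):
        cand = read_newick("((((A,B),C),D),E);")
        gts = GeneTreeSet.from_newicks(["(((A,B),C),D);"])
        assert quartet_score(cand, gts) == 1  # C(4,4) = 1

    def test_matches_nested_loop_oracle(self, rng):
        for rep in range(5):
            sp = sim_species_tree(6, 1.0, seed=rep)
            trees = sim_gene_trees(sp, 15, missing_taxon_prob=0.15, seed=rep)
            trees = [t for t in trees if len(list(t.leaf_node_iter())) >= 4]
            gts = GeneTreeSet(trees)
            cand = sim_species_tree(6, 1.0, seed=rep + 50)
            assert quartet_score(cand, gts) == _oracle_score(cand, trees)


class TestInferSpeciesTree:
    def test_unanimous_gene_trees_recovered(self):
        nwk = "((((A,B),C),D),E);"
        gts = GeneTreeSet.from_newicks([nwk] * 5)
        est = infer_species_tree(gts)
        assert rf_distance(est, read_newick(nwk))[0] == 0

    def test_hillclimb_attains_exhaustive_optimum(self):
        for seed in range(6):
            sp = sim_species_tree(6, 1.0, seed=seed)
            gts = GeneTreeSet(
                sim_gene_trees(sp, 50, missing_taxon_prob=0.1, seed=seed)
            )
            ex = infer_species_tree(gts, mode="exhaustive")
            hc = infer_species_tree(gts, mode="nni_hillclimb", seed=seed)
            assert quartet_score(hc, gts) == quartet_score(ex, gts)

    def test_statistical_consistency(self, balanced6):
        hits = 0
        for seed in range(10):
            gts = GeneTreeSet(sim_gene_trees(balanced6, 300, seed=seed))
            est = infer_species_tree(gts, mode="exhaustive")
            hits += rf_distance(est, balanced6)[0] == 0
        assert hits >= 9

    def test_deterministic_tie_break(self):
        gts = GeneTreeSet.from_newicks(["(A,B,C,D);"] * 3)
        a = write_newick(infer_species_tree(gts))
        b = write_newick(infer_species_tree(gts))
        assert a == b

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            infer_species_tree(GeneTreeSet.from_newicks(["(A,B,C);"]))


def _oracle_branch_freqs(species_tree, gene_trees):
    """All-quartet quadripartition tally via the string-based oracle."""
    from phylodisco.discordance import _quadripartitions
    from phylodisco._splits import TaxonRegistry

    labels = sorted(
        {lf.taxon.label for t in gene_trees for lf in t.leaf_node_iter()}
    )
    reg = TaxonRegistry(labels)
    out = {}
    for bid, masks in _quadripartitions(species_tree, reg):
        clusters = [reg.labels_of(m) for m in masks]
        tally = [0, 0, 0]
        for gt in gene_trees:
            present = {lf.taxon.label for lf in gt.leaf_node_iter()}
            for a in clusters[0]:
                for b in clusters[1]:
                    for c in clusters[2]:
                        for d in clusters[3]:
                            if not {a, b, c, d} <= present:
                                continue
                            topo = _oracle_quartet(gt, (a, b, c, d))
                            if topo == "unresolved":
                                continue
                            main = "|".join(
                                sorted(
                                    [
                                        ",".join(sorted((a, b))),
                                        ",".join(sorted((c, d))),
                                    ]
                                )
                            )
                            alt1 = "|".join(
                                sorted(
                                    [
                                        ",".join(sorted((a, c))),
                                        ",".join(sorted((b, d))),
                                    ]
                                )
                            )
                            if topo == main:
                                tally[0] += 1
                            elif topo == alt1:
                                tally[1] += 1
                            else:
                                tally[2] += 1
        out[bid] = tally
    return out


class TestBranchFrequencies:
    def test_concordant_gene_trees_give_fmain_one(self):
        nwk = "(((A,B),C),(D,E));"
        sp = read_newick(nwk)
        gts = GeneTreeSet.from_newicks([nwk] * 7)
        table = branch_frequencies(sp, gts)
        assert len(table.rows) == 2  # 5 taxa -> 2 internal branches
        for r in table.rows:
            assert r.f_main == 1.0
            # one-per-cluster quartets per tree = product of cluster sizes
            combos = 1
            for cl in r.clusters:
                combos *= len(cl)
            assert r.n_quartets_resolved == 7 * combos

    def test_frequencies_sum_to_one(self, balanced6):
        gts = GeneTreeSet(sim_gene_trees(balanced6, 100, seed=1))
        for r in branch_frequencies(balanced6, gts).rows:
            if r.n_quartets_resolved:
                assert r.f_main + r.f_alt1 + r.f_alt2 == pytest.approx(1.0)

    def test_matches_brute_force_on_handcrafted_trees(self):
        sp = read_newick("(((A,B),C),(D,E));")
        gene_nwks = [
            "(((A,B),C),(D,E));",
            "(((A,C),B),(D,E));",
            "((A,(B,D)),(C,E));",
        ]
        gts = GeneTreeSet.from_newicks(gene_nwks)
        table = branch_frequencies(sp, gts)
        oracle = _oracle_branch_freqs(sp, gts.trees)
        for r in table.rows:
            t = oracle[r.branch_id]
            n = sum(t)
            assert r.n_quartets_resolved == n
            assert (r.f_main, r.f_alt1, r.f_alt2) == pytest.approx(
                tuple(x / n for x in t)
            )

    def test_invariant_to_gene_tree_order_and_rerooting(self, balanced6):
        trees = sim_gene_trees(balanced6, 30, seed=4)
        fwd = branch_frequencies(balanced6, GeneTreeSet(trees))
        rev = branch_frequencies(balanced6, GeneTreeSet(trees[::-1]))
        rerooted = []
        for t in trees:
            t2 = read_newick(write_newick(t))
            leaves = list(t2.leaf_node_iter())
            t2.reroot_at_edge(leaves[0].edge, update_bipartitions=False)
            rerooted.append(t2)
        rr = branch_frequencies(balanced6, GeneTreeSet(rerooted))
        for a, b, c in zip(fwd.rows, rev.rows, rr.rows):
            assert (a.f_main, a.n_quartets_resolved) == (
                b.f_main,
                b.n_quartets_resolved,
            )
            assert a.f_main == pytest.approx(c.f_main)
            assert a.n_quartets_resolved == c.n_quartets_resolved

    def test_collapsing_never_increases_resolved_quartets(self, rng):
        sp = read_newick("(((A,B),C),(D,E));")
        nwks = [
            "(((A,B)20,C)80,(D,E)5);",
            "(((A,C)9,B)95,(D,E)60);",
            "(((A,B)50,C)15,(D,E)90);",
        ]
        full = GeneTreeSet.from_newicks(nwks)
        collapsed = GeneTreeSet(
            [collapse_low_support(t, 30) for t in full.trees]
        )
        t_full = branch_frequencies(sp, full)
        t_coll = branch_frequencies(sp, collapsed)
        for a, b in zip(t_full.rows, t_coll.rows):
            assert b.n_quartets_resolved <= a.n_quartets_resolved

    def test_nonbinary_species_tree_rejected(self):
        sp = read_newick("((A,B),C,D,E);")
        gts = GeneTreeSet.from_newicks(["(((A,B),C),(D,E));"])
        with pytest.raises(ValueError, match="binary"):
            branch_frequencies(sp, gts)

    def test_msc_expectation_on_focal_branch(self):
        T = 0.5
        expected = 1 - (2 / 3) * np.exp(-T)
        sp = read_newick(f"(((A:1,B:1):{T},C:{1+T}):8,(D:1,E:1):{8+T});")
        sp.is_rooted = True
        gts = GeneTreeSet(sim_gene_trees(sp, 10000, seed=99))
        table = branch_frequencies(sp, gts)
        row = next(
            r
            for r in table.rows
            if set(r.clusters[0]) | set(r.clusters[1]) == {"A", "B"}
        )
        se = np.sqrt(expected * (1 - expected) / 10000)
        assert abs(row.f_main - expected) < 3 * se


class TestClassify:
    def test_all_concordant_is_all_single_dominant(self):
        nwk = "(((A,B),C),(D,E));"
        table = branch_frequencies(
            read_newick(nwk), GeneTreeSet.from_newicks([nwk] * 4)
        )
        df, summary = classify_discordance(table)
        assert (df["label"] == "single_dominant").all()
        assert summary["pct_single_dominant"] == 100.0

    @pytest.mark.parametrize(
        "freqs,label",
        [
            ((0.34, 0.34, 0.32), "contested"),
            ((0.50, 0.30, 0.20), "single_dominant"),
            ((0.90, 0.05, 0.05), "single_dominant"),
        ],
    )
    def test_threshold_rules(self, freqs, label):
        from phylodisco.discordance import BranchFrequencyTable, BranchRow

        table = BranchFrequencyTable(
            [BranchRow("b1", (("A",), ("B",), ("C",), ("D",)), *freqs, 100)]
        )
        df, _ = classify_discordance(table)
        assert df["label"].iloc[0] == label

    def test_zero_quartets_uninformative(self):
        from phylodisco.discordance import BranchFrequencyTable, BranchRow

        table = BranchFrequencyTable(
            [BranchRow("b1", (("A",), ("B",), ("C",), ("D",)), 0, 0, 0, 0)]
        )
        df, summary = classify_discordance(table)
        assert df["label"].iloc[0] == "uninformative"
        assert summary["n_informative"] == 0
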