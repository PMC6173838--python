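"""Dollo-parsimony branch assignment: closed forms, fixture, exhaustive oracle."""

import itertools

import dendropy
import numpy as np
import pytest

from syntenic.census import (
    ABSENT,
    PRESENT,
    PSEUDOGENE,
    PresenceMatrix,
    dollo_losses,
    intact_counts,
    load_hox_fixture,
    read_matrix,
    write_matrix,
)
from syntenic.io_formats import ValidationError

STATES = (PRESENT, PSEUDOGENE, ABSENT)


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=False)


def _matrix(genes, taxa, grid):
    states = {(g, t): grid[i][j] for i, g in enumerate(genes) for j, t in enumerate(taxa)}
    return PresenceMatrix(tuple(genes), tuple(taxa), states)


def _edges(tree):
    """Branches named by child node; the root's stem is a branch too."""
    names, leaves_under = [], {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leaves_under[node] = {node.taxon.label}
        else:
            leaves_under[node] = set().union(*(leaves_under[c] for c in node.child_nodes()))
        label = node.taxon.label if node.is_leaf() else (
            node.label or (node.taxon.label if node.taxon else "root"))
        names.append((label, frozenset(leaves_under[node])))
    return names


def _oracle_min_losses(tree, absent):
    """Exhaustive search: smallest edge sets whose removal separates exactly
    the absent leaves from the root."""
    edges = _edges(tree)
    all_leaves = max(edges, key=lambda e: len(e[1]))[1]
    best_size, best_sets = None, []
    for r in range(len(edges) + 1):
        for combo in itertools.combinations(edges, r):
            covered = set().union(*(e[1] for e in combo)) if combo else set()
            if covered == set(absent):
                if best_size is None:
                    best_size = r
                if r == best_size:
                    best_sets.append(frozenset(name for name, _ in combo))
        if best_size is not None:
            break
    return best_size, best_sets


class TestTwoLeafClosedForm:
    """For a 2-leaf tree the Dollo rule has a closed form; check all 9 state
    pairs under both pseudogene modes."""

    @pytest.mark.parametrize("mode", ["as_absent", "as_present"])
    @pytest.mark.parametrize("s_cat,s_zeb", list(itertools.product(STATES, STATES)))
    def test_all_state_combinations(self, s_cat, s_zeb, mode):
        tree = _tree("(catfish,zebrafish)root;")
        m = _matrix(["g"], ["catfish", "zebrafish"], [[s_cat, s_zeb]])
        result = dollo_losses(m, tree, pseudogene_mode=mode)

        def gone(s):
            return s == ABSENT or (mode == "as_absent" and s == PSEUDOGENE)

        expected = {}
        if gone(s_cat) and gone(s_zeb):
            expected = {"root": frozenset({"g"})}
        elif gone(s_cat):
            expected = {"catfish": frozenset({"g"})}
        elif gone(s_zeb):
            expected = {"zebrafish": frozenset({"g"})}
        assert dict(result.losses_by_branch) == expected


def test_hox_fixture_reproduces_published_branch_assignment():
    """The packaged Hox matrix under as_absent mode yields the reported loss
    sets: eight genes on the common-ancestor stem, three catfish-specific,
    five zebrafish-specific."""
    matrix, tree = load_hox_fixture()
    result = dollo_losses(matrix, tree, pseudogene_mode="as_absent")
    assert result.losses("root") == frozenset(
        {"A2a", "A7a", "A10a", "C8b", "C10b", "D4b", "D9b", "D11b"})
    assert result.losses("Pangasianodon") == frozenset({"A5a", "A11a", "B10a"})
    assert result.losses("Danio") == frozenset({"B3b", "C4b", "C5b", "C9a", "D1a"})


def test_hox_fixture_pseudogene_mode_moves_the_three_hoxa_genes():
    """as_present keeps the zebrafish HoxA pseudogenes on the books, so their
    loss shifts from the common ancestor to the catfish branch."""
    matrix, tree = load_hox_fixture()
    result = dollo_losses(matrix, tree, pseudogene_mode="as_present")
    assert result.losses("root") == frozenset({"C8b", "C10b", "D4b", "D9b", "D11b"})
    assert result.losses("Pangasianodon") == frozenset(
        {"A2a", "A5a", "A7a", "A10a", "A11a", "B10a"})


class TestExhaustiveOracle:
    TOPOLOGIES = [
        "((A,B)ab,(C,D)cd)root;",
        "(((A,B)ab,C)abc,D)root;",
        "((A,B)ab,C)root;",
    ]

    @pytest.mark.parametrize("newick", TOPOLOGIES)
    def test_random_matrices_match_exhaustive_search(self, newick):
        tree = _tree(newick)
        taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        rng = np.random.default_rng(50)
        for _ in range(50):
            n_genes = int(rng.integers(1, 6))  # grid stays <= 5 genes x <= 4 taxa
            grid = [[STATES[int(rng.integers(0, 3))] for _ in taxa]
                    for _ in range(n_genes)]
            m = _matrix([f"g{i}" for i in range(n_genes)], taxa, grid)
            for mode in ("as_absent", "as_present"):
                result = dollo_losses(m, tree, pseudogene_mode=mode)
                for i in range(n_genes):
                    gene = f"g{i}"
                    absent = {
                        t for j, t in enumerate(taxa)
                        if grid[i][j] == ABSENT
                        or (mode == "as_absent" and grid[i][j] == PSEUDOGENE)
                    }
                    got = frozenset(
                        b for b, genes in result.losses_by_branch.items() if gene in genes
                    )
                    size, minimal_sets = _oracle_min_losses(tree, absent)
                    assert len(got) == size
                    assert got in minimal_sets

    def test_gene_and_taxon_order_invariance(self):
        tree = _tree("((A,B)ab,(C,D)cd)root;")
        rng = np.random.default_rng(1)
        taxa = ["A", "B", "C", "D"]
        grid = [[STATES[int(rng.integers(0, 3))] for _ in taxa] for _ in range(6)]
        genes = [f"g{i}" for i in range(6)]
        base = dollo_losses(_matrix(genes, taxa, grid), tree)
        perm_g = [4, 2, 0, 5, 1, 3]
        perm_t = [3, 1, 0, 2]
        shuffled = _matrix(
            [genes[i] for i in perm_g],
            [taxa[j] for j in perm_t],
            [[grid[i][j] for j in perm_t] for i in perm_g],
        )
        assert dict(dollo_losses(shuffled, tree).losses_by_branch) == dict(
            base.losses_by_branch)


class TestIntactCounts:
    def test_all_present_counts_every_gene(self):
        m = _matrix([f"g{i}" for i in range(10)], ["A", "B"],
                    [[PRESENT, PRESENT]] * 10)
        assert intact_counts(m) == {"A": 10, "B": 10}

    def test_asymmetric_losses_give_difference_identity(self):
        # A lacks 3 genes B has; B lacks 5 genes A has: count(A) - count(B) = 2.
        genes = [f"g{i}" for i in range(12)]
        grid = [[ABSENT, PRESENT]] * 3 + [[PRESENT, ABSENT]] * 5 + [[PRESENT, PRESENT]] * 4
        m = _matrix(genes, ["A", "B"], grid)
        counts = intact_counts(m)
        assert counts["A"] - counts["B"] == 2

    def test_pseudogene_mode_changes_the_tally(self):
        m = _matrix(["g1", "g2"], ["A"], [[PSEUDOGENE], [PRESENT]])
        assert intact_counts(m, "as_absent") == {"A": 1}
        assert intact_counts(m, "as_present") == {"A": 2}

    def test_random_matrix_matches_cell_tally(self):
        rng = np.random.default_rng(9)
        taxa = ["A", "B", "C"]
        grid = [[STATES[int(rng.integers(0, 3))] for _ in taxa] for _ in range(30)]
        m = _matrix([f"g{i}" for i in range(30)], taxa, grid)
        counts = intact_counts(m, "as_absent")
        for j, t in enumerate(taxa):
            assert counts[t] == sum(1 for i in range(30) if grid[i][j] == PRESENT)


def test_matrix_tsv_round_trip(tmp_path):
    matrix, _ = load_hox_fixture()
    p = tmp_path / "m.tsv"
    write_matrix(matrix, p)
    assert read_matrix(p) == matrix


def test_taxon_mismatch_rejected():
    tree = _tree("(A,B)root;")
    m = _matrix(["g"], ["A", "C"], [[PRESENT, ABSENT]])
    with pytest.raises(ValidationError, match="mismatch"):
        dollo_losses(m, tree)
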