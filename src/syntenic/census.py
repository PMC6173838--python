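"""Dollo-parsimony assignment of gene losses to tree branches.

Given a gene × taxon matrix of states (present / pseudogene / absent) and a
rooted tree whose root is assumed to carry every gene — the natural
assumption for post-duplication gene complements such as the teleost Hox
clusters — each gene's losses are placed on branches under Dollo parsimony:
one origin, no regains, the minimum number of loss events.  That minimum
has a clean combinatorial form: the loss branches of a gene are exactly the
edges above the *maximal* subtrees whose leaves all lack the gene.  A gene
absent from every leaf is lost once, on the root's stem branch.

Pseudogenes are genes in transit: still in the genome, no longer
functional.  ``pseudogene_mode`` decides which side of the ledger they land
on — ``as_absent`` (default) treats a pseudogene as a loss for branch
assignment (the gene's function is gone), ``as_present`` treats it as
retained (the locus is still there).  Both views are defensible and real
datasets mix them, so the mode is explicit everywhere.

Branches are named by their child node: a leaf branch by the taxon, an
internal branch by the internal node's label, and the root's stem by the
root label (or ``"root"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import dendropy

from .io_formats import FormatError, ValidationError

__all__ = ["PresenceMatrix", "BranchLossAssignment", "dollo_losses", "intact_counts",
           "read_matrix", "write_matrix", "load_tree", "load_hox_fixture",
           "PRESENT", "PSEUDOGENE", "ABSENT"]

PRESENT = "present"
PSEUDOGENE = "pseudogene"
ABSENT = "absent"

_STATE_CODES = {"P": PRESENT, "Ψ": PSEUDOGENE, "PSI": PSEUDOGENE, "A": ABSENT}
_CODE_OF = {PRESENT: "P", PSEUDOGENE: "Ψ", ABSENT: "A"}


@dataclass(frozen=True)
class PresenceMatrix:
    """Gene × taxon state matrix; every cell one of present/pseudogene/absent."""

    genes: tuple[str, ...]
    taxa: tuple[str, ...]
    states: Mapping[tuple[str, str], str]  # (gene, taxon) -> state

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene labels in matrix")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon labels in matrix")
        for g in self.genes:
            for t in self.taxa:
                s = self.states.get((g, t))
                if s not in (PRESENT, PSEUDOGENE, ABSENT):
                    raise ValidationError(f"cell ({g}, {t}) missing or invalid: {s!r}")

    def state(self, gene: str, taxon: str) -> str:
        return self.states[(gene, taxon)]


@dataclass(frozen=True)
class BranchLossAssignment:
    losses_by_branch: Mapping[str, frozenset[str]]  # branch name -> genes lost on it
    intact_counts: Mapping[str, int]  # taxon -> intact gene count (mode-dependent)
    pseudogene_mode: str

    def losses(self, branch: str) -> frozenset[str]:
        return self.losses_by_branch.get(branch, frozenset())


def _effective_absent(state: str, pseudogene_mode: str) -> bool:
    if pseudogene_mode == "as_absent":
        return state in (ABSENT, PSEUDOGENE)
    if pseudogene_mode == "as_present":
        return state == ABSENT
    raise ValidationError(f"unknown pseudogene_mode {pseudogene_mode!r}")


def dollo_losses(matrix: PresenceMatrix, tree: dendropy.Tree,
                 pseudogene_mode: str = "as_absent") -> BranchLossAssignment:
    """Place every gene's losses on tree branches under Dollo parsimony.

    Requires every matrix taxon to be a tree leaf and vice versa.  For each
    gene, the branch set is the unique minimum set of edges whose removal
    disconnects exactly the gene-lacking leaves from the (all-present) root.
    """
    leaf_names = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if leaf_names != set(matrix.taxa):
        raise ValidationError(
            f"taxon mismatch: matrix {sorted(matrix.taxa)} vs tree {sorted(leaf_names)}"
        )

    losses: dict[str, set[str]] = {}
    for gene in matrix.genes:
        absent = {
            t for t in matrix.taxa
            if _effective_absent(matrix.state(gene, t), pseudogene_mode)
        }
        if not absent:
            continue
        # Post-order: a subtree is "all-absent" iff every leaf under it is.
        all_absent: dict[dendropy.Node, bool] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                all_absent[node] = node.taxon.label in absent
            else:
                all_absent[node] = all(all_absent[c] for c in node.child_nodes())
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            if all_absent[node] and (parent is None or not all_absent[parent]):
                losses.setdefault(_branch_name(node), set()).add(gene)

    return BranchLossAssignment(
        losses_by_branch={b: frozenset(g) for b, g in sorted(losses.items())},
        intact_counts=intact_counts(matrix, pseudogene_mode),
        pseudogene_mode=pseudogene_mode,
    )


def intact_counts(matrix: PresenceMatrix, pseudogene_mode: str = "as_absent"
                  ) -> dict[str, int]:
    """Intact genes per taxon.  ``as_present`` counts pseudogenes as intact."""
    return {
        t: sum(
            1 for g in matrix.genes
            if not _effective_absent(matrix.state(g, t), pseudogene_mode)
        )
        for t in matrix.taxa
    }


def _branch_name(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    label = node.label or (node.taxon.label if node.taxon is not None else None)
    if label:
        return label
    return "root" if node.parent_node is None else f"node{id(node)}"


# ---------------------------------------------------------------------------
# Serialisation: matrix as TSV (cells P / Ψ / A), tree as Newick.

def read_matrix(path: str | Path) -> PresenceMatrix:
    """Read a gene × taxon TSV: header row of taxa, one row per gene."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty matrix")
    header = lines[0].split("\t")
    taxa = tuple(header[1:])
    genes: list[str] = []
    states: dict[tuple[str, str], str] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(taxa) + 1:
            raise FormatError(f"{path}:{lineno}: expected {len(taxa) + 1} columns")
        gene = fields[0]
        genes.append(gene)
        for taxon, code in zip(taxa, fields[1:]):
            state = _STATE_CODES.get(code.strip().upper() if code.strip() != "Ψ" else "Ψ")
            if state is None:
                raise FormatError(f"{path}:{lineno}: unknown state code {code!r}")
            states[(gene, taxon)] = state
    return PresenceMatrix(genes=tuple(genes), taxa=taxa, states=states)


def write_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(matrix.taxa) + "\n")
        for g in matrix.genes:
            fh.write(
                g + "\t" + "\t".join(_CODE_OF[matrix.state(g, t)] for t in matrix.taxa) + "\n"
            )


def load_tree(path: str | Path) -> dendropy.Tree:
    """Load a rooted Newick tree (internal node labels name the branches)."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             suppress_internal_node_taxa=False)
    for node in tree.preorder_node_iter():
        if node.taxon is not None and node.label is None and not node.is_leaf():
            node.label = node.taxon.label
        if not node.is_leaf() and node.taxon is None and node.label is None:
            pass  # unnamed internal nodes fall back to the "root"/id naming
    return tree


def load_hox_fixture() -> tuple[PresenceMatrix, dendropy.Tree]:
    """The packaged Hox-cluster gene state matrix for striped catfish vs zebrafish.

    Encodes the reported Hox gene complements of *Pangasianodon hypophthalmus*
    (striped catfish) and *Danio rerio* (zebrafish): eight genes missing from
    both lineages (lost in their common ancestor), three catfish-specific and
    five zebrafish-specific losses; the three HoxA genes reported as zebrafish
    pseudogenes are encoded Ψ, so the two pseudogene modes give different
    catfish-vs-ancestor attributions for them.  The tree is the two-taxon
    rooted tree whose stem branch represents the common ancestor.
    """
    data = resources.files("syntenic") / "data"
    with resources.as_file(data / "hox_presence.tsv") as p:
        matrix = read_matrix(p)
    with resources.as_file(data / "catfish_zebrafish.nwk") as p:
        tree = load_tree(p)
    return matrix, tree
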