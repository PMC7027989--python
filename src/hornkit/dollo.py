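"""Dollo-parsimony reconstruction of gene-family gain and loss on a fixed
rooted species tree.

Under the Dollo criterion a family arises exactly once — at the most recent
common ancestor of the species that retain it — and can only be lost on
branches below that gain. The minimal-loss reconstruction marks a node
present iff it lies inside the gain clade and still has at least one
descendant leaf carrying the family; each parent-present/child-absent
branch inside the clade is one loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hornkit.records import FamilyMatrix, SpeciesTree, TreeNode

log = logging.getLogger("hornkit")


def gain_node(tree: SpeciesTree, present_leaves: set[str]) -> TreeNode:
    """The single Dollo gain point: MRCA of the leaves carrying the family."""
    if not present_leaves:
        raise ValueError("family present in no leaf")
    return tree.mrca(sorted(present_leaves))


def reconstruct_family(tree: SpeciesTree, present_leaves: set[str]
                       ) -> tuple[set[str], set[tuple[str, str]]]:
    """Minimal-loss presence set and loss branches for one family.

    Returns (presence node labels, loss branches as (parent, child) label
    pairs). The loss count is minimal over all single-gain assignments.
    """
    gain = gain_node(tree, present_leaves)
    present = set(present_leaves)
    presence: set[str] = set()
    # a node is present iff inside the gain clade and its clade retains the family
    stack = [gain]
    while stack:
        node = stack.pop()
        if tree.leaf_set(node) & present:
            presence.add(node.label)
            stack.extend(node.children)
    losses: set[tuple[str, str]] = set()
    for label in presence:
        for child in tree.node(label).children:
            if child.label not in presence:
                losses.add((label, child.label))
    return presence, losses


@dataclass
class DolloReconstruction:
    """Aggregate gain/loss bookkeeping over a whole family matrix."""

    gain_of: dict[str, str]                       # family -> gain node label
    presence_of: dict[str, set[str]]              # family -> presence labels
    losses_of: dict[str, set[tuple[str, str]]]    # family -> loss branches
    branch_gains: dict[tuple[str, str], int]
    branch_losses: dict[tuple[str, str], int]
    ancestral_count: dict[str, int]               # node label -> families present

    def branches_table(self) -> pd.DataFrame:
        rows = [{"parent": p, "child": c, "gains": self.branch_gains[(p, c)],
                 "losses": self.branch_losses[(p, c)]}
                for p, c in self.branch_gains]
        return pd.DataFrame(rows)

    def nodes_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"node": n, "ancestral_count": c}
             for n, c in self.ancestral_count.items()])


@dataclass
class SpeciesSummary:
    """Per-species family statistics of a count matrix.

    n_orphans follows the requested definition:
      specific_single   — families found only in this species, with one gene
      specific_any      — families found only in this species, any size
      single_copy_universal — single-copy in this species regardless of others
    """

    table: pd.DataFrame

    @staticmethod
    def from_matrix(matrix: FamilyMatrix,
                    orphan_def: str = "specific_single") -> "SpeciesSummary":
        if orphan_def not in {"specific_single", "specific_any",
                              "single_copy_universal"}:
            raise ValueError(f"unknown orphan definition {orphan_def!r}")
        df = matrix.df
        present = df >= 1
        n_species_with = present.sum(axis=1)
        rows = []
        for sp in df.columns:
            col = df[sp]
            specific = (n_species_with == 1) & present[sp]
            if orphan_def == "specific_single":
                orphans = int((specific & (col == 1)).sum())
            elif orphan_def == "specific_any":
                orphans = int(specific.sum())
            else:
                orphans = int((present[sp] & (col == 1)).sum())
            rows.append({"species": sp,
                         "n_families": int(present[sp].sum()),
                         "n_orphans": orphans,
                         "n_genes": int(col.sum())})
        return SpeciesSummary(pd.DataFrame(rows).set_index("species"))


def aggregate(tree: SpeciesTree, matrix: FamilyMatrix,
              orphan_def: str = "specific_single"
              ) -> tuple[DolloReconstruction, SpeciesSummary]:
    """Reconstruct every family and tally gains/losses per branch.

    Counts are binarized (>=1 -> present) for reconstruction; copy numbers
    feed only the species summary. Verifies the branch balance
    count(child) = count(parent) + gains - losses on every branch.
    """
    leaves = set(tree.leaf_names)
    species = set(matrix.species)
    if leaves != species:
        raise ValueError(
            "species/leaf mismatch: only in tree "
            f"{sorted(leaves - species)}, only in matrix {sorted(species - leaves)}")

    empty = matrix.df.index[(matrix.df < 1).all(axis=1)].tolist()
    if empty:
        raise ValueError(f"families present in zero species: {empty[:5]}")

    presence = matrix.presence()
    gain_of: dict[str, str] = {}
    presence_of: dict[str, set[str]] = {}
    losses_of: dict[str, set[tuple[str, str]]] = {}
    branch_gains = {(p.label, c.label): 0 for p, c in tree.branches()}
    branch_losses = {(p.label, c.label): 0 for p, c in tree.branches()}
    ancestral = {n.label: 0 for n in tree.preorder()}

    for fam in matrix.families:
        present_leaves = set(presence.columns[presence.loc[fam]])
        pres, losses = reconstruct_family(tree, present_leaves)
        g = gain_node(tree, present_leaves)
        gain_of[fam] = g.label
        presence_of[fam] = pres
        losses_of[fam] = losses
        if g is not tree.root:
            branch_gains[(g.parent.label, g.label)] += 1
        for br in losses:
            branch_losses[br] += 1
        for label in pres:
            ancestral[label] += 1

    for parent, child in tree.branches():
        pl, cl = parent.label, child.label
        balance = ancestral[pl] + branch_gains[(pl, cl)] - branch_losses[(pl, cl)]
        assert ancestral[cl] == balance, (
            f"branch balance violated on {pl}->{cl}: "
            f"{ancestral[cl]} != {balance}")

    recon = DolloReconstruction(gain_of, presence_of, losses_of,
                                branch_gains, branch_losses, ancestral)
    return recon, SpeciesSummary.from_matrix(matrix, orphan_def)


def brute_force_min_losses(tree: SpeciesTree, present_leaves: set[str]) -> int:
    """Exhaustive minimal loss count under the single-gain constraint.

    Enumerates every 0/1 assignment to internal nodes (leaves fixed by the
    data), keeps assignments with exactly one 0->1 transition counting the
    root's own state as a potential gain, and minimises the number of 1->0
    branches. Exponential in internal-node count — an oracle for small
    trees, not a production path.
    """
    internals = [n for n in tree.preorder() if not n.is_leaf]
    leaves = {n.label: (n.label in present_leaves) for n in tree.leaves}
    best = None
    for mask in range(2 ** len(internals)):
        state = dict(leaves)
        for i, node in enumerate(internals):
            state[node.label] = bool((mask >> i) & 1)
        gains = int(state[tree.root.label])
        losses = 0
        ok = True
        for parent, child in tree.branches():
            p, c = state[parent.label], state[child.label]
            if not p and c:
                gains += 1
            elif p and not c:
                losses += 1
        if gains != 1:
            ok = False
        if ok and (best is None or losses < best):
            best = losses
    assert best is not None, "no single-gain assignment exists"
    return best
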