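"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive everywhere (GFF3 convention). Any
half-open arithmetic is local to the function that needs it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class SeqRecord:
    """A sequence read or CDS: id is the first whitespace token of the header."""

    id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record with empty id")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneRecord:
    """A gene feature with optional family membership (1-based inclusive)."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "."
    family_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


class FamilyMatrix:
    """Species x gene-family count matrix (families are rows).

    Thin wrapper over a pandas DataFrame with integer counts, families as the
    index and species as columns; labels must be unique and counts >= 0.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate family ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate species names: {dups}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise TypeError("family matrix counts must be integers")
        if (arr < 0).any():
            raise ValueError("family matrix counts must be >= 0")
        self._df = counts.copy()

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def species(self) -> list[str]:
        return list(self._df.columns)

    @property
    def families(self) -> list[str]:
        return list(self._df.index)

    @property
    def counts(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def presence(self) -> pd.DataFrame:
        """Binarized view: count >= 1 -> True."""
        return self._df >= 1

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FamilyMatrix) and self._df.equals(other._df)


class TreeNode:
    """Node of a rooted species tree."""

    __slots__ = ("label", "parent", "children", "length")

    def __init__(self, label: str, length: Optional[float] = None):
        self.label = label
        self.parent: Optional[TreeNode] = None
        self.children: list[TreeNode] = []
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:
        return f"TreeNode({self.label!r})"


class SpeciesTree:
    """A rooted tree with uniquely labelled nodes.

    Internal nodes lacking labels are auto-named N1..Nk in preorder, so the
    labelling is deterministic for a given topology. Leaf labels are species
    names and must be unique.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._autolabel()
        labels = [n.label for n in self.preorder()]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate node labels in tree: {dup}")
        self._by_label = {n.label: n for n in self.preorder()}
        self._leafset_cache: dict[str, frozenset[str]] = {}

    def _autolabel(self) -> None:
        counter = 0
        for node in self.preorder():
            if not node.label:
                counter += 1
                node.label = f"N{counter}"

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    # -- queries -----------------------------------------------------------
    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.label for n in self.leaves]

    def node(self, label: str) -> TreeNode:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r} in tree") from None

    def leaf_set(self, node: TreeNode) -> frozenset[str]:
        """Leaf labels in the clade of `node` (cached)."""
        if node.label not in self._leafset_cache:
            for n in self.postorder():
                if n.is_leaf:
                    self._leafset_cache[n.label] = frozenset({n.label})
                else:
                    s: frozenset[str] = frozenset()
                    for c in n.children:
                        s |= self._leafset_cache[c.label]
                    self._leafset_cache[n.label] = s
        return self._leafset_cache[node.label]

    def mrca(self, leaf_labels: Sequence[str]) -> TreeNode:
        """Most recent common ancestor of a non-empty set of leaves."""
        wanted = set(leaf_labels)
        if not wanted:
            raise ValueError("mrca of empty leaf set")
        unknown = wanted - set(self.leaf_names)
        if unknown:
            raise KeyError(f"unknown leaves: {sorted(unknown)}")
        node = self.node(next(iter(wanted)))
        while not wanted <= self.leaf_set(node):
            assert node.parent is not None
            node = node.parent
        return node

    def branches(self) -> Iterator[tuple[TreeNode, TreeNode]]:
        """(parent, child) pairs in preorder of the child."""
        for node in self.preorder():
            for child in node.children:
                yield node, child

    def has_branch_lengths(self) -> bool:
        return all(
            n.length is not None for n in self.preorder() if n is not self.root
        )

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf set of every non-root, non-leaf clade plus trivial splits."""
        return {self.leaf_set(n) for n in self.preorder()}

    def copy(self) -> "SpeciesTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            for c in node.children:
                cc = clone(c)
                cc.parent = new
                new.children.append(cc)
            return new

        return SpeciesTree(clone(self.root))

    def to_newick(self, with_lengths: bool = True, internal_labels: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.label
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if internal_labels:
                    s += node.label
            if with_lengths and node.length is not None and node is not self.root:
                s += f":{node.length:g}"
            return s

        return fmt(self.root) + ";"
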