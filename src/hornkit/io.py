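"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython; Newick parsing to dendropy.
Every reader is total on the corresponding writer's output, and no reader
silently drops records: skips are counted and logged.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import dendropy
import pandas as pd
from Bio import SeqIO

from hornkit.records import FamilyMatrix, GeneRecord, SeqRecord, SpeciesTree, TreeNode

log = logging.getLogger("hornkit")

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_sequences(path: PathLike, format: str = "fasta") -> list[SeqRecord]:
    """Read FASTA or FASTQ into SeqRecords, uppercasing sequences.

    An empty file yields an empty list. Malformed records raise
    :class:`ParseError` naming the offending record/line.
    """
    if format not in {"fasta", "fastq"}:
        raise ValueError(f"unknown sequence format {format!r}")
    records: list[SeqRecord] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), format)):
            quality = None
            if format == "fastq":
                phred = rec.letter_annotations["phred_quality"]
                quality = "".join(chr(q + 33) for q in phred)
            records.append(SeqRecord(rec.id, str(rec.seq).upper(), quality))
    except ValueError as exc:
        lines_per_rec = 4 if format == "fastq" else 2
        raise ParseError(
            f"{path}: malformed {format} near record {len(records) + 1} "
            f"(about line {len(records) * lines_per_rec + 1}): {exc}"
        ) from exc
    return records


def write_sequences(records: Iterable[SeqRecord], path: PathLike,
                    format: str = "fasta") -> None:
    with open(path, "w") as fh:
        for rec in records:
            if format == "fasta":
                fh.write(f">{rec.id}\n{rec.sequence}\n")
            elif format == "fastq":
                qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
                fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
            else:
                raise ValueError(f"unknown sequence format {format!r}")


# ---------------------------------------------------------------------------
# gene annotation (GFF3 + family table)
# ---------------------------------------------------------------------------

def _gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gene_annotation(gff3_path: PathLike,
                         family_table_path: Optional[PathLike] = None
                         ) -> list[GeneRecord]:
    """Read `gene` features from a GFF3 file and join family ids by gene id.

    Coordinates stay 1-based inclusive as in GFF3. Genes absent from the
    family table keep family_id None; family-table rows naming unknown genes
    are skipped with a logged warning.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{gff3_path}:{lineno}: expected 9 columns, got {len(cols)}")
            if cols[2] != "gene":
                continue
            attrs = _gff3_attributes(cols[8])
            gene_id = attrs.get("ID")
            if not gene_id:
                raise ParseError(f"{gff3_path}:{lineno}: gene feature without ID attribute")
            if gene_id in seen:
                raise ParseError(f"{gff3_path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneRecord(
                gene_id=gene_id, scaffold=cols[0],
                start=int(cols[3]), end=int(cols[4]),
                strand=cols[6] if cols[6] in {"+", "-"} else ".",
            ))

    if family_table_path is not None:
        table = pd.read_csv(family_table_path, sep="\t", comment="#",
                            dtype=str).dropna(subset=["gene_id"])
        if not {"gene_id", "family_id"} <= set(table.columns):
            raise ParseError(
                f"{family_table_path}: need columns gene_id, family_id")
        fam = dict(zip(table["gene_id"], table["family_id"]))
        unknown = set(fam) - seen
        if unknown:
            log.warning("family table names %d genes absent from GFF3 (skipped)",
                        len(unknown))
        for g in genes:
            g.family_id = fam.get(g.gene_id)
    return genes


def write_gene_annotation(genes: Iterable[GeneRecord], gff3_path: PathLike,
                          family_table_path: Optional[PathLike] = None) -> None:
    genes = list(genes)
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.scaffold}\thornkit\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
    if family_table_path is not None:
        with open(family_table_path, "w") as fh:
            fh.write("gene_id\tfamily_id\n")
            for g in genes:
                if g.family_id is not None:
                    fh.write(f"{g.gene_id}\t{g.family_id}\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def _from_dendropy(dnode: dendropy.Node) -> TreeNode:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
    else:
        label = dnode.label or ""
    node = TreeNode(label.replace(" ", "_") if label else "", dnode.edge.length)
    for child in dnode.child_nodes():
        cn = _from_dendropy(child)
        cn.parent = node
        node.children.append(cn)
    return node


def read_tree(newick_path: PathLike) -> SpeciesTree:
    """Read a single rooted Newick tree; auto-labels internal nodes N1.. in
    preorder when they carry no label."""
    try:
        trees = dendropy.TreeList.get(path=str(newick_path), schema="newick")
    except Exception as exc:
        raise ParseError(f"{newick_path}: {exc}") from exc
    if len(trees) != 1:
        raise ParseError(f"{newick_path}: expected exactly one tree, found {len(trees)}")
    return SpeciesTree(_from_dendropy(trees[0].seed_node))


def parse_tree(newick: str) -> SpeciesTree:
    """Parse a Newick string (convenience; same contract as read_tree)."""
    try:
        trees = dendropy.TreeList.get(data=newick, schema="newick")
    except Exception as exc:
        raise ParseError(f"bad newick: {exc}") from exc
    if len(trees) != 1:
        raise ParseError(f"expected exactly one tree, found {len(trees)}")
    return SpeciesTree(_from_dendropy(trees[0].seed_node))


def write_tree(tree: SpeciesTree, path: PathLike, with_lengths: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(with_lengths=with_lengths) + "\n")


# ---------------------------------------------------------------------------
# family matrices
# ---------------------------------------------------------------------------

def read_family_matrix(tsv_path: PathLike) -> FamilyMatrix:
    """Read a species-by-family count table.

    First column: family id; header row: species names; cells: integer
    counts. Missing or non-integer cells are errors (no imputation).
    """
    df = pd.read_csv(tsv_path, sep="\t", comment="#", index_col=0, dtype=str)
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise ParseError(f"{tsv_path}: missing cells in families {rows[:5]}")
    parsed = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            parsed[col] = df[col].astype("int64")
        except ValueError:
            bad = df.index[~df[col].str.fullmatch(r"-?\d+")].tolist()
            raise ParseError(
                f"{tsv_path}: non-integer cell at family {bad[0]!r}, "
                f"species {col!r}: {df.loc[bad[0], col]!r}") from None
    parsed.index.name = df.index.name or "family_id"
    return FamilyMatrix(parsed)


def write_family_matrix(matrix: FamilyMatrix, path: PathLike,
                        header_comment: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df = matrix.df.copy()
        df.index.name = df.index.name or "family_id"
        df.to_csv(fh, sep="\t")


def tsv_header_comment(tool: str, seed: Optional[int] = None) -> str:
    """Standard provenance line put atop every tabular output."""
    from hornkit import __version__
    import sys

    parts = [f"hornkit {__version__}", tool, "cmd: " + " ".join(sys.argv)]
    if seed is not None:
        parts.append(f"seed: {seed}")
    return " | ".join(parts)
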