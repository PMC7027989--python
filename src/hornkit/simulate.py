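"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its arguments including the seed, and
its output validates against the corresponding reader. The generators
emulate the statistical structure the analyses assume, not full biological
realism:

* read pools — one high-coverage host genome plus low-coverage, GC-divergent
  contaminant genomes, i.i.d. base composition (no repeats), substitution
  errors only;
* presence/absence family matrices evolved under a single-gain /
  multiple-independent-loss process on a known tree, conditioned on
  non-extinction by rejection;
* gene annotations with planted tandem arrays, spacer genes and
  exponential intergenic gaps;
* CDS sets whose synonymous-codon bias is controlled by a Dirichlet
  concentration (smaller concentration = more ordered usage = higher SCUO);
* alignments evolved site-independently under equal-rate substitution
  models at a series of rate multipliers.

Ground truth is returned in small per-generator dataclasses keyed by the
simulated record ids; the ids themselves encode nothing about the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from hornkit.records import FamilyMatrix, GeneRecord, SeqRecord, SpeciesTree
import pandas as pd

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# read pools
# ---------------------------------------------------------------------------

@dataclass
class ReadPoolTruth:
    source_of: dict[str, str]          # read id -> host | contaminant_i
    genome_size: dict[str, int]        # source label -> bp
    genome_gc: dict[str, float]
    genome_depth: dict[str, float]


def _random_genome(rng: np.random.Generator, size: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=size, p=p).astype(np.uint8)


def sim_read_pool(host_size: int, host_gc: float, host_depth: float,
                  contaminants: Sequence[tuple[int, float, float]] = (),
                  read_len: int = 100, error_rate: float = 0.002,
                  seed: int = 1) -> tuple[list[SeqRecord], ReadPoolTruth]:
    """Simulate a sequencing run over a host genome plus contaminants.

    Genomes are i.i.d. base draws at the requested GC; reads are uniform
    substrings (both strands equiprobable) with i.i.d. substitution errors;
    the read count per genome is Poisson with mean size*depth/read_len.
    """
    rng = np.random.default_rng(seed)
    specs = [("host", host_size, host_gc, host_depth)]
    specs += [(f"contaminant_{i + 1}", s, g, d)
              for i, (s, g, d) in enumerate(contaminants)]
    for label, size, gc, depth in specs:
        if depth <= 0:
            raise ValueError(f"{label}: depth must be > 0")
        if not 0 <= gc <= 1:
            raise ValueError(f"{label}: gc must be in [0, 1]")
        if size < 10 * read_len:
            raise ValueError(f"{label}: genome size must be >= 10x read length")
    if not 0 <= error_rate < 0.05:
        raise ValueError("error_rate must be in [0, 0.05)")

    all_reads: list[np.ndarray] = []
    labels: list[str] = []
    for label, size, gc, depth in specs:
        genome = _random_genome(rng, size, gc)
        n_reads = int(rng.poisson(size * depth / read_len))
        starts = rng.integers(0, size - read_len + 1, size=n_reads)
        mat = genome[starts[:, None] + np.arange(read_len)]
        rev = rng.random(n_reads) < 0.5
        mat[rev] = 3 - mat[rev, ::-1]          # reverse complement in 2-bit space
        if error_rate > 0:
            err = rng.random(mat.shape) < error_rate
            shift = rng.integers(1, 4, size=int(err.sum()))
            mat[err] = (mat[err] + shift) % 4
        all_reads.append(mat)
        labels.extend([label] * n_reads)

    mat = np.concatenate(all_reads) if all_reads else np.empty((0, read_len), np.uint8)
    order = rng.permutation(len(mat))
    ascii_mat = _BASES[mat[order]]
    qual = "I" * read_len
    records, source_of = [], {}
    for i, row in enumerate(ascii_mat):
        rid = f"read{i:07d}"
        records.append(SeqRecord(rid, row.tobytes().decode("ascii"), qual))
        source_of[rid] = labels[order[i]]
    truth = ReadPoolTruth(
        source_of=source_of,
        genome_size={l: s for l, s, _, _ in specs},
        genome_gc={l: g for l, _, g, _ in specs},
        genome_depth={l: d for l, _, _, d in specs},
    )
    return records, truth


# ---------------------------------------------------------------------------
# Dollo presence/absence matrices
# ---------------------------------------------------------------------------

@dataclass
class DolloTruth:
    gain_of: dict[str, str]                      # family -> gain node label
    losses_of: dict[str, list[tuple[str, str]]]  # family -> loss branches
    total_losses: int = 0


def sim_dollo_matrix(tree: SpeciesTree, n_families: int, loss_prob: float,
                     seed: int = 1) -> tuple[FamilyMatrix, DolloTruth]:
    """Evolve presence/absence families under single gain, independent loss.

    Each family gains at a uniformly chosen node (leaves included) and is
    lost independently with loss_prob on every branch below the gain while
    the lineage still carries it. Families extinct in all leaves are
    rejected and resimulated, so the output matrix is observable.
    """
    if not 0 <= loss_prob < 1:
        raise ValueError("loss_prob must be in [0, 1)")
    if len(tree.leaves) < 2:
        raise ValueError("tree needs at least 2 leaves")
    rng = np.random.default_rng(seed)
    nodes = list(tree.preorder())
    leaf_names = tree.leaf_names
    rows, fams = [], []
    gain_of, losses_of = {}, {}
    total_losses = 0
    fam_i = 0
    while fam_i < n_families:
        gain = nodes[rng.integers(len(nodes))]
        present: set[str] = set()
        losses: list[tuple[str, str]] = []
        stack = [gain]
        while stack:
            node = stack.pop()
            present.add(node.label)
            for child in node.children:
                if rng.random() < loss_prob:
                    losses.append((node.label, child.label))
                else:
                    stack.append(child)
        leaf_presence = [leaf in present for leaf in leaf_names]
        if not any(leaf_presence):
            continue            # extinct everywhere: rejection-resimulate
        name = f"fam{fam_i:05d}"
        fams.append(name)
        rows.append([int(x) for x in leaf_presence])
        gain_of[name] = gain.label
        losses_of[name] = losses
        total_losses += len(losses)
        fam_i += 1
    df = pd.DataFrame(rows, index=pd.Index(fams, name="family_id"),
                      columns=leaf_names, dtype="int64")
    return FamilyMatrix(df), DolloTruth(gain_of, losses_of, total_losses)


# ---------------------------------------------------------------------------
# tandem annotations
# ---------------------------------------------------------------------------

@dataclass
class PlantedArray:
    scaffold: str
    family_id: str
    members: list[str]
    n_spacers: int                     # spacers between one consecutive pair


@dataclass
class TandemTruth:
    arrays: list[PlantedArray]


def sim_tandem_annotation(n_scaffolds: int = 5, genes_per_scaffold: int = 100,
                          n_arrays: int = 10,
                          array_size_range: tuple[int, int] = (2, 5),
                          spacer_range: tuple[int, int] = (0, 3),
                          intergenic_mean: float = 2000.0,
                          seed: int = 1) -> tuple[list[GeneRecord], TandemTruth]:
    """Annotation with planted tandem arrays among singleton background genes.

    Background genes each get a unique singleton family. Each planted array
    holds k same-family genes (k uniform in array_size_range); its spacer
    genes — extra singleton-family genes — are all inserted between one
    randomly chosen consecutive pair, so the array is callable exactly at
    spacer thresholds s >= its spacer count. Intergenic gaps are
    exponential(intergenic_mean); coordinates are laid out left to right.
    """
    lo_a, hi_a = array_size_range
    lo_s, hi_s = spacer_range
    if not 2 <= lo_a <= hi_a <= 10:
        raise ValueError("array_size_range must lie within [2, 10]")
    if not 0 <= lo_s <= hi_s <= 10:
        raise ValueError("spacer_range must lie within [0, 10]")
    capacity = n_scaffolds * max(1, genes_per_scaffold // 2)
    if n_arrays > capacity:
        raise ValueError(f"{n_arrays} arrays exceed capacity {capacity} "
                         f"({n_scaffolds} scaffolds x {genes_per_scaffold} genes)")
    rng = np.random.default_rng(seed)
    genes: list[GeneRecord] = []
    arrays: list[PlantedArray] = []
    gid = 0
    bg_fam = 0

    def new_background(scaffold_items: list[tuple[str, str]]) -> None:
        nonlocal gid, bg_fam
        scaffold_items.append((f"g{gid:05d}", f"BG{bg_fam:05d}"))
        gid += 1
        bg_fam += 1

    per_scaffold = [n_arrays // n_scaffolds + (1 if i < n_arrays % n_scaffolds else 0)
                    for i in range(n_scaffolds)]
    for sc_i in range(n_scaffolds):
        scaffold = f"scaf{sc_i + 1}"
        items: list[tuple[str, str]] = []       # (gene_id, family_id)
        for _ in range(genes_per_scaffold):
            new_background(items)
        for a_i in range(per_scaffold[sc_i]):
            k = int(rng.integers(lo_a, hi_a + 1))
            m = int(rng.integers(lo_s, hi_s + 1))
            fam = f"ARR{len(arrays):04d}"
            member_ids = [f"g{gid + j:05d}" for j in range(k)]
            gid += k
            block: list[tuple[str, str]] = [(mid, fam) for mid in member_ids]
            if k > 1 and m > 0:
                gap_at = int(rng.integers(1, k))     # between members gap_at-1, gap_at
                spacers = []
                for _ in range(m):
                    spacers.append((f"g{gid:05d}", f"BG{bg_fam:05d}"))
                    gid += 1
                    bg_fam += 1
                block = block[:gap_at] + spacers + block[gap_at:]
            pos = int(rng.integers(0, len(items) + 1))
            items[pos:pos] = block
            arrays.append(PlantedArray(scaffold, fam, member_ids, m))
        pos = 1
        for gene_id, fam in items:
            length = int(rng.integers(800, 1201))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(gene_id, scaffold, pos, pos + length - 1,
                                    strand, fam))
            pos += length + int(rng.exponential(intergenic_mean)) + 1
    return genes, TandemTruth(arrays)


# ---------------------------------------------------------------------------
# CDS sets with controllable codon bias
# ---------------------------------------------------------------------------

@dataclass
class CdsTruth:
    bias_concentration: float
    gc_target: Optional[float]
    gc_achieved: float
    gc_satisfied: bool


def _tilted(p: np.ndarray, gc_codon: np.ndarray, t: float) -> np.ndarray:
    w = p * np.exp(t * gc_codon)
    return w / w.sum()


def sim_cds_set(n_genes: int, length_codons: int = 300,
                bias_concentration: float = 1.0,
                gc_target: Optional[float] = None,
                seed: int = 1,
                id_prefix: str = "gene") -> tuple[list[SeqRecord], CdsTruth]:
    """CDS set whose synonymous-codon usage follows per-gene Dirichlet draws.

    Amino acids are i.i.d. uniform over the 20; per gene and per amino
    acid, synonym probabilities are Dirichlet(bias_concentration) draws, so
    small concentrations give ordered (high-SCUO) usage and large
    concentrations approach uniform synonym use (SCUO -> 0). Start codon
    ATG, no internal stops, one terminal stop. GC is emergent: a gc_target
    only tilts the synonym choice toward GC-rich or GC-poor codons and is
    flagged unsatisfied when the tilt cannot reach it.
    """
    from hornkit.scuo import SYNONYM_FAMILIES

    if length_codons < 30:
        raise ValueError("length_codons must be >= 30")
    if bias_concentration <= 0:
        raise ValueError("bias_concentration must be > 0")
    rng = np.random.default_rng(seed)
    aas = sorted(SYNONYM_FAMILIES)
    fam_codons = {aa: SYNONYM_FAMILIES[aa] for aa in aas}
    fam_gc = {aa: np.array([c.count("G") + c.count("C") for c in fam_codons[aa]],
                           dtype=float)
              for aa in aas}

    tilt = 0.0
    satisfied = True
    if gc_target is not None:
        def expected_gc(t: float) -> float:
            num = den = 0.0
            for aa in aas:
                n = len(fam_codons[aa])
                p = _tilted(np.full(n, 1.0 / n), fam_gc[aa], t)
                num += float((p * fam_gc[aa]).sum())
                den += 3.0
            return num / den

        lo, hi = -8.0, 8.0
        if not expected_gc(lo) <= gc_target <= expected_gc(hi):
            satisfied = False
            tilt = lo if gc_target < expected_gc(lo) else hi
        else:
            for _ in range(60):          # bisection on the monotone tilt curve
                mid = (lo + hi) / 2
                if expected_gc(mid) < gc_target:
                    lo = mid
                else:
                    hi = mid
            tilt = (lo + hi) / 2

    records = []
    gc_total = base_total = 0
    stops = ["TAA", "TAG", "TGA"]
    for g in range(n_genes):
        probs = {}
        for aa in aas:
            n = len(fam_codons[aa])
            p = rng.dirichlet(np.full(n, bias_concentration)) if n > 1 else np.ones(1)
            probs[aa] = _tilted(p, fam_gc[aa], tilt) if tilt else p
        codons = ["ATG"]
        aa_draws = rng.integers(0, len(aas), size=length_codons - 1)
        for ai in aa_draws:
            aa = aas[ai]
            j = rng.choice(len(fam_codons[aa]), p=probs[aa])
            codons.append(fam_codons[aa][j])
        codons.append(stops[rng.integers(3)])
        seq = "".join(codons)
        gc_total += seq.count("G") + seq.count("C")
        base_total += len(seq)
        records.append(SeqRecord(f"{id_prefix}{g:05d}", seq))
    achieved = gc_total / base_total if base_total else 0.0
    if gc_target is not None and abs(achieved - gc_target) > 0.05:
        satisfied = False
    return records, CdsTruth(bias_concentration, gc_target, achieved, satisfied)


# ---------------------------------------------------------------------------
# alignment series at increasing substitution rates
# ---------------------------------------------------------------------------

@dataclass
class AlignmentTruth:
    rate_multipliers: list[float]
    model: str
    base_length: int


def _evolve(tree: SpeciesTree, length: int, mult: float, c: int,
            rng: np.random.Generator) -> dict[str, np.ndarray]:
    root_seq = rng.integers(0, c, size=length)
    seqs = {tree.root.label: root_seq}
    for node in tree.preorder():
        if node is tree.root:
            continue
        b = node.length * mult
        q = math.exp(-c / (c - 1) * b)
        parent = seqs[node.parent.label]
        child = parent.copy()
        hit = rng.random(length) >= q        # a substitution event (may resample same)
        child[hit] = rng.integers(0, c, size=int(hit.sum()))
        seqs[node.label] = child
    return seqs


def sim_alignment_series(tree: SpeciesTree, base_length: int = 2000,
                         rate_multipliers: Sequence[float] = (1, 2, 5, 10),
                         model: str = "JC_nt", seed: int = 1
                         ) -> tuple[list[list[SeqRecord]], AlignmentTruth]:
    """Leaf alignments evolved under an equal-rate model at scaled rates.

    JC_nt: 4-state Jukes-Cantor; Poisson_aa: 20-state equal-rate model.
    Branch lengths (expected substitutions per site) are scaled by each
    multiplier; one alignment is returned per multiplier, in order.
    """
    if model not in {"JC_nt", "Poisson_aa"}:
        raise ValueError(f"unknown model {model!r}")
    if not tree.has_branch_lengths():
        raise ValueError("tree must carry branch lengths")
    if any(m <= 0 for m in rate_multipliers):
        raise ValueError("rate multipliers must be > 0")
    c = 4 if model == "JC_nt" else 20
    alphabet = "ACGT" if c == 4 else "ACDEFGHIKLMNPQRSTVWY"
    rng = np.random.default_rng(seed)
    out = []
    for mult in rate_multipliers:
        seqs = _evolve(tree, base_length, float(mult), c, rng)
        aln = [SeqRecord(leaf, "".join(alphabet[s] for s in seqs[leaf]))
               for leaf in tree.leaf_names]
        out.append(aln)
    return out, AlignmentTruth([float(m) for m in rate_multipliers],
                               model, base_length)
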