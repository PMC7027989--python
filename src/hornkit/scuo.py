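"""Synonymous codon usage order (SCUO) and GC content per gene, plus the
comparison between a candidate gene set (e.g. horizontally transferred
genes) and the rest of the genome.

SCUO measures how ordered a gene's synonymous codon choice is. For each
amino acid i with degeneracy n_i >= 2 present in the gene, the Shannon
entropy of its synonym usage H_i = -sum_j p_ij ln p_ij is compared with the
maximum ln n_i; the normalized entropy deficiency

    O_i = (ln n_i - H_i) / ln n_i

is averaged over amino acids weighted by their share F_i of all degenerate
amino-acid occurrences:  SCUO = sum_i F_i * O_i.

SCUO is 0 when every represented degenerate amino acid uses its synonyms
uniformly and 1 when each uses a single codon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from hornkit.records import SeqRecord

log = logging.getLogger("hornkit")

_TABLE = CodonTable.unambiguous_dna_by_id[1]   # standard genetic code
STOP_CODONS = set(_TABLE.stop_codons)
SENSE_CODONS = sorted(_TABLE.forward_table)    # 61 codons
AA_OF_CODON = dict(_TABLE.forward_table)

SYNONYM_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in AA_OF_CODON.items():
    SYNONYM_FAMILIES.setdefault(_aa, []).append(_codon)
for _aa in SYNONYM_FAMILIES:
    SYNONYM_FAMILIES[_aa].sort()
DEGENERATE_AAS = {aa for aa, codons in SYNONYM_FAMILIES.items() if len(codons) >= 2}


class CdsRejected(ValueError):
    """CDS unusable for codon-usage statistics (length, internal stop...)."""


@dataclass
class CodonUsage:
    """Sense-codon counts, GC and SCUO for one CDS."""

    gene_id: str
    counts: dict[str, int]
    n_codons: int
    gc: float
    scuo: Optional[float] = None        # None when no degenerate aa present
    n_skipped_codons: int = 0           # codons containing N


def codon_counts(cds: SeqRecord) -> CodonUsage:
    """Count sense codons of a CDS.

    The terminal stop codon is excluded from the counts but included in the
    GC fraction (computed over all CDS bases). Codons containing N are
    skipped with a count kept. A CDS whose length is not a multiple of 3,
    or with an internal stop codon, is rejected.
    """
    seq = cds.sequence.upper()
    if len(seq) % 3 != 0:
        raise CdsRejected(f"{cds.id}: length {len(seq)} not a multiple of 3")
    if not seq:
        raise CdsRejected(f"{cds.id}: empty sequence")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    counts: dict[str, int] = {}
    skipped = 0
    for i, codon in enumerate(codons):
        if set(codon) - set("ACGT"):
            skipped += 1
            continue
        if codon in STOP_CODONS:
            raise CdsRejected(f"{cds.id}: internal stop codon {codon} at codon {i + 1}")
        counts[codon] = counts.get(codon, 0) + 1
    if skipped:
        log.info("%s: %d codons with ambiguous bases skipped", cds.id, skipped)
    denom = sum(1 for b in seq if b in "ACGT")
    gc = sum(1 for b in seq if b in "GC") / denom if denom else 0.0
    return CodonUsage(cds.id, counts, sum(counts.values()), gc,
                      n_skipped_codons=skipped)


def scuo_gene(usage: CodonUsage) -> Optional[float]:
    """Composition-weighted normalized entropy deficiency of synonym use.

    Returns None (excluded, logged) for genes containing no degenerate
    amino acid occurrence.
    """
    aa_counts: dict[str, dict[str, int]] = {}
    for codon, n in usage.counts.items():
        aa = AA_OF_CODON[codon]
        if aa in DEGENERATE_AAS:
            aa_counts.setdefault(aa, {})[codon] = n
    total = sum(sum(c.values()) for c in aa_counts.values())
    if total == 0:
        log.info("%s: no degenerate amino acids, SCUO undefined", usage.gene_id)
        return None
    scuo = 0.0
    for aa, codons in aa_counts.items():
        n_i = sum(codons.values())
        h = -sum((c / n_i) * math.log(c / n_i) for c in codons.values() if c)
        hmax = math.log(len(SYNONYM_FAMILIES[aa]))
        o_i = (hmax - h) / hmax
        scuo += (n_i / total) * o_i
    return scuo


def usage_table(cds_records: Iterable[SeqRecord]) -> list[CodonUsage]:
    """Codon usage + SCUO for a CDS set; rejected genes are logged and
    dropped."""
    out = []
    for rec in cds_records:
        try:
            u = codon_counts(rec)
        except CdsRejected as exc:
            log.warning("rejected: %s", exc)
            continue
        u.scuo = scuo_gene(u)
        out.append(u)
    return out


@dataclass
class GroupComparison:
    """HGT-vs-rest style comparison of SCUO and GC."""

    n_group: int
    n_rest: int
    mean_scuo_group: float
    mean_scuo_rest: float
    mean_gc_group: float
    mean_gc_rest: float
    scuo_u: Optional[float] = None
    scuo_p: Optional[float] = None
    gc_u: Optional[float] = None
    gc_p: Optional[float] = None


def compare_groups(group_ids: Iterable[str],
                   all_usages: Sequence[CodonUsage]) -> GroupComparison:
    """Mann-Whitney U (two-sided) on SCUO and GC between a gene set and the
    remaining genes. Genes with undefined SCUO are excluded from the SCUO
    test but kept in the GC comparison. Groups smaller than 3 get means
    only (test skipped with a warning)."""
    ids = set(group_ids)
    grp = [u for u in all_usages if u.gene_id in ids]
    rest = [u for u in all_usages if u.gene_id not in ids]
    if not grp or not rest:
        raise ValueError("both groups must be non-empty")
    scuo_g = [u.scuo for u in grp if u.scuo is not None]
    scuo_r = [u.scuo for u in rest if u.scuo is not None]
    gc_g = [u.gc for u in grp]
    gc_r = [u.gc for u in rest]
    cmp = GroupComparison(
        n_group=len(grp), n_rest=len(rest),
        mean_scuo_group=float(np.mean(scuo_g)) if scuo_g else float("nan"),
        mean_scuo_rest=float(np.mean(scuo_r)) if scuo_r else float("nan"),
        mean_gc_group=float(np.mean(gc_g)),
        mean_gc_rest=float(np.mean(gc_r)),
    )
    if min(len(grp), len(rest)) < 3:
        log.warning("group too small for a rank test; means only")
        return cmp
    if scuo_g and scuo_r:
        u, p = stats.mannwhitneyu(scuo_g, scuo_r, alternative="two-sided")
        cmp.scuo_u, cmp.scuo_p = float(u), float(p)
    u, p = stats.mannwhitneyu(gc_g, gc_r, alternative="two-sided")
    cmp.gc_u, cmp.gc_p = float(u), float(p)
    return cmp
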