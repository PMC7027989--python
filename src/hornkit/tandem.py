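"""Detection of tandemly arrayed genes.

Two genes of the same family are tandem neighbours when they sit on the
same scaffold within a distance bound of each other and are separated by at
most s non-homologous intervening "spacer" genes; arrays are maximal chains
of such neighbours. The conventional spacer thresholds are s in
{0, 1, 5, 10} and the distance bound 100 kb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from hornkit.records import GeneRecord

log = logging.getLogger("hornkit")

DEFAULT_MAX_DISTANCE = 100_000


@dataclass
class TandemCluster:
    """A maximal run of same-family genes on one scaffold."""

    scaffold: str
    family_id: str
    members: list[str]          # gene ids in coordinate order
    spacers: int                # the s threshold used for the call
    span_bp: int

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("tandem cluster needs >= 2 members")


def _sorted_by_scaffold(genes: Sequence[GeneRecord]) -> dict[str, list[GeneRecord]]:
    with_family = [g for g in genes if g.family_id is not None]
    dropped = len(genes) - len(with_family)
    if dropped:
        log.info("tandem: %d genes without family assignment excluded", dropped)
    by_scaffold: dict[str, list[GeneRecord]] = {}
    for g in with_family:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    for scaffold in by_scaffold:
        by_scaffold[scaffold].sort(key=lambda g: (g.start, g.end, g.gene_id))
    return by_scaffold


def find_tandem_clusters(genes: Sequence[GeneRecord], s: int = 0,
                         max_distance: int = DEFAULT_MAX_DISTANCE,
                         whole_span: bool = False) -> list[TandemCluster]:
    """Call tandem arrays allowing at most `s` spacer genes between members.

    Genes are sorted per scaffold by (start, end, gene_id); links run between
    consecutive occurrences of a family in that order. Two occurrences are
    linked iff the number of other-family genes between them is <= s and
    their start-to-start distance is <= max_distance. With whole_span=True
    the distance bound instead applies to the whole array span (first to
    last member start). Strand is ignored; genes without a family are
    excluded (logged).
    """
    if s < 0:
        raise ValueError("spacer threshold must be >= 0")
    clusters: list[TandemCluster] = []
    for scaffold, ordered in sorted(_sorted_by_scaffold(genes).items()):
        index_of_family: dict[str, list[int]] = {}
        for i, g in enumerate(ordered):
            index_of_family.setdefault(g.family_id, []).append(i)
        for family, idxs in sorted(index_of_family.items()):
            if len(idxs) < 2:
                continue
            chain = [idxs[0]]
            runs: list[list[int]] = []
            for prev, cur in zip(idxs, idxs[1:]):
                n_spacers = cur - prev - 1   # intervening genes are all other-family
                dist = ordered[cur].start - ordered[prev].start
                linked = n_spacers <= s and (whole_span or dist <= max_distance)
                if linked and whole_span:
                    span = ordered[cur].start - ordered[chain[0]].start
                    linked = span <= max_distance
                if linked:
                    chain.append(cur)
                else:
                    runs.append(chain)
                    chain = [cur]
            runs.append(chain)
            for run in runs:
                if len(run) < 2:
                    continue
                members = [ordered[i].gene_id for i in run]
                span = ordered[run[-1]].end - ordered[run[0]].start + 1
                clusters.append(TandemCluster(scaffold, family, members, s, span))
    return clusters


def tandem_fraction(genes: Sequence[GeneRecord],
                    clusters: Sequence[TandemCluster]) -> float:
    """Percentage of family-assigned genes that sit in any tandem array."""
    with_family = [g.gene_id for g in genes if g.family_id is not None]
    if not with_family:
        return 0.0
    in_cluster = set()
    for c in clusters:
        in_cluster.update(c.members)
    return 100.0 * len(in_cluster & set(with_family)) / len(with_family)


def tandem_summary(genes: Sequence[GeneRecord],
                   spacer_values: Sequence[int] = (0, 1, 5, 10),
                   max_distance: int = DEFAULT_MAX_DISTANCE) -> pd.DataFrame:
    """Per-s summary: number of clusters, clustered genes, and fraction %."""
    rows = []
    for s in spacer_values:
        clusters = find_tandem_clusters(genes, s=s, max_distance=max_distance)
        n_genes = len({m for c in clusters for m in c.members})
        rows.append({"spacers": s, "n_clusters": len(clusters),
                     "n_genes": n_genes,
                     "fraction_pct": tandem_fraction(genes, clusters)})
    return pd.DataFrame(rows)
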