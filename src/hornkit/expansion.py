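"""Gene-family expansion screen.

Families restricted to a single species (species-specific) and families
with a single gene overall (orphans) are removed, the remaining counts are
z-scored per family across species to centre and normalise them, and the
largest families in a focal species are selected for inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from hornkit.records import FamilyMatrix

log = logging.getLogger("hornkit")


@dataclass
class FilterResult:
    matrix: FamilyMatrix
    removed: list[str]
    mean_family_size: float     # mean gene count per retained family


def filter_families(matrix: FamilyMatrix,
                    exclude: Optional[Sequence[str]] = None) -> FilterResult:
    """Drop species-specific families, single-gene families, and any ids in
    an optional exclusion list (e.g. transposon-derived families annotated
    externally)."""
    df = matrix.df
    present = df >= 1
    species_specific = present.sum(axis=1) == 1
    single_gene = df.sum(axis=1) <= 1
    drop = species_specific | single_gene
    if exclude:
        drop |= df.index.isin(set(exclude))
    removed = df.index[drop].tolist()
    kept = df.loc[~drop]
    if kept.empty:
        raise ValueError("no informative families after filtering")
    log.info("expansion filter: removed %d of %d families", len(removed), len(df))
    return FilterResult(FamilyMatrix(kept), removed,
                        float(kept.sum(axis=1).mean()))


@dataclass
class ZScoreMatrix:
    """Per-family z-scores across species, with the row moments recorded."""

    z: pd.DataFrame
    row_mean: pd.Series
    row_sd: pd.Series           # sample sd (ddof=1)
    dropped: list[str]          # zero-variance families


def zscore(matrix: FamilyMatrix) -> ZScoreMatrix:
    """Row-wise z-transform: z = (x - mean) / sd with sample sd (n-1).

    Rows with zero variance carry no cross-species signal and are dropped
    (logged). Requires at least two species.
    """
    df = matrix.df
    if df.shape[1] < 2:
        raise ValueError("z-scores need at least two species")
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    zero = sd == 0
    dropped = df.index[zero].tolist()
    if dropped:
        log.info("zscore: dropped %d zero-variance families", len(dropped))
    kept = df.loc[~zero].astype(float)
    z = kept.sub(mean[~zero], axis=0).div(sd[~zero], axis=0)
    return ZScoreMatrix(z, mean[~zero], sd[~zero], dropped)


def top_families(matrix: FamilyMatrix, focal_species: str,
                 n: int = 100, by: str = "count") -> list[str]:
    """The n largest families in the focal species.

    by="count" ranks by raw focal gene count (default); by="zscore" ranks
    by the focal species' z-score instead. Ties break by total count
    descending, then family id ascending. Asking for more families than
    exist returns all of them with a warning.
    """
    df = matrix.df
    if focal_species not in df.columns:
        raise KeyError(f"focal species {focal_species!r} not in matrix")
    if by == "count":
        key = df[focal_species]
    elif by == "zscore":
        zm = zscore(matrix)
        key = zm.z[focal_species].reindex(df.index)
        df = df.loc[key.dropna().index]
        key = key.dropna()
    else:
        raise ValueError(f"unknown ranking {by!r}")
    order = pd.DataFrame({
        "key": key, "total": df.sum(axis=1), "family": df.index,
    }).sort_values(["key", "total", "family"],
                   ascending=[False, False, True])
    if n > len(order):
        log.warning("requested top %d but only %d families available", n, len(order))
    return order["family"].head(n).tolist()
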