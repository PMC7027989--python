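"""Substitution-saturation assessment.

For every pair of taxa in an alignment the uncorrected p-distance is
plotted against a model-corrected distance; ordinary least squares of p on
d gives the saturation slope. As divergence grows, multiple hits make p
level off while d keeps growing, so the shallower the slope the stronger
the saturation. Poisson correction (d = -ln(1-p)) serves amino-acid data;
Jukes-Cantor and the closed-form Tamura-Nei (1993) distance serve
nucleotide data.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from hornkit.records import SeqRecord

log = logging.getLogger("hornkit")

_NT = set("ACGT")
_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _usable_mask(a: str, b: str, seqtype: str) -> list[bool]:
    alphabet = _NT if seqtype == "nt" else _AA
    if len(a) != len(b):
        raise ValueError(f"aligned sequences differ in length: {len(a)} vs {len(b)}")
    return [x in alphabet and y in alphabet for x, y in zip(a, b)]


def p_distance(a: str, b: str, seqtype: str = "nt") -> float:
    """Proportion of differing sites among usable (unambiguous, ungapped)
    sites; sites with a gap or ambiguity in either sequence are excluded
    from numerator and denominator alike."""
    mask = _usable_mask(a.upper(), b.upper(), seqtype)
    usable = sum(mask)
    if usable == 0:
        raise ValueError("no usable sites between the two sequences")
    diffs = sum(1 for x, y, m in zip(a.upper(), b.upper(), mask) if m and x != y)
    return diffs / usable


def _tn93(a: str, b: str) -> float:
    """Tamura-Nei 1993 distance from empirical base frequencies and the
    two transition classes (A<->G purine, C<->T pyrimidine) vs
    transversions. Returns inf when a logarithm argument drops to <= 0
    (saturated pair)."""
    a, b = a.upper(), b.upper()
    mask = _usable_mask(a, b, "nt")
    sites = [(x, y) for x, y, m in zip(a, b, mask) if m]
    n = len(sites)
    if n == 0:
        raise ValueError("no usable sites between the two sequences")
    freq = {base: 0.0 for base in "ACGT"}
    for x, y in sites:
        freq[x] += 0.5 / n
        freq[y] += 0.5 / n
    gA, gC, gG, gT = freq["A"], freq["C"], freq["G"], freq["T"]
    gR, gY = gA + gG, gC + gT
    p1 = sum(1 for x, y in sites if {x, y} == {"A", "G"}) / n   # purine ts
    p2 = sum(1 for x, y in sites if {x, y} == {"C", "T"}) / n   # pyrimidine ts
    q = sum(1 for x, y in sites if x != y) / n - p1 - p2        # transversions
    if min(gA, gC, gG, gT) <= 0:
        return math.inf
    k1 = 2 * gA * gG / gR
    k2 = 2 * gC * gT / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1 - p1 / k1 - q / (2 * gR)
    w2 = 1 - p2 / k2 - q / (2 * gY)
    w3 = 1 - q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return math.inf
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def corrected_distance(a: str, b: str, model: str = "poisson_aa") -> float:
    """Model-corrected distance; math.inf flags a saturated pair whose
    correction is undefined (log argument <= 0)."""
    if model == "poisson_aa":
        p = p_distance(a, b, "aa")
        return -math.log(1 - p) if p < 1 else math.inf
    if model == "jc_nt":
        p = p_distance(a, b, "nt")
        arg = 1 - 4 * p / 3
        return -0.75 * math.log(arg) if arg > 0 else math.inf
    if model == "tn93_nt":
        return _tn93(a, b)
    raise ValueError(f"unknown distance model {model!r}")


@dataclass
class DistancePair:
    taxon1: str
    taxon2: str
    p: float
    d: float


@dataclass
class SaturationResult:
    slope: float
    intercept: float
    slope_through_origin: float
    n_pairs: int
    n_saturated: int


def pairwise_distances(alignment: Sequence[SeqRecord],
                       model: str = "poisson_aa") -> list[DistancePair]:
    """p and corrected distances for every unordered taxon pair."""
    seqtype = "aa" if model == "poisson_aa" else "nt"
    pairs = []
    for ra, rb in itertools.combinations(alignment, 2):
        p = p_distance(ra.sequence, rb.sequence, seqtype)
        d = corrected_distance(ra.sequence, rb.sequence, model)
        pairs.append(DistancePair(ra.id, rb.id, p, d))
    return pairs


def saturation_slope(pairs: Sequence[DistancePair]) -> SaturationResult:
    """OLS of p (response) on d (predictor) over the finite pairs.

    Saturated pairs (infinite d) are excluded and counted. The
    through-origin slope sum(p*d)/sum(d^2) is reported alongside.
    """
    finite = [(q.d, q.p) for q in pairs if math.isfinite(q.d)]
    n_sat = len(pairs) - len(finite)
    if n_sat:
        log.info("saturation: %d saturated pairs excluded", n_sat)
    if len(finite) < 2:
        raise ValueError(f"need >= 2 finite pairs, have {len(finite)}")
    d = np.array([x for x, _ in finite])
    p = np.array([y for _, y in finite])
    slope, intercept = np.polyfit(d, p, 1)
    origin = float(np.sum(p * d) / np.sum(d * d)) if np.any(d) else float("nan")
    return SaturationResult(float(slope), float(intercept), origin,
                            len(finite), n_sat)
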