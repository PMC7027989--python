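"""K-mer spectrum construction, read profiling, depth-band decontamination
and Lander-Waterman genome sizing.

The workflow mirrors the read-cleaning stage of a haploid genome project
whose raw reads mix a high-coverage host with low-coverage symbiont
contamination: count canonical k-mers, locate the main (host) peak of the
depth histogram, keep reads whose k-mer depth falls inside a band around
that peak, and estimate genome size as

    genome size = total k-mer occurrences / expected (peak) k-mer depth.

K-mers are packed 2 bits per base into int64, so k <= 31. A k-mer and its
reverse complement are collapsed onto the lexicographically smaller of the
two (the canonical form); windows containing N are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from hornkit.records import SeqRecord

log = logging.getLogger("hornkit")

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i
_CODE_BASE = "ACGT"


def encode_bases(seq: str) -> np.ndarray:
    """Map a sequence string to codes A=0 C=1 G=2 T=3, everything else 4."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _check_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k}")
    if not 3 <= k <= 31:
        raise ValueError(f"k must be in [3, 31], got {k}")


def _window_codes(vals: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical codes and validity mask for every length-k window."""
    n = len(vals) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, bool)
    v = vals.astype(np.int64)
    code = np.zeros(n, np.int64)
    rc = np.zeros(n, np.int64)
    valid = np.ones(n, bool)
    for j in range(k):
        w = v[j:j + n]
        valid &= w != 4
        b = w & 3
        code = (code << 2) | b
        rc |= (3 - b) << (2 * j)
    return np.minimum(code, rc), valid


def kmer_to_code(kmer: str) -> int:
    vals = encode_bases(kmer)
    if (vals == 4).any():
        raise ValueError(f"k-mer {kmer!r} contains non-ACGT bases")
    code = 0
    for b in vals:
        code = (code << 2) | int(b)
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_CODE_BASE[code & 3])
        code >>= 2
    return "".join(reversed(out))


def canonical(kmer: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    rc = kmer.translate(comp)[::-1]
    return min(kmer, rc)


@dataclass
class KmerSpectrum:
    """Canonical k-mer -> occurrence count map with its occurrence total.

    Stored columnar: `codes` is the sorted array of packed canonical k-mers
    and `counts` the matching occurrence counts. `total_occurrences` equals
    the number of N-free windows in the read pool (= sum of counts).
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray
    total_occurrences: int

    @property
    def n_distinct(self) -> int:
        return len(self.codes)

    def count_of(self, kmer: str) -> int:
        code = kmer_to_code(canonical(kmer))
        i = np.searchsorted(self.codes, code)
        if i < len(self.codes) and self.codes[i] == code:
            return int(self.counts[i])
        return 0

    def depth_of_codes(self, codes: np.ndarray) -> np.ndarray:
        """Spectrum counts for an array of canonical codes (0 if absent)."""
        idx = np.searchsorted(self.codes, codes)
        idx_c = np.minimum(idx, len(self.codes) - 1)
        hit = self.codes[idx_c] == codes
        return np.where(hit, self.counts[idx_c], 0)

    def as_dict(self) -> dict[str, int]:
        """String-keyed view; intended for small spectra."""
        return {code_to_kmer(int(c), self.k): int(n)
                for c, n in zip(self.codes, self.counts)}

    def to_tsv(self, path: Union[str, Path], header_comment: str = "") -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# k={self.k} total_occurrences={self.total_occurrences}\n")
            fh.write("kmer\tcount\n")
            for c, n in zip(self.codes, self.counts):
                fh.write(f"{code_to_kmer(int(c), self.k)}\t{int(n)}\n")


def _concat_encoded(reads: Sequence[SeqRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Encode all reads into one array separated by sentinel 4s.

    Returns (values, offsets); read i occupies values[offsets[i] :
    offsets[i] + len(read_i)].
    """
    lengths = np.fromiter((len(r.sequence) for r in reads), np.int64, len(reads))
    offsets = np.zeros(len(reads), np.int64)
    np.cumsum(lengths[:-1] + 1, out=offsets[1:])
    total = int(lengths.sum()) + len(reads)
    vals = np.full(total, 4, np.uint8)
    for off, rec in zip(offsets, reads):
        vals[off:off + len(rec.sequence)] = encode_bases(rec.sequence)
    return vals, offsets


def count_kmers(reads: Sequence[SeqRecord], k: int = 17) -> KmerSpectrum:
    """Count canonical k-mers across a read pool.

    Windows containing N (or any non-ACGT base) are skipped;
    total_occurrences is exactly the number of counted windows.
    """
    _check_k(k)
    if not reads:
        raise ValueError("count_kmers: empty read pool")
    vals, _ = _concat_encoded(reads)
    canon, valid = _window_codes(vals, k)
    canon = canon[valid]
    codes, counts = np.unique(canon, return_counts=True)
    return KmerSpectrum(k=k, codes=codes, counts=counts.astype(np.int64),
                        total_occurrences=int(len(canon)))


# ---------------------------------------------------------------------------
# depth histogram and peak finding
# ---------------------------------------------------------------------------

def depth_histogram(spectrum: KmerSpectrum) -> dict[int, int]:
    """Map depth d -> number of distinct canonical k-mers seen d times."""
    if spectrum.n_distinct == 0:
        raise ValueError("empty spectrum")
    depths, n = np.unique(spectrum.counts, return_counts=True)
    hist = {int(d): int(c) for d, c in zip(depths, n)}
    assert sum(d * c for d, c in hist.items()) == spectrum.total_occurrences
    return hist


def _auto_min_depth(hist: dict[int, int]) -> int:
    """First local minimum of n(d) over the depths present, after d=1.

    This is the valley between the sequencing-error peak at depth ~1 and
    the signal peak; counting runs over depths actually present so sparse
    histograms behave sensibly.
    """
    ds = sorted(hist)
    if len(ds) < 3:
        return ds[0]
    for i in range(1, len(ds) - 1):
        if hist[ds[i]] <= hist[ds[i - 1]] and hist[ds[i]] <= hist[ds[i + 1]]:
            return ds[i]
    return ds[0]


def find_peak(hist: dict[int, int], min_depth: Union[int, str] = "auto") -> int:
    """Depth of the main histogram peak, searching at depth >= min_depth.

    min_depth="auto" places the cutoff at the first local minimum after
    d=1 (the error-peak valley). Ties break toward smaller depth.
    """
    if not hist:
        raise ValueError("empty histogram")
    lo = _auto_min_depth(hist) if min_depth == "auto" else int(min_depth)
    candidates = [(d, n) for d, n in sorted(hist.items()) if d >= lo]
    if not candidates:
        raise ValueError(f"no signal peak: all histogram mass below depth {lo}")
    best_d, best_n = candidates[0]
    for d, n in candidates[1:]:
        if n > best_n:
            best_d, best_n = d, n
    return best_d


def find_main_peak(hist: dict[int, int], smooth: int = 5) -> int:
    """Depth of the peak carrying the most sequencing mass.

    Maximises the occurrence-weighted histogram d*n(d) (moving-average
    smoothed) over d >= 2. Error k-mers are rare per k-mer and low-coverage
    contaminant k-mers are shallow, so even when they outnumber the host's
    distinct k-mers the host peak dominates in occurrences — this locates
    the genomic peak where plain argmax of n(d) can lock onto a
    contaminant blob.
    """
    if not hist:
        raise ValueError("empty histogram")
    dense = np.zeros(max(hist) + 1, dtype=float)
    for d, n in hist.items():
        dense[d] = d * n
    if len(dense) > 2:
        kernel = np.ones(smooth) / smooth
        smoothed = np.convolve(dense, kernel, mode="same")
    else:
        smoothed = dense
    smoothed[:2] = 0.0
    if not smoothed.any():
        raise ValueError("no signal peak above depth 1")
    return int(np.argmax(smoothed))


def suggest_band(hist: dict[int, int], peak: Optional[int] = None) -> "DepthBand":
    """Symmetric retention band around the main (mass-weighted) peak.

    The lower bound sits in the valley separating low-depth mass (errors
    and low-coverage contaminants) from the main peak: the midpoint of the
    flattest stretch of the dense histogram below the peak. The upper bound
    mirrors it about the peak.
    """
    if peak is None:
        peak = find_main_peak(hist)
    dense = np.zeros(max(hist) + 1, np.int64)
    for d, n in hist.items():
        dense[d] = n
    lo_region = dense[2:peak]
    if len(lo_region) == 0:
        return DepthBand(1, 2 * peak - 1)
    m = lo_region.min()
    tied = np.flatnonzero(lo_region == m) + 2
    valley = int(np.median(tied))
    return DepthBand(valley, 2 * peak - valley)


# ---------------------------------------------------------------------------
# read profiling and band filtering
# ---------------------------------------------------------------------------

@dataclass
class ReadProfile:
    """Per-read coordinates of the GC x depth 'blob' plot."""

    read_id: str
    gc: float
    median_depth: int
    n_kmers: int

    @property
    def flagged(self) -> bool:
        return self.n_kmers == 0


@dataclass
class DepthBand:
    """Inclusive depth interval [lo, hi] used for read retention."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not 1 <= self.lo <= self.hi:
            raise ValueError(f"invalid depth band [{self.lo}, {self.hi}]")

    def __contains__(self, depth: int) -> bool:
        return self.lo <= depth <= self.hi


def profile_reads(reads: Sequence[SeqRecord],
                  spectrum: KmerSpectrum) -> list[ReadProfile]:
    """GC fraction and lower-median k-mer depth per read.

    The spectrum must be built from the same pool (or a superset) so every
    N-free window has depth >= 1. The lower median is the element at index
    (n-1)//2 of the sorted depths — robust to errors near read ends. Reads
    with no countable k-mer (too short, or all windows contain N) get
    median_depth 0 and are flagged.
    """
    k = spectrum.k
    vals, offsets = _concat_encoded(reads)
    canon, valid = _window_codes(vals, k)
    depths = spectrum.depth_of_codes(canon)

    lengths = np.fromiter((len(r.sequence) for r in reads), np.int64, len(reads))
    gc_cum = np.concatenate(([0], np.cumsum(np.isin(vals, (1, 2)))))
    nn_cum = np.concatenate(([0], np.cumsum(vals != 4)))
    denom = nn_cum[offsets + lengths] - nn_cum[offsets]
    gc_count = gc_cum[offsets + lengths] - gc_cum[offsets]
    gc = np.where(denom > 0, gc_count / np.maximum(denom, 1), 0.0)

    med = np.zeros(len(reads), np.int64)
    nk = np.zeros(len(reads), np.int64)
    # vectorize per read-length group: windows of equal-length reads form a
    # rectangular block, so the lower median is one sort + one gather
    for L in np.unique(lengths):
        rows = np.flatnonzero(lengths == L)
        w = int(L) - k + 1
        if w <= 0:
            continue
        pos = offsets[rows][:, None] + np.arange(w)
        d = depths[pos]
        v = valid[pos]
        nvalid = v.sum(axis=1)
        d = np.where(v, d, np.iinfo(np.int64).max)
        d.sort(axis=1)
        idx = np.maximum(nvalid - 1, 0) // 2
        got = np.take_along_axis(d, idx[:, None], axis=1)[:, 0]
        med[rows] = np.where(nvalid > 0, got, 0)
        nk[rows] = nvalid

    return [ReadProfile(rec.id, float(gc[i]), int(med[i]), int(nk[i]))
            for i, rec in enumerate(reads)]


def filter_reads_by_band(profiles: Iterable[ReadProfile],
                         band: DepthBand) -> tuple[list[str], list[str]]:
    """Partition read ids into (kept, discarded) by median depth in band."""
    kept, discarded = [], []
    for p in profiles:
        (kept if p.median_depth in band else discarded).append(p.read_id)
    return kept, discarded


# ---------------------------------------------------------------------------
# genome sizing and coverage
# ---------------------------------------------------------------------------

@dataclass
class GenomeSizeEstimate:
    """Lander-Waterman estimate: size = total occurrences / peak depth."""

    total_occurrences: int
    peak_depth: int
    size_bp: int = field(init=False)

    def __post_init__(self) -> None:
        if self.peak_depth < 1:
            raise ValueError("peak depth must be >= 1")
        if self.total_occurrences < 1:
            raise ValueError("total occurrences must be >= 1")
        self.size_bp = self.total_occurrences // self.peak_depth

    def coverage_of(self, bases: int) -> float:
        return bases / self.size_bp


def estimate_genome_size(total_occurrences: int, peak_depth: int) -> GenomeSizeEstimate:
    """Genome size as the floored quotient of occurrences over peak depth."""
    return GenomeSizeEstimate(total_occurrences, peak_depth)


def size_from_spectrum(spectrum: KmerSpectrum,
                       min_depth: Union[int, str] = "auto",
                       exclude_error_kmers: bool = False) -> GenomeSizeEstimate:
    """Convenience: histogram, peak, and size estimate in one step.

    min_depth="mass" locates the peak with find_main_peak (mass-weighted,
    robust to contaminant blobs); "auto" or an integer follows the
    find_peak contract. exclude_error_kmers subtracts occurrences below
    the auto valley from the total before dividing (off by default: the
    plain quotient is the standard arithmetic).
    """
    hist = depth_histogram(spectrum)
    peak = find_main_peak(hist) if min_depth == "mass" else find_peak(hist, min_depth)
    total = spectrum.total_occurrences
    if exclude_error_kmers:
        valley = _auto_min_depth(hist)
        total -= sum(d * n for d, n in hist.items() if d < valley)
    return estimate_genome_size(total, peak)


def report_coverage(kept_bases: int, estimate: GenomeSizeEstimate) -> tuple[float, int]:
    """Fold coverage of kept bases over the estimated genome size.

    Returns (exact coverage, nearest-integer summary as in 'about 35x').
    """
    cov = kept_bases / estimate.size_bp
    return cov, round(cov)
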