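# Methods

hornkit reimplements, at desk scale, the bespoke computational stages of a
haploid plant genome project whose raw sequencing data mix the host with
low-coverage symbiont contamination: k-mer-based read decontamination and
genome sizing, Dollo-parsimony gene-family gain/loss, tandem-array
detection, gene-family expansion screening, substitution-saturation
assessment, and synonymous codon usage order (SCUO). This note records the
models, the parameters that matter, and the numerical choices.

## K-mer spectrum, decontamination and genome sizing

Canonical k-mers (the lexicographic minimum of a k-mer and its reverse
complement) are counted over the read pool with a 2-bit packed encoding
(k ≤ 31, odd; default k = 17, a standard choice for genomes of ~10^8 bp).
Windows containing N are skipped; `total_occurrences` is exactly the number
of counted windows, and the histogram identity Σ_d d·n(d) =
total_occurrences is asserted on every run.

Genome size follows the Lander–Waterman argument: every genome position is
covered by about (peak depth) k-mer occurrences, so

    size = total k-mer occurrences / peak depth   (floored quotient).

Two peak locators are provided. `find_peak` is the classical rule: argmax
of the distinct-k-mer counts n(d) at depths at or above a cutoff, with
`auto` placing the cutoff at the first local minimum after d = 1 (the
error-peak valley) and ties breaking toward smaller depth. `find_main_peak`
instead maximises the smoothed occurrence-weighted histogram d·n(d): when a
low-coverage contaminant contributes more *distinct* k-mers per depth bin
than the host (which it does whenever contaminant size × its narrow depth
spread beats host size over a wide Poisson spread), plain argmax locks onto
the contaminant, while the host peak always dominates in occurrence mass.
The CLI and the decontamination workflow use the mass-weighted peak;
`find_peak` remains available and is the right tool on a decontaminated
pool.

Reads are profiled by GC fraction (over non-N bases) and the **lower
median** of their k-mer depths — the element at index (n−1)//2 of the
sorted depths — which is robust to errors near read ends. Reads too short
to contain a k-mer are flagged with depth 0. The retention band is
inclusive on both ends; `suggest_band` puts the lower bound at the valley
between low-depth mass and the main peak (midpoint of the flattest stretch
of the dense histogram below the peak) and mirrors it above the peak. GC
plays no role in the default filter; it is reported for blob-plot style
inspection only.

Numerical caveat: the histogram peak is an integer while the expected
k-mer depth is depth·(L−k+1)/L (e.g. 33.6 at 40× with 100 bp reads and
k = 17), so size estimates carry a quantization error of up to roughly
1/peak; at 40× this is ~3%, shrinking with depth.

## Dollo gain/loss

A family matrix is binarized (count ≥ 1 → present); copy numbers feed only
the per-species summary. Under Dollo parsimony each family is gained once —
necessarily at the MRCA of the species retaining it — and can only be lost
below that gain. The minimal-loss reconstruction marks a node present iff
it lies in the gain clade and has a descendant leaf carrying the family;
losses are parent-present→child-absent branches. Aggregation verifies the
balance count(child) = count(parent) + gains − losses on every branch of
every input. A brute-force oracle (exhaustive enumeration of internal-state
assignments under the single-gain constraint) ships alongside and is
checked against the reconstruction on all leaf subsets of trees up to 7
leaves.

Parsimony under-counts true losses whenever independent losses erase an
entire internal clade's signal (the MRCA then shifts down); on matrices
simulated at loss probability 0.1 per branch the inferred total is roughly
half the simulated total, and the inequality inferred ≤ truth always holds.

"Orphan" is ambiguous in the field; the default statistic is
species-specific single-gene families, with `specific_any` and
`single_copy_universal` selectable.

## Tandem arrays

Genes are sorted per scaffold by (start, end, gene_id). Two consecutive
occurrences of a family are linked iff at most s other-family genes
intervene in sort order and their start-to-start distance is ≤ 100 kb
(defaults; both configurable, and a whole-span distance mode is available).
Clusters are maximal linked chains with ≥ 2 members; strand is ignored;
genes without a family assignment are excluded from calling and from the
tandem-fraction denominator (logged). Membership is monotone
non-decreasing in s, and the conventional thresholds s ∈ {0, 1, 5, 10} are
reported together.

## Expansion z-scores

Families present in exactly one species and families with a single gene
overall are removed (plus an optional externally supplied exclusion list,
e.g. transposon-derived families). Retained rows are z-scored across
species with the sample (n−1) standard deviation; zero-variance rows are
dropped and logged, and every retained row is standardised to mean 0, sd 1
within 1e−9. The top families in a focal species are ranked by raw focal
count (z-score ranking by flag), ties broken by total count then family id.

## Substitution saturation

For every taxon pair the uncorrected p-distance (differing / usable sites;
gaps and ambiguities excluded from both counts) is paired with a corrected
distance: Poisson −ln(1−p) for amino acids, Jukes–Cantor or the closed-form
Tamura–Nei (1993) distance for nucleotides. TN93 stands in for pooled
maximum-composite-likelihood distances, the closest closed-form per-pair
model; this substitution is flagged in output headers. Pairs whose
correction is undefined (log argument ≤ 0) are excluded and counted rather
than clamped. The saturation statistic is the OLS slope of p on d with free
intercept (through-origin slope Σpd/Σd² reported alongside): 1 means no
saturation, shallower means more.

## SCUO

For each amino acid i with degeneracy n_i ≥ 2 present in a gene, the
Shannon entropy of synonym usage H_i = −Σ_j p_ij ln p_ij is compared with
its maximum ln n_i; the normalized deficiency O_i = (ln n_i − H_i)/ln n_i
is averaged with weights F_i = occurrences of i / all degenerate-amino-acid
occurrences. Six-fold families (Leu, Ser, Arg) are treated as single
synonymous families of degeneracy six; only the standard genetic code is
supported. The terminal stop is excluded from codon counts but included in
the GC fraction; genes with internal stops or length not divisible by 3
are rejected and logged; genes with no degenerate amino acid have
undefined SCUO and are excluded from the rank test. Group comparison uses
the two-sided Mann–Whitney U (asymptotic with tie correction); group means
of SCUO and GC are reported either way, the test is skipped below n = 3
per group.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of their arguments including the seed.

* **Read pools** draw genomes as i.i.d. bases at a target GC (no repeats,
  no heterozygosity), reads as uniform substrings of either strand with
  Poisson read counts (mean size·depth/read_len) and i.i.d. substitution
  errors (no indels, no quality model). Defaults mirror the study's
  contamination structure: host at GC 0.50 and high depth versus
  GC-divergent contaminants at low depth. This reproduces the two-blob
  GC×depth pattern and Lander–Waterman depth expectations, which is what
  the decontamination and sizing stages consume; it says nothing about
  repeat-induced spectrum shoulders or mappability.
* **Dollo matrices** gain each family at a uniformly chosen node and lose
  it independently per branch below (default loss probability 0.1),
  conditioning on non-extinction by rejection. Branch lengths are ignored
  — losses are per-branch events, as parsimony itself assumes.
* **Tandem annotations** plant same-family arrays (sizes 2–5 by default)
  with all spacers of an array in one internal gap, so truth recovery at a
  spacer threshold is exact; intergenic gaps are exponential (mean 2 kb),
  gene lengths uniform 0.8–1.2 kb.
* **CDS sets** draw per-gene synonym probabilities from a symmetric
  Dirichlet (concentration 0.1 = strongly biased, 10 = near-uniform; 300
  codons per gene, amino acids uniform over the 20); GC targets are only
  nudged via an exponential tilt of synonym choice and flagged when
  unreachable. No selection, amino-acid composition or expression
  covariates are modelled.
* **Alignments** evolve site-independently under equal-rate models (4-state
  JC, 20-state Poisson) along a fixed tree, with all branch lengths scaled
  by each rate multiplier — sufficient to produce controlled saturation,
  with no rate heterogeneity across sites.

Passing tests therefore demonstrate correctness of the algorithms under
their own model assumptions, not robustness to repeat structure, indels,
alignment error, or lineage-specific composition bias in real data.

## Problem sizes

The test and acceptance workloads are sized for a desk run: the two-blob
pool is ~308k reads (~31 Mbp, k-mer pipeline ~1 min), the clean sizing
pool 100 kb at 40×, Dollo oracle checks cover all leaf subsets of trees up
to 7 leaves, alignments are 8 taxa × 2000 sites across five rate
multipliers, and SCUO groups are 200 genes × 300 codons each.
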