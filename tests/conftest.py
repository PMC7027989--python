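import pytest

from hornkit import kmer, simulate
from hornkit.io import parse_tree

# A fixed 8-leaf tree with branch lengths in expected substitutions/site,
# used for alignment simulation and saturation checks.
EIGHT_LEAF_NEWICK = (
    "(((A:0.08,B:0.12):0.05,(C:0.1,D:0.07):0.09):0.04,"
    "((E:0.11,F:0.06):0.08,(G:0.09,H:0.13):0.05):0.07);"
)


@pytest.fixture(scope="session")
def eight_leaf_tree():
    return parse_tree(EIGHT_LEAF_NEWICK)


@pytest.fixture(scope="session")
def balanced_quartet():
    return parse_tree("((A,B),(C,D));")


@pytest.fixture(scope="session")
def blob_pool():
    """Two-blob read pool: high-coverage host vs low-coverage GC-divergent
    contaminant, mimicking symbiont contamination of a haploid run."""
    reads, truth = simulate.sim_read_pool(
        host_size=200_000, host_gc=0.50, host_depth=150.0,
        contaminants=[(100_000, 0.65, 8.0)],
        read_len=100, error_rate=0.002, seed=1)
    return reads, truth


@pytest.fixture(scope="session")
def blob_spectrum(blob_pool):
    reads, _ = blob_pool
    return kmer.count_kmers(reads, k=17)


@pytest.fixture(scope="session")
def blob_profiles(blob_pool, blob_spectrum):
    reads, _ = blob_pool
    return kmer.profile_reads(reads, blob_spectrum)


@pytest.fixture(scope="session")
def clean_pool_40x():
    """Error-free single-genome pool: 100 kb at 40x, read length 100."""
    reads, truth = simulate.sim_read_pool(
        host_size=100_000, host_gc=0.5, host_depth=40.0,
        contaminants=[], read_len=100, error_rate=0.0, seed=1)
    return reads, truth


@pytest.fixture(scope="session")
def jc_alignment_series(eight_leaf_tree):
    """JC alignments at rate multipliers 0.1, 1, 2, 5, 10; 2000 sites."""
    mults = (0.1, 1.0, 2.0, 5.0, 10.0)
    alns, truth = simulate.sim_alignment_series(
        eight_leaf_tree, base_length=2000, rate_multipliers=mults,
        model="JC_nt", seed=1)
    return mults, alns


@pytest.fixture(scope="session")
def cds_two_groups():
    """Biased (Dirichlet 0.1) vs unbiased (Dirichlet 10) CDS groups."""
    biased, _ = simulate.sim_cds_set(200, 300, bias_concentration=0.1,
                                     seed=1, id_prefix="biased")
    uniform, _ = simulate.sim_cds_set(200, 300, bias_concentration=10.0,
                                      seed=2, id_prefix="uniform")
    return biased, uniform
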