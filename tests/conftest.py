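import numpy as np
import pytest

from foxpair import pdseq, simulate

#: A 10-motif reference list mixing G1 (FKHM-like) and G2 (GCAT-core)
#: patterns, including phase-shifted G1 variants so tandem TnG arrays can
#: complete head-to-tail pairs.
MOTIFS10 = [
    "TGTTTNN",
    "NTGTTTN",
    "NNTGTTT",
    "TGTTGNN",
    "NTGTTGN",
    "NNGCATN",
    "TGCATNN",
    "NGCATNC",
    "TNGCATN",
    "CGCATNN",
]


@pytest.fixture(scope="session")
def template():
    return pdseq.DegenerateTemplate()


@pytest.fixture(scope="session")
def rr_template():
    return pdseq.random_random_template()


@pytest.fixture(scope="session")
def motifs10():
    return list(MOTIFS10)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def topology_bundle():
    """Genome with linked (zero-gap) and far TnG arrays in two length classes,
    plus coverage boosted only at the zero-gap repeats."""
    cfg = simulate.GenomeConfig(
        chrom_lengths={"chr1": 150_000, "chr2": 150_000},
        n_chip_peaks=48,
        chip_peak_len=600,
        n_atac_peaks=30,
        atac_peak_len=400,
        tngs=(
            simulate.TnGPlant("TTTG", 5, count=10, strand="+", hh_offset=0),
            simulate.TnGPlant("TTTG", 12, count=10, strand="+", hh_offset=0),
            simulate.TnGPlant("TTTG", 5, count=10, strand="+"),
            simulate.TnGPlant("TTTG", 12, count=10, strand="+"),
        ),
    )
    return simulate.gen_genome(cfg, seed=11)
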