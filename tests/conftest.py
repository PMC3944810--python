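import numpy as np
import pandas as pd
import pysam
import pytest

from homeobias.simulate import SimConfig, simulate_truth


SMALL = SimConfig(
    n_genes=120,
    gene_length=600,
    baseline_mean=60.0,
    error_rate=0.0,
    seed=11,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Small error-free design used by most read-level tests."""
    return SMALL


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config)


@pytest.fixture(scope="session")
def sam_header() -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
    )


@pytest.fixture
def make_read(sam_header):
    """Factory for in-memory aligned reads on chr1."""

    def _make(seq: str, start: int = 0, cigar=None, qname: str = "r1", flag: int = 0):
        rec = pysam.AlignedSegment(sam_header)
        rec.query_name = qname
        rec.flag = flag
        rec.reference_id = 0
        rec.reference_start = start
        rec.mapping_quality = 60
        rec.cigartuples = cigar if cigar is not None else [(0, len(seq))]
        rec.query_sequence = seq
        return rec

    return _make


def count_frame(data: dict, genes=None) -> pd.DataFrame:
    """Build a gene x (library, category) frame from {(lib, cat): values}."""
    df = pd.DataFrame(data)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    if genes is not None:
        df.index = pd.Index(genes, name="gene_id")
    else:
        df.index = pd.Index([f"g{i}" for i in range(len(df))], name="gene_id")
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
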