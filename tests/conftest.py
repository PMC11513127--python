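import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_sumstats_frame(rows):
    """Build a summary-statistics DataFrame with default headers from a list
    of (snp, chrom, pos, ea, nea, eaf, beta, se, p, n) tuples."""
    cols = ["SNP", "CHR", "POS", "EA", "NEA", "EAF", "BETA", "SE", "P", "N"]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def sumstats_file(tmp_path):
    """Write a small well-formed scan to disk; returns a factory."""

    def _write(rows, name="scan.txt"):
        path = tmp_path / name
        make_sumstats_frame(rows).to_csv(path, sep="\t", index=False)
        return path

    return _write
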