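import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from genomepair import GenomeComparison, SimParams, simulate_pair

settings.register_profile(
    "deterministic", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_pair():
    """A small but fully featured simulated genome pair with ground truth."""
    p = SimParams(n_genes=60, gene_len_mean=120, gene_len_sd=40, seed=7)
    return simulate_pair(p)


@pytest.fixture(scope="session")
def fitted_small(small_pair):
    A, B, truth = small_pair
    res = GenomeComparison(A, B).fit()
    return A, B, truth, res


@pytest.fixture()
def toy_gff3(tmp_path):
    """One CDS at 1..9 (+) over ATGAAATAG."""
    text = (
        "##gff-version 3\n"
        "##sequence-region chr1 1 12\n"
        "chr1\ttest\tCDS\t1\t9\t.\t+\t0\tID=g1;locus_tag=g1;product=toy\n"
        "##FASTA\n"
        ">chr1\n"
        "ATGAAATAGCCC\n"
    )
    path = tmp_path / "toy.gff3"
    path.write_text(text)
    return path
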