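import numpy as np
import pandas as pd
import pytest

from sigsubtype.signature_space import build_cs_matrix, filter_signatures
from sigsubtype.synthetic_cohort import (
    SimulationConfig,
    make_synthetic_signatures,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def signatures():
    """A 12-signature synthetic reference set shared across tests."""
    return make_synthetic_signatures(seed=42)


@pytest.fixture(scope="session")
def small_cohort(signatures):
    """100-sample default-preset cohort with ground truth."""
    return simulate_cohort(SimulationConfig(n_samples=100, seed=7), signatures=signatures)


@pytest.fixture(scope="session")
def small_cs(small_cohort, signatures):
    return build_cs_matrix(small_cohort.spectra, signatures)


@pytest.fixture(scope="session")
def small_retained(small_cs):
    return filter_signatures(small_cs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_maf(tmp_path):
    """5-row MAF: 4 valid SNVs (one purine-referenced) and 1 insertion."""
    rows = [
        ("T1", "1", 100, "C", "T", "ACA"),
        ("T1", "1", 200, "G", "A", "TGT"),
        ("T1", "2", 300, "T", "G", "CTG"),
        ("T2", "3", 400, "C", "A", "GCC"),
        ("T2", "3", 500, "C", "CT", "ACG"),  # insertion -> skipped
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "Tumor_Sample_Barcode",
            "Chromosome",
            "Start_Position",
            "Reference_Allele",
            "Tumor_Seq_Allele2",
            "ref_context",
        ],
    )
    path = tmp_path / "toy.maf.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path
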