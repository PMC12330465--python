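import numpy as np
import pandas as pd
import pytest

from immunoruler.io_formats import PrecursorTable, SampleSheet


@pytest.fixture
def sheet2x2() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "condition": ["ctrl", "ctrl", "treat", "treat"],
                "replicate": [1, 2, 1, 2],
            }
        )
    )


def make_precursor_table(rows, samples):
    """Build a PrecursorTable from (id, seq, modseq, charge, pg, gene, q,
    intensity-per-sample...) tuples."""
    meta_cols = list(PrecursorTable.META_COLUMNS)
    df = pd.DataFrame(rows, columns=meta_cols + samples)
    for s in samples:
        df[s] = df[s].astype(float)
    return PrecursorTable(df, samples)


@pytest.fixture
def tiny_precursors():
    """Two peptides; ALDKVEASL has two charge variants, one partly missing."""
    samples = ["s1", "s2"]
    rows = [
        ("p1", "ALDKVEASL", "ALDKVEASL", 1, "PG1", "TPP1", 0.001, 100.0, np.nan),
        ("p2", "ALDKVEASL", "ALDKVEASL", 2, "PG1", "TPP1", 0.001, 50.0, np.nan),
        ("p3", "KTWGQYWQV", "KTWGQYWQV", 2, "PG2", "PMEL", 0.001, 7.5, 30.0),
    ]
    return make_precursor_table(rows, samples)


@pytest.fixture(scope="session")
def small_dataset():
    """Session-wide noisy simulated dataset with its analysis result."""
    from immunoruler.pipeline import analyze_tables
    from immunoruler.simulate import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(
        n_samples=10, n_proteins=200, n_antigens=120, frac_histone=0.05, seed=123
    )
    truth, immuno, proteome = simulate_dataset(cfg)
    result = analyze_tables(immuno, proteome, truth.proteome.records)
    return truth, immuno, proteome, result
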