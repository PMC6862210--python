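import numpy as np
import pytest

from srnzyme.descriptors import descriptor_table
from srnzyme.multitask import compute_class_profiles, make_pairs
from srnzyme.seqio import ProteinSequence
from srnzyme.synthetic import SynthSpec, generate


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing raw FASTA text to a temporary file."""

    def _write(text: str, name: str = "input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture(scope="session")
def small_dataset():
    """A small strongly-separated synthetic dataset shared across tests."""
    spec = SynthSpec(
        n_classes=3,
        sequences_per_class=12,
        n_nonenzymes=20,
        length_range=(150, 250),
        seed=11,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    """Descriptors, profiles and default pair records for the small dataset."""
    seqs, anns = small_dataset
    table = descriptor_table(seqs)
    profiles = compute_class_profiles(table, anns)
    pairs = make_pairs(table, anns, profiles, seed=11)
    return {"table": table, "profiles": profiles, "pairs": pairs, "annotations": anns}


@pytest.fixture
def peptide():
    def _make(residues: str, sid: str = "pep"):
        return ProteinSequence(id=sid, residues=residues)

    return _make


@pytest.fixture(scope="session")
def gaussian_pairs():
    """Synthetic pair records separated only along DTr3 (±2 vs ±1 SD)."""
    rng = np.random.default_rng(42)
    n = 200
    import pandas as pd

    def cloud(label, dtr3_mean):
        return pd.DataFrame(
            {
                "sequence_id": [f"{label}_{i}" for i in range(n)],
                "class_id": "1.1",
                "Tr3_mean": rng.normal(0, 1, n),
                "Tr5_mean": rng.normal(0, 1, n),
                "DTr3": rng.normal(dtr3_mean, 1, n),
                "DTr5": rng.normal(0, 1, n),
                "label": label,
            }
        )

    return pd.concat([cloud(1, 2.0), cloud(-1, -2.0)], ignore_index=True)
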