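import pandas as pd
import pytest

from mixochain.community import AsvMatrix
from mixochain.stoichiometry import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def small_matrix():
    """Three samples × four ASVs with taxonomy and sequences."""
    counts = pd.DataFrame(
        [[50, 30, 15, 5], [40, 40, 10, 10], [60, 20, 10, 10]],
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        columns=["asv1", "asv2", "asv3", "asv4"],
    )
    meta = pd.DataFrame(
        {"reactor_id": ["R1", "R1", "R1"], "time_d": [1.0, 2.0, 3.0]},
        index=counts.index,
    )
    base = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
    seqs = {
        "asv1": base,
        "asv2": base[:-1] + "C",               # 1 mismatch to asv1
        "asv3": "TGCA" * 10,                   # unrelated
        "asv4": base[:20] + "T" + base[21:],   # 1 mismatch to asv1
    }
    taxonomy = {
        "asv1": ("Bacteria", "Bacillota", "Clostridia", "Eubacteriales", "f", "Clostridium", "sp1"),
        "asv2": ("Bacteria", "Bacillota", "Clostridia", "Eubacteriales", "f", "Clostridium", "sp2"),
        "asv3": ("Bacteria", "Bacillota", "Clostridia", "Eubacteriales", "f", "Eubacterium", "sp3"),
        "asv4": ("Bacteria", "Bacillota", "Clostridia", "Eubacteriales", "f", "Clostridium", "sp1"),
    }
    return AsvMatrix(counts=counts, sample_meta=meta, taxonomy=taxonomy, sequences=seqs)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Shared noiseless default simulation (seed 3)."""
    from mixochain.synthetic import default_config, simulate

    return simulate(default_config(seed=3))
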