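import numpy as np
import pytest

from repeatfp.mapping import ReferenceContig
from repeatfp.records import ReadRecord
from repeatfp.synthetic import FamilySpec, LibraryProfile, build_reference, simulate_reads


def make_read(seq: str, qual: int = 35, read_id: str = "r", mate: int = 0) -> ReadRecord:
    return ReadRecord(read_id, seq, np.full(len(seq), qual, dtype=np.uint8), mate)


@pytest.fixture(scope="session")
def small_build():
    """Small two-family genome with UCOS genes, shared across tests."""
    specs = [
        FamilySpec("FAM1", "I", "LTR/Gypsy", 2000, 10, 0.03),
        FamilySpec("FAM2", "II", "DNA/hAT", 1500, 6, 0.01),
    ]
    return build_reference(specs, n_ucos=5, ucos_length=1000, background_length=60_000, seed=42)


@pytest.fixture(scope="session")
def small_reads(small_build):
    profile = LibraryProfile(read_length=60, mean_depth=6.0, base_error_rate=0.002, seed=7, library_id="lib1")
    return simulate_reads(small_build.genome, profile)


@pytest.fixture()
def toy_contig():
    return ReferenceContig("toy", "ACGTACGTAAACCCGGGTTTACGTACGT", "other")
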