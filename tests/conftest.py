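import numpy as np
import pytest

from ampnet.ingest import PropensityIndex, ProteinRecord, default_index


@pytest.fixture
def index() -> PropensityIndex:
    return default_index()


@pytest.fixture
def flat_index():
    """Index scoring every residue the same value, for analytic scan cases."""

    def make(value: float, **kwargs) -> PropensityIndex:
        from ampnet.ingest import AMINO_ACIDS

        return PropensityIndex(scores={a: value for a in AMINO_ACIDS}, **kwargs)

    return make


@pytest.fixture
def record_factory():
    def make(sequence: str, accession: str = "P1", taxon: str = "TaxA",
             curated: bool = True) -> ProteinRecord:
        return ProteinRecord(
            accession=accession, taxon_id=taxon, description=accession,
            sequence=sequence, curated=curated,
        )

    return make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
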