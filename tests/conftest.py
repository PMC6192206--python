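import numpy as np
import pytest

from triscore import RunConfig, pipeline, synthio
from triscore.seqdb import ProteinEntry


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small synthetic FASTA+MGF pair with truth labels, searched once and
    shared across tests (120 spectra keeps the whole suite fast)."""
    out = tmp_path_factory.mktemp("smalldata")
    cfg = synthio.SyntheticConfig(n_proteins=120, n_spectra=150, seed=7)
    fasta, mgf, truth = synthio.generate_dataset(cfg, out)
    return cfg, fasta, mgf, truth


@pytest.fixture(scope="session")
def searched(small_dataset):
    cfg, fasta, mgf, truth = small_dataset
    rc = RunConfig()
    by_scan, entries, index = pipeline.run_search(fasta, mgf, rc)
    return rc, by_scan, entries, index, truth


@pytest.fixture(scope="session")
def filtered(searched):
    rc, by_scan, entries, index, truth = searched
    fo = pipeline.run_filter(by_scan, pipeline.decoy_ids_from_entries(entries), rc)
    return rc, fo, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_protein(identifier: str, sequence: str, **kw) -> ProteinEntry:
    return ProteinEntry(identifier=identifier, description="", sequence=sequence, **kw)
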