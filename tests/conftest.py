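import pytest

from nacortho.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated family under the standard recovery conditions."""
    return simulate(SimConfig(seed=5))


@pytest.fixture(scope="session")
def toy8_dataset():
    """Eight sequences (two per species) from two ancestral genes, no
    duplications or losses: exhaustively checkable by hand."""
    cfg = SimConfig(n_ancestral_genes=2, wgd_events={}, loss_prob=0.0,
                    tandem_rate=0.0, seed=17)
    ds = simulate(cfg)
    assert len(ds.all_seqs) == 8
    return ds


@pytest.fixture(scope="session")
def table1():
    from nacortho.io_formats import read_table1_fixture

    return read_table1_fixture()
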