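import numpy as np
import pytest

import nanobrdu as nb


@pytest.fixture(scope="session")
def pore_model():
    return nb.build_pore_model(seed=1, shift_magnitude=1.5)


@pytest.fixture(scope="session")
def null_pore_model():
    return nb.build_pore_model(seed=1, shift_magnitude=0.0)


@pytest.fixture(scope="session")
def small_events(pore_model):
    """A compact mixed event table: 20 reads x 120 events, 50% substitution."""
    cfg = nb.SimConfig(n_reads=20, read_length=120, substitution_rate=0.5, seed=42)
    return nb.simulate_reads(pore_model, cfg)


@pytest.fixture(scope="session")
def small_windows(small_events):
    return nb.extract_windows(small_events, mode="all")


@pytest.fixture(scope="session")
def tiny_trained_model(pore_model):
    """A deliberately small trained classifier for plumbing tests."""
    cfg = nb.SimConfig(n_reads=30, read_length=80, substitution_rate=0.5, seed=7)
    events = nb.simulate_reads(pore_model, cfg)
    ws = nb.extract_windows(events, mode="t")
    tr, va, _ = nb.split_dataset(ws, nb.SplitSpec(shuffle_seed=0))
    mc = nb.ModelConfig(
        n_layers=2, units_per_direction=8, max_epochs=2, early_stop_patience=2, train_seed=0
    )
    return nb.train(tr, va, mc)
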