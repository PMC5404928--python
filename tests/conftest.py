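import pytest

from retromzt import simulate as sim


@pytest.fixture(scope="session")
def small_sim():
    """One small end-to-end synthetic dataset shared across tests."""
    cfg = sim.SimulationConfig(seed=11, mean_library_size=1500,
                               samples_per_group=2)
    sequences, ann, truth, counts, alns = sim.simulate_all(cfg)
    return {"config": cfg, "sequences": sequences, "ann": ann,
            "truth": truth, "counts": counts, "alns": alns}
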