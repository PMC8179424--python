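import numpy as np
import pytest

import fretdyn as fd


@pytest.fixture(scope="session")
def clean_single_state_stream():
    """Single state at mu_R = R0: crosstalk-free, background-free, so every
    donor-excitation photon is a fair coin between DD and DA."""
    scheme = fd.KineticScheme(["s"], [65.0], [0.0], np.array([[0.0]]))
    cfg = fd.SimConfig(duration=40.0, seed=7, alpha=0.0, delta=0.0,
                       background_rates={"DD": 0.0, "DA": 0.0, "AA": 0.0})
    return fd.simulate_photon_stream(scheme, cfg), cfg


@pytest.fixture(scope="session")
def three_state_burst_table():
    """Quasi-static three-state stream with the well-resolved populations,
    processed into a burst table (shared across PDA tests)."""
    from fretdyn.workflows import STATE_MU_R, STATE_SIGMA_R, condition_weights

    scheme = fd.three_state_scheme(condition_weights(1.61, 0.20),
                                   STATE_MU_R, STATE_SIGMA_R, relax_rate=1.0)
    cfg = fd.SimConfig(duration=700.0, seed=13, burst_rate=2.5, delta=0.0)
    stream = fd.simulate_photon_stream(scheme, cfg)
    cf = fd.CorrectionFactors(alpha=cfg.alpha, delta=0.0,
                              bg_rates=cfg.background_rates)
    df = fd.process_bursts(stream, cf, m=20, estimate_lifetimes=False)
    return df[df["species"] == "mid"], cfg


@pytest.fixture(scope="session")
def toy_dimers():
    a = fd.make_toy_dimer(8, "closedA", seed=3)
    b = fd.make_toy_dimer(8, "closedB", seed=3)
    return a, b
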