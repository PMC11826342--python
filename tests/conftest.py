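import numpy as np
import pytest

import calumen as cm


@pytest.fixture(scope="session")
def hek_cohort():
    """Seeded 40-cell wild-type HEK cohort (depletion-refill protocol)."""
    return cm.simulate_cohort(cm.default_config("hek", "WT"), 40, seed=1)


@pytest.fixture(scope="session")
def hek_report(hek_cohort):
    return cm.run_pipeline(
        [r.trace for r in hek_cohort], cm.RunConfig(profile="hek", seed=1)
    )


@pytest.fixture(scope="session")
def myocyte_cohort():
    """Seeded 11-cell wild-type myocyte cohort with calsequestrin buffering."""
    return cm.simulate_cohort(cm.default_config("myocyte", "WT"), 11, seed=1)


@pytest.fixture(scope="session")
def myocyte_report(myocyte_cohort):
    return cm.run_pipeline(
        [r.trace for r in myocyte_cohort], cm.RunConfig(profile="myocyte", seed=1)
    )


def exponential_refill_trace(
    c_max_mm=0.8, k=0.2, dt=0.02, caffeine_end=5.0, total_s=65.0
):
    """Noiseless calibrated trace refilling as c(t) = C_max(1 - e^(-k t))."""
    time = np.arange(0.0, total_s, dt)
    t_rel = np.maximum(time - caffeine_end, 0.0)
    ca_free = 1000.0 * c_max_mm * (1.0 - np.exp(-k * t_rel))
    epochs = [
        cm.ProtocolEvent("caffeine", 0.0, caffeine_end),
        cm.ProtocolEvent("ruthenium_red", caffeine_end, total_s),
    ]
    return cm.CaTrace(time=time, ca_free=ca_free, epochs=epochs, cell_id="exp")
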