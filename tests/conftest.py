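import numpy as np
import pandas as pd
import pytest

from pupilmath import synthgen as sg


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny full cohort with raw traces, shared across trace-level tests."""
    cfg = sg.CohortConfig(n_participants=3, seed=11)
    return sg.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def profiles_5000():
    """A large trait-only cohort for correlation-recovery checks."""
    cfg = sg.CohortConfig(n_participants=5000, seed=7)
    return sg.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def feature_table_70():
    """A 70-participant feature table with realistic correlation structure,
    built from the trait generator (no traces needed)."""
    cfg = sg.CohortConfig(n_participants=70, seed=23)
    profs = sg.simulate_cohort(cfg)
    tab = sg.cohort_table(profs)
    rng = np.random.default_rng(23)
    return pd.DataFrame(
        {
            "participant": tab["participant"],
            "amas": tab["amas"].astype(float),
            "tai": tab["tai"].astype(float),
            "stai": tab["stai"].astype(float),
            "pmp": tab["pmp"].astype(float),
            "accuracy": tab["accuracy_trait"],
            "baseline_ps": tab["tonic_baseline_au"],
            "max_dilation": 2.4 + 0.5 * rng.standard_normal(len(tab)),
            "peak_latency": (tab["easy_latency_s"] + tab["hard_latency_s"]) / 2,
        }
    )
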