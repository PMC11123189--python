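import numpy as np
import pandas as pd
import pytest

import soilroot as sr


@pytest.fixture(scope="session")
def tiny_counts() -> sr.CountMatrix:
    """Hand-sized table: 4 samples x 5 OTUs."""
    data = pd.DataFrame(
        [[5, 0, 3, 1, 1], [4, 1, 2, 2, 1], [0, 6, 1, 2, 1], [1, 5, 0, 3, 1]],
        index=["s1", "s2", "s3", "s4"],
        columns=[f"otu{i}" for i in range(1, 6)],
    )
    return sr.CountMatrix(data)


@pytest.fixture(scope="session")
def gradient_data():
    """Moderate-size compartment gradient with truth labels (shared, read-only)."""
    meta = sr.simulate_metacommunity(sr.MetacommunityConfig(n_otus=600, seed=11))
    cm, md, truth = sr.simulate_compartment_gradient(
        meta, sr.GradientConfig(seed=11), depth=20_000, n_reps=6
    )
    return cm, md, truth


@pytest.fixture(scope="session")
def gradient_ra(gradient_data):
    cm, md, truth = gradient_data
    return sr.relative_abundance(cm), md, truth


@pytest.fixture(scope="session")
def neutral_fit():
    """One forward neutral simulation and its NCM fit (m=0.1, N=1000, M=50)."""
    meta = sr.simulate_metacommunity(sr.MetacommunityConfig(n_otus=500, seed=1))
    cm = sr.simulate_neutral_assembly(
        sr.NeutralAssemblyConfig(m=0.1, N=1000, M=50, seed=3), meta
    )
    return cm, sr.fit_ncm(cm)
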