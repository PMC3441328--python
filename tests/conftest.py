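import numpy as np
import pytest

from rxdiffusion.datasets import load_adoption_table
from rxdiffusion.pipeline import fit_cohort
from rxdiffusion.simulate import SimulationConfig, simulate_cohort, truth_frame


@pytest.fixture(scope="session")
def adoption_table():
    return load_adoption_table()


@pytest.fixture(scope="session")
def default_cohort_fit():
    """Full pipeline run on the default simulated cohort, joined to truth.

    Shared by the end-to-end recovery and classification-agreement tests;
    a single fixed-seed realisation of the study-scale cohort.
    """
    series, truths = simulate_cohort(SimulationConfig(seed=20120810))
    results, exclusions = fit_cohort(series)
    merged = results.merge(truth_frame(truths), on="drug_id", suffixes=("_est", "_true"))
    return merged, exclusions
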