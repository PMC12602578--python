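import numpy as np
import pandas as pd
import pytest

from tlradiomics import FeatureTable, SimulationDesign, simulate_cohort


def make_table(values, batch=None, outcome=None, modality=None, is_shape=None,
               **extra_meta):
    """Small FeatureTable builder for unit tests."""
    values = pd.DataFrame(values)
    if not isinstance(values.index, pd.Index) or values.index.dtype == np.int64:
        values.index = pd.Index([f"s{i}" for i in range(len(values))],
                                name="sample_id")
    values.columns = [str(c) for c in values.columns]
    n, p = values.shape
    meta = {"batch": batch if batch is not None else ["b1"] * n}
    if outcome is not None:
        meta["outcome"] = outcome
    meta.update(extra_meta)
    sample_meta = pd.DataFrame(meta, index=values.index)
    feature_meta = pd.DataFrame({
        "modality": modality if modality is not None else ["CT"] * p,
        "is_shape": is_shape if is_shape is not None else [0] * p,
    }, index=values.columns)
    return FeatureTable(values, sample_meta, feature_meta)


@pytest.fixture(scope="session")
def default_cohort():
    """The generator's default three-scanner cohort (seed 7)."""
    return simulate_cohort(SimulationDesign())


@pytest.fixture(scope="session")
def noiseless_uptake_cohort():
    """Uptake nuisance on, every other noise source off: the setting in
    which tumor-to-liver ratios must cancel the uptake factor exactly."""
    design = SimulationDesign(noise_sd=0.0, uptake_sd=0.5, batch_shift_sd=0.3,
                              batch_scale_sd=0.05, seed=3)
    return simulate_cohort(design)
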