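import warnings

import numpy as np
import pytest

from ioncoloc.peakflow import preprocess_runs
from ioncoloc.synthio import SynthConfig, generate_biclonal_runs

# the statistical fits legitimately warn on saturated toy designs
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def small_cfg():
    """A compact dataset: full layout, reduced grid, quick to preprocess."""
    return SynthConfig(grid_w=32, grid_h=32, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    runs, truth = generate_biclonal_runs(small_cfg)
    return runs, truth


@pytest.fixture(scope="session")
def small_feature_table(small_dataset):
    runs, truth = small_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ft = preprocess_runs(runs)
    return ft, truth
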