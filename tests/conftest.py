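import numpy as np
import pytest
from hypothesis import settings

import isobeak as ib

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Two small populations, one per species, with ground truth."""
    pops = [
        ib.PopulationParams(species="G_fabricii", time_series="1970s",
                            year=1977, n_individuals=5,
                            n_subsections_range=(8, 12)),
        ib.PopulationParams(species="G_fabricii", time_series="2010s",
                            year=2014, n_individuals=5,
                            n_subsections_range=(8, 12)),
    ]
    return ib.generate_scenario(pops, seed=7)


@pytest.fixture(scope="session")
def small_corrected(small_dataset):
    """Corrected table for the small dataset."""
    import pandas as pd

    from isobeak.io import (corrected_frame, specimens_from_frame,
                            subsections_from_frame)

    frames = []
    for sp in specimens_from_frame(small_dataset.beaks):
        subs = subsections_from_frame(small_dataset.subsections,
                                      sp.individual_id)
        frames.append(corrected_frame(ib.correct_profile(sp, subs), sp))
    return pd.concat(frames, ignore_index=True)
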