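import numpy as np
import pytest

from tmascore.study import DEFAULT_SCORE_GRID
from tmascore.synthetic import generate_spot, study_scale_config


@pytest.fixture(scope="session")
def small_spot():
    """One 600 px synthetic spot (50% positive, intensity 2) with ground truth."""
    config = study_scale_config(seed=7)
    image, truth = generate_spot(config)
    return config, image, truth


@pytest.fixture(scope="session")
def cohort():
    """24 synthetic spots (3 passes over the programmed score grid).

    Shared by the scoring round-trip and segmentation recovery checks; the
    grid spans percent positive {0, 0.5, 5, 10, 25, 50, 70, 90} and
    intensity bins 0-3.
    """
    spots = []
    for i in range(24):
        pct, ibin = DEFAULT_SCORE_GRID[i % len(DEFAULT_SCORE_GRID)]
        config = study_scale_config(
            seed=5000 + i,
            programmed_percent_positive=pct,
            programmed_intensity_bin=ibin,
        )
        image, truth = generate_spot(config)
        spots.append((config, image, truth))
    return spots
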