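import numpy as np
import pytest

import idiobias as ib


@pytest.fixture(scope="session")
def continuum147():
    return ib.build_continuum(3, 48)


@pytest.fixture(scope="session")
def small_matching_cohort():
    """A compact matching cohort (4+3 observers) for pipeline-level tests."""
    cfg = ib.MatchingCohortConfig(
        n_radiologists=4, n_untrained=3, n_trials=200, lapse_rate=0.0
    )
    return ib.generate_matching_cohort(cfg, seed=20240901)


@pytest.fixture(scope="session")
def small_rating_cohort():
    """A compact rating cohort (4+3 observers, 60 images, 20 repeats)."""
    cfg = ib.RatingCohortConfig(
        n_radiologists=4, n_untrained=3, n_images=60, n_repeats=20
    )
    return ib.generate_rating_cohort(cfg, seed=20240902)
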