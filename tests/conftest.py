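import numpy as np
import pytest

from cnclonality import (Arm, GenomeLayout, MarkerTrack, SampleProfile,
                         SimConfig, make_track)


@pytest.fixture(scope="session")
def default_layout():
    return GenomeLayout.default()


@pytest.fixture(scope="session")
def small_layout():
    """Three arms on two chromosomes, small enough for brute-force oracles."""
    return GenomeLayout([
        Arm("chr1", "p", 1, 1_000_000),
        Arm("chr1", "q", 1_200_001, 3_000_000),
        Arm("chr2", "q", 1, 2_000_000),
    ])


@pytest.fixture
def small_track(small_layout):
    """60 evenly spaced markers over the three small arms."""
    cfg = SimConfig(layout=small_layout, n_markers=60)
    return make_track(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_profile(values, sample="S1", patient="P1", lesion="LCIS"):
    return SampleProfile(sample, patient, lesion, np.asarray(values, float))


@pytest.fixture
def make_profile_fn():
    return make_profile
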