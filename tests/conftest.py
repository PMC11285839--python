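import numpy as np
import pandas as pd
import pytest

from straitcross import gen_cohort, gen_coastlines
from straitcross.synthetic import BirdSpec, WindEpisode, WindScript


@pytest.fixture(scope="session")
def coasts():
    """Stylised strait geometry: (spain, morocco, geofence)."""
    return gen_coastlines()


@pytest.fixture(scope="session")
def levanter_script():
    """One steady easterly episode, the drift-experiment wind condition."""
    return WindScript(episodes=[WindEpisode(0, 1, "east", 10.0, 15.0)], n_days=1)


@pytest.fixture(scope="session")
def small_bundle(levanter_script):
    """Six adult birds (γ = 0.5) under a Levanter; in-memory input bundle."""
    spec = {"adult": BirdSpec(age_class="adult", compensation=0.5)}
    return gen_cohort(
        0, 6, spec_by_age=spec, script=levanter_script, seed=5, start_window_days=(0.05, 0.6)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def frame_from_bundle(bundle, config=None):
    """Run the in-memory ingest + kinematics pipeline on a generated bundle."""
    from straitcross import build_frame

    fixes = bundle["fixes"][["bird_id", "t", "lon", "lat"]].copy()
    fixes["age_class"] = fixes["bird_id"].map(bundle["ages"])
    return build_frame(
        fixes, bundle["wind"], bundle["spain"], bundle["morocco"], bundle["geofence"], config
    )
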