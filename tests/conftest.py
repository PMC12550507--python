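import numpy as np
import pandas as pd
import pytest
from hypothesis import settings
from shapely.geometry import box

from ecometrica import summarize_traits_by_point
from ecometrica.synthetic import WorldConfig, generate_fossils, generate_world

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_points(coords, env=None, env_col="env"):
    """Points DataFrame from [(lon, lat), ...] with optional env values."""
    df = pd.DataFrame(
        {
            "point_id": [f"p{k}" for k in range(len(coords))],
            "lon": [c[0] for c in coords],
            "lat": [c[1] for c in coords],
        }
    )
    if env is not None:
        df[env_col] = env
    return df


def make_ranges(boxes, species=None):
    """Ranges DataFrame from [(minx, miny, maxx, maxy), ...]."""
    species = species or [f"sp{k}" for k in range(len(boxes))]
    return pd.DataFrame({"species": species, "geometry": [box(*b) for b in boxes]})


def make_traits(species, traits):
    return pd.DataFrame({"species": species, "trait": traits})


@pytest.fixture
def tiny_overlap():
    """Three overlapping unit squares all containing (0.5, 0.5), traits 1,2,3."""
    ranges = make_ranges(
        [(0, 0, 1, 1), (0.2, 0.2, 1.2, 1.2), (-0.2, -0.2, 1.0, 1.0)],
        species=["a", "b", "c"],
    )
    traits = make_traits(["a", "b", "c"], [1.0, 2.0, 3.0])
    return ranges, traits


# --- seeded synthetic worlds shared across tests (session-scoped: the fit is
# deterministic, so sharing cannot leak state between tests) -----------------


@pytest.fixture(scope="session")
def qual_world():
    cfg = WorldConfig()  # defaults: 2000 points, 4 bands, rho=0.95, seed 0
    ranges, traits, points = generate_world(cfg)
    summaries = summarize_traits_by_point(points, traits, ranges)
    fossils = generate_fossils(cfg, ranges, traits, points, summaries=summaries)
    return cfg, ranges, traits, points, summaries, fossils


@pytest.fixture(scope="session")
def cont_world():
    cfg = WorldConfig(env_kind="continuous")
    ranges, traits, points = generate_world(cfg)
    summaries = summarize_traits_by_point(points, traits, ranges)
    return cfg, ranges, traits, points, summaries


@pytest.fixture(scope="session")
def small_qual_summaries():
    """A quick 400-point categorical world for unit-scale model tests."""
    cfg = WorldConfig(n_points=400, seed=5)
    ranges, traits, points = generate_world(cfg)
    return summarize_traits_by_point(points, traits, ranges)
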