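"""Synthetic worlds for testing and demonstration.

The generator builds a self-contained study system: a rectangular lon/lat
domain with an environmental gradient running along longitude (a smooth
linear gradient, or K equal-width longitudinal bands for categorical
environments), a pool of species with random box or ellipse ranges, a
species-level trait coupled to the environment at the range centroid, a set
of sampling points with the environment evaluated at each point, and fossil
sites whose trait summaries are borrowed (plus noise) from nearby sampling
points, with the true environment recorded for recovery experiments.

The coupling strength rho controls how much of the trait is environmental
signal versus species-level noise: trait = rho * e + (1 - rho) * eps, where
e is the scaled (0-1) environment at the range centroid and eps is Gaussian.
At rho near 1 community trait summaries track the gradient closely, so
models fitted to the synthetic world should recover the environment well;
at rho = 0 the trait carries no signal.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import affinity
from shapely.geometry import Point, box

from .errors import ValidationError
from .summarize import summarize_traits_by_point

#: band labels for categorical environments (extended as class_<k> beyond 5)
VEGETATION_LABELS = ["arctic", "deciduous", "desert", "evergreen", "grassland"]


@dataclass
class WorldConfig:
    """Parameters of a synthetic world.

    Defaults describe a continental-scale study: 80 species over a 60 x 20
    degree domain, ranges spanning 6-16 degrees, 2000 sampling points, strong
    trait-environment coupling (rho = 0.95), and 15 fossil sites with small
    measurement noise on their community summaries.
    """

    n_species: int = 80
    n_points: int = 2000
    n_fossils: int = 15
    lon_min: float = -30.0
    lon_max: float = 30.0
    lat_min: float = -10.0
    lat_max: float = 10.0
    rho: float = 0.95
    env_kind: str = "categorical"  # "categorical" | "continuous"
    n_categories: int = 4
    env_col: str = "env"
    half_width_min: float = 3.0  # species range half-width, degrees
    half_width_max: float = 8.0
    noise_sd: float = 1.0  # SD of the species-level trait noise
    fossil_noise_sd: float = 0.01  # SD of noise added to fossil summaries
    fossil_jitter_deg: float = 0.2  # location jitter of fossils around source points
    continuous_scale: float = 30.0  # continuous env reported on [0, scale]
    seed: int = 0

    def __post_init__(self):
        if min(self.n_species, self.n_points, self.n_fossils) < 1:
            raise ValidationError("n_species, n_points and n_fossils must all be >= 1")
        if not 0.0 <= self.rho <= 1.0:
            raise ValidationError("coupling strength rho must lie in [0, 1]")
        if not (
            -180 <= self.lon_min < self.lon_max <= 180
            and -90 <= self.lat_min < self.lat_max <= 90
        ):
            raise ValidationError("domain box must be a valid lon/lat rectangle")
        if self.env_kind not in ("categorical", "continuous"):
            raise ValidationError(f"unknown env_kind {self.env_kind!r}")
        if self.env_kind == "categorical" and self.n_categories > self.n_points:
            raise ValidationError("more categories than sampling points is infeasible")

    def category_labels(self) -> list[str]:
        k = self.n_categories
        if k <= len(VEGETATION_LABELS):
            return VEGETATION_LABELS[:k]
        return VEGETATION_LABELS + [f"class_{i}" for i in range(len(VEGETATION_LABELS), k)]


def scaled_env(config: WorldConfig, lon) -> np.ndarray:
    """Scaled environment in [0, 1]: position along the longitudinal gradient."""
    e = (np.asarray(lon, dtype=float) - config.lon_min) / (config.lon_max - config.lon_min)
    return np.clip(e, 0.0, 1.0)


def env_at(config: WorldConfig, lon):
    """Environment value(s) at longitude(s): label for categorical worlds,
    a value on [0, continuous_scale] for continuous ones."""
    e = scaled_env(config, lon)
    if config.env_kind == "continuous":
        return e * config.continuous_scale
    labels = config.category_labels()
    idx = np.minimum((e * config.n_categories).astype(int), config.n_categories - 1)
    return np.asarray([labels[k] for k in np.atleast_1d(idx)], dtype=object)


def generate_world(config: WorldConfig):
    """Generate (ranges, traits, points) DataFrames from a seeded RNG.

    Ranges are random boxes or ellipses centred in the domain; each species'
    trait derives from the environment at its range centroid. Sampling points
    are uniform in the domain with the environment evaluated in place. For
    categorical worlds, point sampling is retried (bounded) until every label
    is represented.
    """
    rng = np.random.default_rng(config.seed)

    # species ranges and traits
    cx = rng.uniform(config.lon_min, config.lon_max, config.n_species)
    cy = rng.uniform(config.lat_min, config.lat_max, config.n_species)
    hwx = rng.uniform(config.half_width_min, config.half_width_max, config.n_species)
    hwy = rng.uniform(config.half_width_min, config.half_width_max, config.n_species)
    is_ellipse = rng.random(config.n_species) < 0.5
    geoms = []
    for k in range(config.n_species):
        if is_ellipse[k]:
            circ = Point(cx[k], cy[k]).buffer(1.0, quad_segs=16)
            geoms.append(affinity.scale(circ, xfact=hwx[k], yfact=hwy[k]))
        else:
            geoms.append(box(cx[k] - hwx[k], cy[k] - hwy[k], cx[k] + hwx[k], cy[k] + hwy[k]))
    species = [f"species_{k:03d}" for k in range(config.n_species)]
    ranges = pd.DataFrame({"species": species, "geometry": geoms})

    e_centroid = scaled_env(config, cx)
    noise = rng.normal(0.0, config.noise_sd, config.n_species)
    trait = config.rho * e_centroid + (1.0 - config.rho) * noise
    traits = pd.DataFrame({"species": species, "trait": trait})

    # sampling points; categorical worlds must show every label
    for attempt in range(20):
        px = rng.uniform(config.lon_min, config.lon_max, config.n_points)
        py = rng.uniform(config.lat_min, config.lat_max, config.n_points)
        env = env_at(config, px)
        if config.env_kind == "continuous" or (
            len(set(env)) == config.n_categories
        ):
            break
    else:
        raise ValidationError(
            "could not sample points covering all categories; "
            "increase n_points or decrease n_categories"
        )
    points = pd.DataFrame(
        {
            "point_id": [f"pt_{k:05d}" for k in range(config.n_points)],
            "lon": px,
            "lat": py,
            config.env_col: env,
        }
    )
    return ranges, traits, points


def generate_fossils(
    config: WorldConfig,
    ranges: pd.DataFrame,
    traits: pd.DataFrame,
    points: pd.DataFrame,
    summaries: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Generate fossil sites by perturbing summaries of source sampling points.

    Each fossil picks a random *valid* sampling point, sits at that location
    with a small jitter, and inherits the source community's (metric1,
    metric2) plus Gaussian noise of SD ``fossil_noise_sd``. The environment
    at the fossil's own location is recorded as ``true_env`` so recovery
    experiments can score reconstructions; ``source_point_id`` links back to
    the source community. With zero noise and zero jitter the fossil metrics
    equal the source point's exactly.
    """
    rng = np.random.default_rng(config.seed + 1)
    if summaries is None:
        summaries = summarize_traits_by_point(points, traits, ranges)
    valid = summaries[summaries["valid"] & summaries["metric2"].notna()].reset_index(drop=True)
    if len(valid) == 0:
        raise ValidationError("no valid sampling points to source fossil communities from")
    src = rng.choice(len(valid), size=config.n_fossils, replace=len(valid) < config.n_fossils)
    rows = []
    for k, s in enumerate(src):
        row = valid.iloc[int(s)]
        lon = float(row["lon"]) + rng.normal(0.0, config.fossil_jitter_deg)
        lat = float(row["lat"]) + rng.normal(0.0, config.fossil_jitter_deg)
        lon = float(np.clip(lon, config.lon_min, config.lon_max))
        lat = float(np.clip(lat, config.lat_min, config.lat_max))
        m1 = float(row["metric1"]) + rng.normal(0.0, config.fossil_noise_sd)
        m2 = float(row["metric2"]) + rng.normal(0.0, config.fossil_noise_sd)
        true_env = env_at(config, lon)
        rows.append(
            {
                "site_id": f"fossil_{k:03d}",
                "lon": lon,
                "lat": lat,
                "metric1": m1,
                "metric2": max(m2, 0.0),
                "true_env": true_env[0] if config.env_kind == "categorical" else float(true_env),
                "source_point_id": str(row["point_id"]),
            }
        )
    return pd.DataFrame(rows)
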