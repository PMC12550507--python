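"""Reading and validating the four tabular/geometric inputs, plus model archives.

Tables (sampling points, species traits, fossil sites) are CSV and come back as
pandas DataFrames with canonical column names. Species range polygons are read
from GeoJSON into shapely geometries. Fitted models round-trip through a
versioned JSON archive.
"""
from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
from shapely.geometry import shape, mapping
from shapely.geometry.base import BaseGeometry
from shapely import make_valid, union_all

from .errors import ArchiveError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

ARCHIVE_FORMAT_VERSION = 1

#: canonical column names per table schema; extra columns are carried through
#: (environmental variables on points, nothing on traits/fossil).
_SCHEMAS = {
    "points": ["point_id", "lon", "lat"],
    "traits": ["species", "trait"],
    "fossil": ["site_id", "lon", "lat", "metric1", "metric2"],
}


def normalize_species(name: str) -> str:
    """Normalize a species name: strip, collapse whitespace runs to single '_'.

    Idempotent: applying it twice gives the same result.
    """
    return "_".join(str(name).split())


def _check_coords(df: pd.DataFrame, what: str) -> None:
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad = ~(lon.between(-180, 180) & lat.between(-90, 90))
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad]]  # 1-based incl. header
        raise ValidationError(
            f"{what}: invalid or out-of-range coordinates in file rows {rows} "
            "(lon must be in [-180, 180], lat in [-90, 90])"
        )
    df["lon"] = lon.astype(float)
    df["lat"] = lat.astype(float)


def read_tabular(path, schema: str, column_map: dict | None = None) -> pd.DataFrame:
    """Read one of the three CSV inputs and validate it.

    Parameters
    ----------
    path : file path to a CSV file.
    schema : one of ``"points"``, ``"traits"``, ``"fossil"``.
    column_map : optional mapping from canonical name (e.g. ``"lon"``) to the
        column name actually present in the file.

    Returns
    -------
    DataFrame with canonical columns first; any extra columns (environmental
    variables for points) are preserved.
    """
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    df = pd.read_csv(path)
    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items() if v in df.columns}
    df = df.rename(columns=rename)
    required = _SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing} for schema {schema!r}")

    if schema == "points":
        _check_coords(df, "points table")
        df["point_id"] = df["point_id"].astype(str)
        if df["point_id"].duplicated().any():
            dups = sorted(df.loc[df["point_id"].duplicated(), "point_id"].unique())
            raise ValidationError(f"points table: duplicate point_id values {dups}")
    elif schema == "traits":
        df["species"] = df["species"].map(normalize_species)
        if df["species"].duplicated().any():
            dups = sorted(df.loc[df["species"].duplicated(), "species"].unique())
            raise ValidationError(f"traits table: duplicate species {dups}")
        df["trait"] = pd.to_numeric(df["trait"], errors="coerce")
        if not np.isfinite(df["trait"]).all():
            rows = [int(i) + 2 for i in df.index[~np.isfinite(df["trait"])]]
            raise ValidationError(f"traits table: non-finite trait values in file rows {rows}")
    elif schema == "fossil":
        _check_coords(df, "fossil table")
        df["site_id"] = df["site_id"].astype(str)
        if df["site_id"].duplicated().any():
            dups = sorted(df.loc[df["site_id"].duplicated(), "site_id"].unique())
            raise ValidationError(f"fossil table: duplicate site_id values {dups}")
        for col in ("metric1", "metric2"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        m2 = df["metric2"].dropna()
        if (m2 < 0).any():
            raise ValidationError("fossil table: metric2 (community SD) must be >= 0")

    ordered = required + [c for c in df.columns if c not in required]
    return df[ordered]


def read_ranges(path, species_col: str = "species") -> pd.DataFrame:
    """Read species range polygons from a GeoJSON file.

    Each feature must carry the species name in ``species_col`` of its
    properties. Multiple features for the same species are unioned into a
    single (multi)polygon. Invalid geometries are repaired with
    ``make_valid``; species whose geometry cannot be repaired are dropped
    with a logged warning. Coordinates are assumed WGS84 lon/lat; a missing
    CRS declaration is accepted with a warning rather than an error.

    Returns a DataFrame with columns ``species`` (normalized) and
    ``geometry`` (shapely geometry).
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a GeoJSON FeatureCollection")
    if "crs" not in gj:
        logger.warning("%s declares no CRS; assuming WGS84 lon/lat", path)

    by_species: dict[str, list[BaseGeometry]] = {}
    for k, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        if species_col not in props:
            raise SchemaError(
                f"{path}: feature {k} lacks property {species_col!r} naming the species"
            )
        sp = normalize_species(props[species_col])
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            geom = make_valid(geom)
            if not geom.is_valid:
                logger.warning("dropping unrepairable geometry for species %s", sp)
                continue
        by_species.setdefault(sp, []).append(geom)

    records = [
        {"species": sp, "geometry": geoms[0] if len(geoms) == 1 else union_all(geoms)}
        for sp, geoms in by_species.items()
    ]
    if not records:
        raise ValidationError(f"{path}: no usable range polygons")
    return pd.DataFrame.from_records(records)


def write_ranges(ranges: pd.DataFrame, path, species_col: str = "species") -> None:
    """Write a ranges DataFrame back to GeoJSON (used by the simulator/CLI)."""
    features = [
        {
            "type": "Feature",
            "properties": {species_col: row.species},
            "geometry": mapping(row.geometry),
        }
        for row in ranges.itertuples()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# model archive


def _grid_to_json(grid) -> dict:
    return {
        "edges1": [float(v) for v in grid.edges1],
        "edges2": [float(v) for v in grid.edges2],
        "membership": {str(k): [int(v[0]), int(v[1])] for k, v in grid.membership.items()},
    }


def _grid_from_json(d):
    from .binning import TraitGrid

    return TraitGrid(
        edges1=np.asarray(d["edges1"], dtype=float),
        edges2=np.asarray(d["edges2"], dtype=float),
        membership={k: (int(i), int(j)) for k, (i, j) in d["membership"].items()},
    )


def save_model(model, path) -> None:
    """Serialize a fitted model to a single JSON archive.

    The archive is versioned and fully self-describing: loading it back
    reproduces every numeric field bit-identically (floats go through
    ``repr``-faithful JSON doubles).
    """
    from .models import CategoricalModel, ContinuousModel

    doc: dict = {"format_version": ARCHIVE_FORMAT_VERSION}
    if isinstance(model, CategoricalModel):
        doc["kind"] = "categorical"
        doc["categories"] = list(model.categories)
        doc["counts"] = model.counts.tolist()
        doc["env_col"] = model.env_col
    elif isinstance(model, ContinuousModel):
        doc["kind"] = "continuous"
        doc["env_edges"] = [float(v) for v in model.env_edges]
        doc["freq"] = model.freq.tolist()
        doc["env_col"] = model.env_col
    else:
        raise TypeError(f"cannot archive object of type {type(model).__name__}")
    doc["grid"] = _grid_to_json(model.grid)
    doc["training"] = {
        "point_id": [str(v) for v in model.training["point_id"]],
        "observed": [
            (v if isinstance(v, str) else float(v)) for v in model.training["observed"]
        ],
        "i": [int(v) for v in model.training["i"]],
        "j": [int(v) for v in model.training["j"]],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path):
    """Load a model archive written by :func:`save_model`."""
    from .models import categorical_from_counts, continuous_from_freq

    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ArchiveError(f"{path}: not a readable model archive ({exc})") from exc
    version = doc.get("format_version")
    if version != ARCHIVE_FORMAT_VERSION:
        raise ArchiveError(
            f"{path}: archive format version {version!r} not supported "
            f"(expected {ARCHIVE_FORMAT_VERSION})"
        )
    grid = _grid_from_json(doc["grid"])
    training = pd.DataFrame(doc["training"])
    kind = doc.get("kind")
    if kind == "categorical":
        return categorical_from_counts(
            grid=grid,
            categories=list(doc["categories"]),
            counts=np.asarray(doc["counts"], dtype=int),
            env_col=doc["env_col"],
            training=training,
        )
    if kind == "continuous":
        return continuous_from_freq(
            grid=grid,
            env_edges=np.asarray(doc["env_edges"], dtype=float),
            freq=np.asarray(doc["freq"], dtype=int),
            env_col=doc["env_col"],
            training=training,
        )
    raise ArchiveError(f"{path}: unknown model kind {kind!r}")
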