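"""Community trait summaries at geographic sampling points.

A community is the set of species whose range polygons contain a sampling
point (boundary-inclusive). Per point we record the species present, the
richness, the richness restricted to trait-bearing species, and two summary
metrics of the trait values of the trait-bearing species — by default the
sample mean and sample SD (n-1 denominator). Any function of a nonempty
numeric vector can be plugged in for either metric. A point is *valid* when
at least ``min_species_valid`` trait-bearing species are present (default 3);
only valid points enter downstream models.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_SPECIES_VALID = 3


def community_mean(x) -> float:
    """Default first summary metric: sample mean."""
    return float(np.mean(x))


def community_sd(x) -> float:
    """Default second summary metric: sample SD (n-1 denominator).

    Undefined (raises) for fewer than two values, mirroring the convention
    that a single-species community has no trait spread.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("sample SD undefined for fewer than 2 values")
    return float(np.std(x, ddof=1))


def _species_at_points(points: pd.DataFrame, ranges: pd.DataFrame) -> list[list[str]]:
    """Species whose polygon covers each point, via an STRtree prefilter.

    The spatial index is a performance device only: results are identical to
    a brute-force per-(point, polygon) containment scan (covers semantics,
    boundary-inclusive).
    """
    geoms = list(ranges["geometry"])
    species = list(ranges["species"])
    tree = STRtree(geoms)
    pts = [Point(lo, la) for lo, la in zip(points["lon"], points["lat"])]
    pt_idx, poly_idx = tree.query(pts, predicate="covered_by")
    present: list[list[str]] = [[] for _ in range(len(pts))]
    for a, b in zip(pt_idx, poly_idx):
        present[a].append(species[b])
    for lst in present:
        lst.sort()
    return present


def _apply_summary(fn, values, point_id, which):
    try:
        out = float(fn(values))
    except Exception as exc:  # noqa: BLE001 - user-supplied summary functions
        # routine for the default SD on single-species communities
        logger.debug("summary %s missing at point %s: %s", which, point_id, exc)
        return np.nan
    return out if np.isfinite(out) else np.nan


def summarize_traits_by_point(
    points: pd.DataFrame,
    traits: pd.DataFrame,
    ranges: pd.DataFrame,
    summary_fn_1=community_mean,
    summary_fn_2=community_sd,
    min_species_valid: int = DEFAULT_MIN_SPECIES_VALID,
) -> pd.DataFrame:
    """Summarize community trait distributions at each sampling point.

    Parameters
    ----------
    points : DataFrame with ``point_id``, ``lon``, ``lat`` plus any number of
        environmental columns, which are carried through unchanged.
    traits : DataFrame with ``species`` and ``trait``.
    ranges : DataFrame with ``species`` and shapely ``geometry``.
    summary_fn_1, summary_fn_2 : functions of a nonempty numeric vector.
        A summary that raises on some community is recorded as missing for
        that point and the run continues.
    min_species_valid : minimum number of trait-bearing species for a point's
        summaries to be flagged valid.

    Returns
    -------
    DataFrame with columns point_id, lon, lat, species_present (list),
    richness, richness_with_trait, metric1, metric2, valid, plus the
    carried-over environmental columns.
    """
    if len(points) == 0 or len(traits) == 0 or len(ranges) == 0:
        raise ValidationError("points, traits and ranges must each be non-empty")
    trait_of = dict(zip(traits["species"], traits["trait"].astype(float)))
    present = _species_at_points(points, ranges)

    rows = []
    for k, sp_list in enumerate(present):
        pid = str(points["point_id"].iloc[k])
        trait_vals = np.array([trait_of[s] for s in sp_list if s in trait_of])
        rwt = int(trait_vals.size)
        m1 = _apply_summary(summary_fn_1, trait_vals, pid, "metric1") if rwt else np.nan
        m2 = _apply_summary(summary_fn_2, trait_vals, pid, "metric2") if rwt else np.nan
        rows.append(
            {
                "point_id": pid,
                "lon": float(points["lon"].iloc[k]),
                "lat": float(points["lat"].iloc[k]),
                "species_present": sp_list,
                "richness": len(sp_list),
                "richness_with_trait": rwt,
                "metric1": m1,
                "metric2": m2,
                "valid": rwt >= min_species_valid,
            }
        )
    out = pd.DataFrame(rows)
    env_cols = [c for c in points.columns if c not in ("point_id", "lon", "lat")]
    for c in env_cols:
        out[c] = points[c].to_numpy()
    return out


def assign_regions(points: pd.DataFrame, regions: pd.DataFrame) -> pd.Series:
    """Label each point with the region polygon containing it.

    ``regions`` is a DataFrame with ``region`` (label) and ``geometry``
    columns. Points in no region get ``"unassigned"``; where regions overlap,
    the first-listed region wins (logged).
    """
    if len(regions) == 0:
        raise ValidationError("assign_regions requires at least one region polygon")
    geoms = list(regions["geometry"])
    labels = list(regions["region"])
    tree = STRtree(geoms)
    pts = [Point(lo, la) for lo, la in zip(points["lon"], points["lat"])]
    pt_idx, poly_idx = tree.query(pts, predicate="covered_by")
    best: dict[int, int] = {}
    multi = set()
    for a, b in zip(pt_idx, poly_idx):
        if a in best:
            multi.add(a)
            best[a] = min(best[a], b)  # first-listed region wins
        else:
            best[a] = b
    if multi:
        logger.warning(
            "%d point(s) fall in overlapping regions; first-listed region used", len(multi)
        )
    out = [labels[best[k]] if k in best else "unassigned" for k in range(len(pts))]
    return pd.Series(out, index=points.index, name="region")


def inspect_points(
    summaries: pd.DataFrame,
    point_ids: list[str] | None = None,
    n_random: int = 10,
    seed: int | None = None,
    min_species_valid: int = DEFAULT_MIN_SPECIES_VALID,
) -> list[dict]:
    """Build a per-point inspection report.

    With explicit ``point_ids`` the report covers exactly those points in the
    given order; otherwise ``n_random`` points are drawn with the seeded RNG.
    Each entry lists the point's metrics, richness values, environmental
    columns, species list and validity status against the threshold.
    """
    idx = summaries.set_index(summaries["point_id"].astype(str))
    if point_ids is not None:
        missing = [p for p in point_ids if str(p) not in idx.index]
        if missing:
            raise ValidationError(f"unknown point_id(s) in inspect request: {missing}")
        chosen = [str(p) for p in point_ids]
    else:
        rng = np.random.default_rng(seed)
        n = len(summaries)
        if n_random > n:
            logger.warning("n_random=%d exceeds %d available points; reporting all", n_random, n)
            n_random = n
        chosen = list(
            np.asarray(summaries["point_id"].astype(str))[
                rng.choice(n, size=n_random, replace=False)
            ]
        )
    core = {
        "point_id", "lon", "lat", "species_present", "richness",
        "richness_with_trait", "metric1", "metric2", "valid",
    }
    env_cols = [c for c in summaries.columns if c not in core]
    report = []
    for pid in chosen:
        row = idx.loc[pid]
        report.append(
            {
                "point_id": pid,
                "lon": float(row["lon"]),
                "lat": float(row["lat"]),
                "metric1": None if pd.isna(row["metric1"]) else float(row["metric1"]),
                "metric2": None if pd.isna(row["metric2"]) else float(row["metric2"]),
                "richness": int(row["richness"]),
                "richness_with_trait": int(row["richness_with_trait"]),
                "env": {c: row[c] for c in env_cols},
                "species": list(row["species_present"]),
                "valid": bool(row["richness_with_trait"] >= min_species_valid),
            }
        )
    return report


def format_report(report: list[dict]) -> str:
    """Render an inspection report as human-readable text."""
    lines = []
    for e in report:
        status = "valid" if e["valid"] else "NON-VALID"
        lines.append(
            f"point {e['point_id']} ({e['lon']:.3f}, {e['lat']:.3f}) [{status}]"
        )
        lines.append(
            f"  richness={e['richness']} with_trait={e['richness_with_trait']} "
            f"metric1={e['metric1']} metric2={e['metric2']}"
        )
        for k, v in e["env"].items():
            lines.append(f"  env {k} = {v}")
        lines.append(f"  species: {', '.join(e['species']) if e['species'] else '(none)'}")
    return "\n".join(lines)
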