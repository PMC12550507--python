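"""Palaeoenvironmental reconstruction from fossil community summaries.

Each fossil site's (metric1, metric2) pair is projected into the fitted
model's trait grid; the bin's prediction and probability vector become the
site's reconstruction. Fossil summaries outside the modern grid are clamped
to the nearest edge bin and flagged ``out_of_range``; fossils landing in an
empty bin borrow the nearest non-empty bin (Euclidean distance on bin-index
coordinates, ties towards smaller indices) and are flagged ``imputed_bin``.
Optionally each fossil is matched to its nearest modern sampling point by
great-circle distance.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .binning import assign_bin
from .errors import ValidationError
from .models import CategoricalModel, ContinuousModel

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between (lon1, lat1) and (lon2, lat2).

    Spherical haversine with mean Earth radius 6371.0088 km; broadcasting
    follows numpy rules.
    """
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def nearest_modern_analogue(
    fossil_lon: float, fossil_lat: float, modern_points: pd.DataFrame
) -> tuple[str, float]:
    """Nearest modern sampling point to a fossil location.

    Searches all modern points (valid or not); distance ties are broken by
    the lexicographically smallest point_id. Returns (point_id, distance_km).
    """
    if len(modern_points) == 0:
        raise ValidationError("nearest_modern_analogue requires at least one modern point")
    d = haversine_km(
        fossil_lon,
        fossil_lat,
        modern_points["lon"].to_numpy(dtype=float),
        modern_points["lat"].to_numpy(dtype=float),
    )
    ids = modern_points["point_id"].astype(str).to_numpy()
    dmin = d.min()
    tied = ids[d == dmin]
    return str(min(tied)), float(dmin)


def _nonempty_bins(model) -> list[tuple[int, int]]:
    if isinstance(model, CategoricalModel):
        occ = model.counts.sum(axis=2)
    else:
        occ = model.freq.sum(axis=2)
    return [(i, j) for i in range(occ.shape[0]) for j in range(occ.shape[1]) if occ[i, j] > 0]


def _nearest_nonempty(i: int, j: int, nonempty: list[tuple[int, int]]) -> tuple[int, int]:
    # ties -> smaller i, then smaller j (list is built in that order)
    return min(nonempty, key=lambda b: ((b[0] - i) ** 2 + (b[1] - j) ** 2, b[0], b[1]))


def _reconstruct(
    fossils: pd.DataFrame,
    model,
    prob_labels: list[str],
    prob_of_bin,
    pred_of_bin,
    match_nearest: bool,
    modern_points: pd.DataFrame | None,
) -> pd.DataFrame:
    nonempty = _nonempty_bins(model)
    if not nonempty:
        raise ValidationError("model has no non-empty bins; cannot reconstruct")
    if match_nearest and (modern_points is None or len(modern_points) == 0):
        raise ValidationError("match_nearest=True requires modern_points")

    rows = []
    for row in fossils.itertuples():
        m1, m2 = float(row.metric1), float(row.metric2)
        if not (np.isfinite(m1) and np.isfinite(m2)):
            raise ValidationError(f"fossil {row.site_id}: non-finite trait metrics")
        i, j, oor = assign_bin(model.grid, m1, m2, clamp=True)
        imputed = (i, j) not in set(nonempty)
        if imputed:
            i, j = _nearest_nonempty(i, j, nonempty)
        rec = {
            "site_id": str(row.site_id),
            "bin_i": i,
            "bin_j": j,
            "out_of_range": bool(oor),
            "imputed_bin": bool(imputed),
            "prediction": pred_of_bin(i, j),
        }
        for lab, p in zip(prob_labels, prob_of_bin(i, j)):
            rec[lab] = float(p)
        if match_nearest:
            pid, dist = nearest_modern_analogue(float(row.lon), float(row.lat), modern_points)
            rec["nearest_modern_id"] = pid
            rec["nearest_modern_distance_km"] = dist
            # the analogue's own trait bin, when it was a training point
            bin_ = model.grid.membership.get(pid)
            rec["analogue_bin_i"] = bin_[0] if bin_ else None
            rec["analogue_bin_j"] = bin_[1] if bin_ else None
        rows.append(rec)
    return pd.DataFrame(rows)


def reconstruct_env_qual(
    fossils: pd.DataFrame,
    model: CategoricalModel,
    match_nearest: bool = False,
    modern_points: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Reconstruct the most likely environmental category at each fossil site.

    Returns one row per fossil with the assigned bin, flags, the predicted
    category, per-category probability columns (``prob_<category>``), and —
    when ``match_nearest`` — the nearest modern analogue and its trait bin.
    """
    labels = [f"prob_{c}" for c in model.categories]
    return _reconstruct(
        fossils,
        model,
        labels,
        lambda i, j: model.prob[i, j],
        lambda i, j: model.predicted[i, j],
        match_nearest,
        modern_points,
    )


def reconstruct_env(
    fossils: pd.DataFrame,
    model: ContinuousModel,
    match_nearest: bool = False,
    modern_points: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Reconstruct a continuous environmental value at each fossil site.

    The prediction is the bin's maximum-likelihood estimate (midpoint of the
    modal environmental interval); probability columns give the bin's
    frequency distribution over the environmental intervals, labelled by
    interval midpoint.
    """
    mids = model.env_midpoints
    labels = [f"prob_env_{k}" for k in range(len(mids))]

    def prob_of_bin(i, j):
        f = model.freq[i, j].astype(float)
        return f / f.sum()

    return _reconstruct(
        fossils,
        model,
        labels,
        prob_of_bin,
        lambda i, j: float(model.predicted[i, j]),
        match_nearest,
        modern_points,
    )
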