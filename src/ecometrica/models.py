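"""Ecometric models: per-bin maximum-likelihood predictions over trait space.

Both model kinds tabulate the environmental variable of the valid training
points falling in each trait bin. The categorical model stores per-bin
category counts, normalized probabilities, and a modal prediction with a
deterministic two-stage tie rule (higher global category frequency, then
lexicographic order). The continuous model discretizes the environmental
variable into equal-width intervals and predicts the midpoint of the modal
interval per bin — the maximum-likelihood estimate under the discretized
distribution — plus the per-bin mean of raw values as a secondary summary.
Empty bins carry no prediction; nothing is imputed at fit time.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .binning import TraitGrid, assign_bin, make_grid, optimal_bins


@dataclass
class CategoricalModel:
    grid: TraitGrid
    categories: list[str]
    counts: np.ndarray  # (B1, B2, C) int
    env_col: str
    training: pd.DataFrame  # point_id, observed, i, j
    prob: np.ndarray = field(init=False)  # (B1, B2, C); NaN rows for empty bins
    predicted: np.ndarray = field(init=False)  # (B1, B2) object; None for empty

    def __post_init__(self):
        totals = self.counts.sum(axis=2, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.prob = np.where(totals > 0, self.counts / totals, np.nan)
        global_counts = self.counts.sum(axis=(0, 1))
        # tie rule: max probability, then higher global frequency, then
        # lexicographically smaller label; encoded as a stable sort key.
        order = sorted(
            range(len(self.categories)),
            key=lambda c: (-global_counts[c], self.categories[c]),
        )
        self.predicted = np.full((self.grid.b1, self.grid.b2), None, dtype=object)
        for i in range(self.grid.b1):
            for j in range(self.grid.b2):
                if totals[i, j, 0] > 0:
                    best = max(order, key=lambda c: self.counts[i, j, c], default=None)
                    # max() keeps the earliest element of `order` on ties
                    self.predicted[i, j] = self.categories[best]

    @property
    def n_training(self) -> int:
        return len(self.training)

    def predict_bin(self, i: int, j: int):
        return self.predicted[i, j]


@dataclass
class ContinuousModel:
    grid: TraitGrid
    env_edges: np.ndarray  # (E+1,) equal-width over training env range
    freq: np.ndarray  # (B1, B2, E) int
    env_col: str
    training: pd.DataFrame  # point_id, observed, i, j
    predicted: np.ndarray = field(init=False)  # (B1, B2) float; NaN for empty
    bin_mean: np.ndarray = field(init=False)  # per-bin mean of raw env values

    def __post_init__(self):
        mid = 0.5 * (self.env_edges[:-1] + self.env_edges[1:])
        self.predicted = np.full((self.grid.b1, self.grid.b2), np.nan)
        for i in range(self.grid.b1):
            for j in range(self.grid.b2):
                f = self.freq[i, j]
                if f.sum() > 0:
                    # ties between equally frequent intervals -> lower interval
                    self.predicted[i, j] = mid[int(np.argmax(f))]
        self.bin_mean = np.full((self.grid.b1, self.grid.b2), np.nan)
        sums = np.zeros_like(self.bin_mean)
        ns = np.zeros_like(self.bin_mean)
        for _, row in self.training.iterrows():
            sums[int(row["i"]), int(row["j"])] += float(row["observed"])
            ns[int(row["i"]), int(row["j"])] += 1
        with np.errstate(invalid="ignore"):
            self.bin_mean = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)

    @property
    def env_midpoints(self) -> np.ndarray:
        return 0.5 * (self.env_edges[:-1] + self.env_edges[1:])

    @property
    def n_training(self) -> int:
        return len(self.training)


def _valid_rows(summaries: pd.DataFrame, env_col: str) -> pd.DataFrame:
    if env_col not in summaries.columns:
        raise KeyError(f"column {env_col!r} not found in summaries")
    use = summaries[
        summaries["valid"]
        & summaries["metric1"].notna()
        & summaries["metric2"].notna()
        & summaries[env_col].notna()
    ]
    return use


def fit_categorical(
    summaries: pd.DataFrame,
    category_col: str,
    bins1: int | None = None,
    bins2: int | None = None,
    grid: TraitGrid | None = None,
) -> CategoricalModel:
    """Fit a categorical ecometric model.

    Only valid summaries enter the fit. Categories are the sorted unique
    labels observed. ``grid`` may be supplied to reuse an existing binning;
    otherwise one is built from the training points.
    """
    use = _valid_rows(summaries, category_col)
    if grid is None:
        grid = make_grid(use, bins1=bins1, bins2=bins2)
    categories = sorted(str(c) for c in use[category_col].unique())
    if len(categories) == 1:
        import logging

        logging.getLogger(__name__).warning(
            "degenerate model: a single category (%s) in the training data", categories[0]
        )
    cat_index = {c: k for k, c in enumerate(categories)}
    counts = np.zeros((grid.b1, grid.b2, len(categories)), dtype=int)
    recs = []
    for pid, m1, m2, obs in zip(
        use["point_id"].astype(str), use["metric1"], use["metric2"], use[category_col]
    ):
        if pid in grid.membership:
            i, j = grid.membership[pid]
        else:
            i, j, _ = assign_bin(grid, float(m1), float(m2), clamp=True)
        counts[i, j, cat_index[str(obs)]] += 1
        recs.append({"point_id": pid, "observed": str(obs), "i": i, "j": j})
    return CategoricalModel(
        grid=grid,
        categories=categories,
        counts=counts,
        env_col=category_col,
        training=pd.DataFrame(recs),
    )


def fit_continuous(
    summaries: pd.DataFrame,
    env_col: str,
    bins1: int | None = None,
    bins2: int | None = None,
    env_bins: int | None = None,
    grid: TraitGrid | None = None,
) -> ContinuousModel:
    """Fit a continuous ecometric model.

    The environmental variable is discretized into ``env_bins`` equal-width
    intervals spanning its training range (Scott's rule by default); per
    trait bin the model records interval frequencies and predicts the modal
    interval's midpoint.
    """
    use = _valid_rows(summaries, env_col)
    env = use[env_col].to_numpy(dtype=float)
    if not np.isfinite(env).all():
        raise ValueError(f"column {env_col!r} contains non-finite values")
    if grid is None:
        grid = make_grid(use, bins1=bins1, bins2=bins2)
    if env_bins is None:
        env_bins = optimal_bins(env)  # raises on constant env
    lo, hi = float(env.min()), float(env.max())
    if lo == hi:
        raise ValueError(f"environmental variable {env_col!r} is constant; supply env_bins")
    env_edges = np.linspace(lo, hi, int(env_bins) + 1)

    def env_interval(v: float) -> int:
        if v >= env_edges[-1]:
            return len(env_edges) - 2
        return int(np.searchsorted(env_edges, v, side="right")) - 1

    freq = np.zeros((grid.b1, grid.b2, int(env_bins)), dtype=int)
    recs = []
    for pid, m1, m2, obs in zip(use["point_id"].astype(str), use["metric1"], use["metric2"], env):
        if pid in grid.membership:
            i, j = grid.membership[pid]
        else:
            i, j, _ = assign_bin(grid, float(m1), float(m2), clamp=True)
        freq[i, j, env_interval(float(obs))] += 1
        recs.append({"point_id": pid, "observed": float(obs), "i": i, "j": j})
    return ContinuousModel(
        grid=grid,
        env_edges=env_edges,
        freq=freq,
        env_col=env_col,
        training=pd.DataFrame(recs),
    )


def categorical_from_counts(grid, categories, counts, env_col, training) -> CategoricalModel:
    """Rebuild a categorical model from archived fields (no refitting)."""
    return CategoricalModel(
        grid=grid, categories=categories, counts=counts, env_col=env_col, training=training
    )


def continuous_from_freq(grid, env_edges, freq, env_col, training) -> ContinuousModel:
    """Rebuild a continuous model from archived fields (no refitting)."""
    return ContinuousModel(
        grid=grid, env_edges=env_edges, freq=freq, env_col=env_col, training=training
    )


def model_diagnostics(model) -> dict:
    """Training diagnostics recomputed from the model's stored training table.

    Categorical: overall training accuracy (share of training points whose
    observed category equals their bin's prediction), per-category accuracy,
    and a confusion matrix (rows = observed, columns = predicted).
    Continuous: Pearson r between observed and per-bin predictions, and the
    per-point anomaly (observed - predicted) summary.
    """
    t = model.training
    if isinstance(model, CategoricalModel):
        pred = np.array(
            [model.predicted[int(i), int(j)] for i, j in zip(t["i"], t["j"])], dtype=object
        )
        obs = t["observed"].to_numpy(dtype=object)
        correct = pred == obs
        cats = model.categories
        confusion = pd.DataFrame(0, index=cats, columns=cats, dtype=int)
        for o, p in zip(obs, pred):
            confusion.loc[o, p] += 1
        per_cat = {
            c: float(correct[obs == c].mean()) if (obs == c).any() else np.nan for c in cats
        }
        return {
            "kind": "categorical",
            "n_training": len(t),
            "accuracy": float(correct.mean()),
            "per_category_accuracy": per_cat,
            "confusion": confusion,
        }
    if isinstance(model, ContinuousModel):
        pred = np.array(
            [model.predicted[int(i), int(j)] for i, j in zip(t["i"], t["j"])], dtype=float
        )
        obs = t["observed"].to_numpy(dtype=float)
        anomaly = obs - pred
        if np.std(pred) == 0 or np.std(obs) == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(obs, pred).statistic)
        return {
            "kind": "continuous",
            "n_training": len(t),
            "pearson_r": r,
            "anomaly_mean": float(np.mean(anomaly)),
            "anomaly_sd": float(np.std(anomaly, ddof=1)) if len(t) > 1 else np.nan,
        }
    raise TypeError(f"unknown model type {type(model).__name__}")
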