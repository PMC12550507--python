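"""Model robustness under varying sample sizes.

Repeated subsampling without replacement: at each sample size s and replicate,
min(s, n) valid points are drawn as the training set and the complement is
held out. A model is refitted on the draw; training accuracy (categorical) or
Pearson r (continuous) measures sensitivity, the same metric on held-out
points measures transferability. Held-out points whose trait summaries land
in an empty bin of the replicate's model cannot be predicted; they are
excluded from the test metric and reported through ``test_coverage`` instead,
so no information is hidden. All randomness flows through the seed.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .binning import assign_bin, make_grid, optimal_bins
from .models import fit_categorical, fit_continuous, model_diagnostics

logger = logging.getLogger(__name__)

DEFAULT_REPLICATES = 50


def _prepare(summaries: pd.DataFrame, env_col: str) -> pd.DataFrame:
    use = summaries[
        summaries["valid"]
        & summaries["metric1"].notna()
        & summaries["metric2"].notna()
        & summaries[env_col].notna()
    ].reset_index(drop=True)
    if len(use) < 2:
        raise ValueError("need at least 2 valid summaries for a sensitivity analysis")
    return use


def _test_bins(model, test: pd.DataFrame):
    """Bin each held-out point (clamped) and split by bin occupancy."""
    if hasattr(model, "counts"):
        occ = model.counts.sum(axis=2)
    else:
        occ = model.freq.sum(axis=2)
    covered, preds = [], []
    for m1, m2 in zip(test["metric1"], test["metric2"]):
        i, j, _ = assign_bin(model.grid, float(m1), float(m2), clamp=True)
        if occ[i, j] > 0:
            covered.append(True)
            preds.append(model.predicted[i, j])
        else:
            covered.append(False)
            preds.append(None)
    return np.asarray(covered, dtype=bool), preds


def _run(
    summaries: pd.DataFrame,
    env_col: str,
    sample_sizes,
    replicates: int,
    bins1,
    bins2,
    seed,
    fit_fn,
    train_metric_fn,
    test_metric_fn,
) -> pd.DataFrame:
    use = _prepare(summaries, env_col)
    n = len(use)
    rng = np.random.default_rng(seed)
    warned_full = False
    records = []
    for s in sample_sizes:
        s_eff = min(int(s), n)
        if int(s) >= n and not warned_full:
            logger.warning(
                "sample size %d >= %d valid points; using all points, empty test set", s, n
            )
            warned_full = True
        for b in range(int(replicates)):
            idx = rng.choice(n, size=s_eff, replace=False)
            train = use.iloc[np.sort(idx)]
            test = use.drop(use.index[idx])
            rec = {
                "sample_size": int(s),
                "replicate": b,
                "train_metric": np.nan,
                "test_metric": np.nan,
                "test_coverage": np.nan,
                "failed": False,
            }
            try:
                model = fit_fn(train, bins1, bins2)
            except Exception as exc:  # degenerate draw (one category / constant env)
                logger.warning("size %d replicate %d failed to fit: %s", s, b, exc)
                rec["failed"] = True
                records.append(rec)
                continue
            rec["train_metric"] = train_metric_fn(model)
            if len(test):
                covered, preds = _test_bins(model, test)
                rec["test_coverage"] = float(covered.mean())
                if covered.any():
                    rec["test_metric"] = test_metric_fn(
                        test.loc[covered.tolist(), env_col].to_numpy(),
                        [p for p, c in zip(preds, covered) if c],
                    )
            records.append(rec)
    return pd.DataFrame(records)


def run_sensitivity_qual(
    summaries: pd.DataFrame,
    category_col: str,
    sample_sizes,
    replicates: int = DEFAULT_REPLICATES,
    bins1: int | None = None,
    bins2: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bootstrap sensitivity analysis for a categorical model.

    Metric on both splits is classification accuracy. A replicate whose
    training draw contains a single category is recorded as failed and the
    run continues.
    """
    use = _prepare(summaries, category_col)
    n_cat = use[category_col].nunique()
    if min(int(s) for s in sample_sizes) < n_cat:
        logger.warning(
            "smallest sample size is below the number of categories (%d); "
            "expect failed replicates",
            n_cat,
        )

    def fit_fn(train, b1, b2):
        if train[category_col].nunique() < 2:
            raise ValueError("single-category training draw")
        return fit_categorical(train, category_col, bins1=b1, bins2=b2)

    def test_acc(obs, preds):
        obs = np.asarray([str(o) for o in obs], dtype=object)
        preds = np.asarray([str(p) for p in preds], dtype=object)
        return float((obs == preds).mean())

    return _run(
        summaries, category_col, sample_sizes, replicates, bins1, bins2, seed,
        fit_fn,
        lambda m: float(model_diagnostics(m)["accuracy"]),
        test_acc,
    )


def run_sensitivity_cont(
    summaries: pd.DataFrame,
    env_col: str,
    sample_sizes,
    replicates: int = DEFAULT_REPLICATES,
    bins1: int | None = None,
    bins2: int | None = None,
    env_bins: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bootstrap sensitivity analysis for a continuous model.

    Metric on both splits is the Pearson correlation of observed vs predicted
    environmental values; an undefined correlation (constant predictions) is
    recorded as missing.
    """

    def fit_fn(train, b1, b2):
        return fit_continuous(train, env_col, bins1=b1, bins2=b2, env_bins=env_bins)

    def test_r(obs, preds):
        obs = np.asarray(obs, dtype=float)
        preds = np.asarray(preds, dtype=float)
        if len(obs) < 2 or np.std(obs) == 0 or np.std(preds) == 0:
            return np.nan
        return float(stats.pearsonr(obs, preds).statistic)

    return _run(
        summaries, env_col, sample_sizes, replicates, bins1, bins2, seed,
        fit_fn,
        lambda m: (
            np.nan
            if np.isnan(model_diagnostics(m)["pearson_r"])
            else float(model_diagnostics(m)["pearson_r"])
        ),
        test_r,
    )


def summarize_sensitivity(records: pd.DataFrame) -> pd.DataFrame:
    """Per-size mean and SD of train/test metrics plus mean coverage.

    Failed replicates are excluded; the row count equals the number of
    distinct sizes with at least one successful replicate.
    """
    ok = records[~records["failed"]]
    if len(ok) == 0:
        raise ValueError("no successful replicates to summarize")
    g = ok.groupby("sample_size")
    out = pd.DataFrame(
        {
            "n_replicates": g.size(),
            "train_mean": g["train_metric"].mean(),
            "train_sd": g["train_metric"].std(),
            "test_mean": g["test_metric"].mean(),
            "test_sd": g["test_metric"].std(),
            "coverage_mean": g["test_coverage"].mean(),
        }
    ).reset_index()
    return out


def plot_sensitivity(summary: pd.DataFrame, path=None):
    """Line plot of train/test metric against sample size (mean +/- SD)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for col, sd, label in (
        ("train_mean", "train_sd", "training (sensitivity)"),
        ("test_mean", "test_sd", "held-out (transferability)"),
    ):
        ax.errorbar(
            summary["sample_size"], summary[col], yerr=summary[sd], marker="o", label=label
        )
    ax.set_xlabel("training sample size")
    ax.set_ylabel("metric")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
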