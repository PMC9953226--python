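"""Benchmark harness: splits, error metrics, significance, reports.

Activity classes are repeatedly partitioned 90:10 into training and
test sets over independent trials; every method is fit on identical
training data and scored on identical test data by MAE and RMSE,
overall and on the 10% most potent test compounds. Per-trial metric
values of method pairs are compared with the two-sided Wilcoxon
signed-rank test at alpha = 0.05.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mean_absolute_error, mean_squared_error

from .curation import ActivityClass

__all__ = [
    "TrialSplit",
    "split",
    "mae",
    "rmse",
    "top_potent_subset",
    "wilcoxon_compare",
    "EvaluationReport",
    "run_benchmark",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TrialSplit:
    """One train/test partition of an activity class."""

    trial: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test overlap")


def split(
    n_or_class: int | ActivityClass,
    fraction: float = 0.9,
    seed: int = 0,
    trial: int = 0,
) -> TrialSplit:
    """Uniform random train/test partition (default 90:10).

    ``fraction`` is the training share; 0.8 gives the 80:20 control
    partition. Reproducible from the seed.
    """
    n = n_or_class if isinstance(n_or_class, int) else len(n_or_class)
    if n < 10:
        raise ValueError(f"class of size {n} too small to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fraction * n))
    return TrialSplit(trial, np.sort(perm[:n_train]), np.sort(perm[n_train:]), seed)


def mae(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute error, in log units."""
    y, y_pred = _check_pair(y, y_pred)
    return float(mean_absolute_error(y, y_pred))


def rmse(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared error, in log units."""
    y, y_pred = _check_pair(y, y_pred)
    return float(np.sqrt(mean_squared_error(y, y_pred)))


def _check_pair(y, y_pred):
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.ndim != 1:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_pred.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return y, y_pred


def top_potent_subset(y: np.ndarray, fraction: float = 0.10) -> np.ndarray:
    """Indices of the ceil(fraction*n) most potent compounds.

    Ties at the cutoff are resolved by stable order (lower index
    first).
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    m = int(np.ceil(fraction * y.size))
    return np.argsort(-y, kind="stable")[:m]


def wilcoxon_compare(a: Sequence[float], b: Sequence[float]) -> tuple[float, bool]:
    """Two-sided paired Wilcoxon signed-rank test of two metric series.

    Returns (p-value, significant at alpha = 0.05). Zero differences
    are dropped (standard signed-rank convention); the exact null
    distribution is used for up to 25 non-zero pairs, the normal
    approximation above. All-zero differences give p = 1 with a
    warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 5:
        raise ValueError("need paired samples of equal length >= 5")
    diffs = a - b
    nz = np.count_nonzero(diffs)
    if nz == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0, False
    method = "exact" if nz <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method=method)
    p = float(res.pvalue)
    return p, p <= ALPHA


@dataclass
class EvaluationReport:
    """Per-cell metrics plus pairwise significance results.

    ``metrics`` is tidy: one row per (class, method, trial) with
    columns mae, rmse, mae_top, rmse_top, error. ``significance`` has
    one row per (class, method_a, method_b, metric) with the Wilcoxon
    p-value and its flag at alpha = 0.05.
    """

    metrics: pd.DataFrame
    significance: pd.DataFrame
    n_trials: int
    train_fraction: float
    predictions: dict = field(default_factory=dict, repr=False)

    def medians(self, metric: str = "mae") -> pd.DataFrame:
        """Median of a metric per class x method (trial-aggregated)."""
        return self.metrics.pivot_table(
            index="class", columns="method", values=metric, aggfunc="median"
        )

    def save(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        sig = self.significance.to_dict(orient="records")
        (out / "significance.json").write_text(json.dumps(sig, indent=1))

    def boxplot(self, metric: str = "mae", path=None):
        """Box plot of per-trial metric values by method (optional)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        methods = sorted(self.metrics["method"].unique())
        data = [self.metrics.loc[self.metrics["method"] == m, metric].dropna() for m in methods]
        ax.boxplot(data, tick_labels=methods)
        ax.set_ylabel(f"{metric.upper()} (log units)")
        if path:
            fig.savefig(path, bbox_inches="tight")
            plt.close(fig)
        return fig


def run_benchmark(
    classes: Sequence[ActivityClass],
    methods: Mapping[str, Callable[[int], object]],
    n_trials: int = 10,
    fraction: float = 0.9,
    seed: int = 0,
    top_fraction: float = 0.10,
    keep_predictions: bool = False,
) -> EvaluationReport:
    """Run the full benchmarking protocol.

    ``methods`` maps a tag to a factory ``seed -> model`` where the
    model implements fit(fingerprints, potencies) / predict(fingerprints).
    For each class and trial, one split is drawn and every method sees
    the identical train and test data. A failing method is recorded in
    the report's ``error`` column and the run continues.
    """
    rows = []
    predictions: dict = {}
    root_ss = np.random.SeedSequence(seed)
    class_seeds = root_ss.spawn(len(classes))

    for ci, ac in enumerate(classes):
        fps = ac.fingerprints()
        y = ac.potencies
        trial_seeds = class_seeds[ci].spawn(n_trials)
        for t in range(n_trials):
            split_seed = int(trial_seeds[t].generate_state(1)[0] % (2**31))
            ts = split(len(ac), fraction=fraction, seed=split_seed, trial=t)
            Xtr, ytr = fps[ts.train_idx], y[ts.train_idx]
            Xte, yte = fps[ts.test_idx], y[ts.test_idx]
            top = top_potent_subset(yte, top_fraction)
            for name, factory in methods.items():
                method_seed = int((split_seed * 1000003 + zlib.crc32(name.encode())) % (2**31))
                try:
                    model = factory(method_seed)
                    model.fit(Xtr, ytr)
                    pred = np.asarray(model.predict(Xte), dtype=float)
                    row = {
                        "class": ac.target_id,
                        "method": name,
                        "trial": t,
                        "mae": mae(yte, pred),
                        "rmse": rmse(yte, pred),
                        "mae_top": mae(yte[top], pred[top]),
                        "rmse_top": rmse(yte[top], pred[top]),
                        "error": "",
                    }
                    if keep_predictions:
                        predictions[(ac.target_id, name, t)] = (yte.copy(), pred)
                except Exception as exc:  # noqa: BLE001 - per-cell isolation
                    row = {
                        "class": ac.target_id,
                        "method": name,
                        "trial": t,
                        "mae": np.nan,
                        "rmse": np.nan,
                        "mae_top": np.nan,
                        "rmse_top": np.nan,
                        "error": f"{type(exc).__name__}: {exc}",
                    }
                rows.append(row)

    metrics = pd.DataFrame(rows)
    significance = _pairwise_significance(metrics)
    return EvaluationReport(
        metrics=metrics,
        significance=significance,
        n_trials=n_trials,
        train_fraction=fraction,
        predictions=predictions,
    )


def _pairwise_significance(metrics: pd.DataFrame) -> pd.DataFrame:
    rows = []
    names = sorted(metrics["method"].unique())
    for cls, sub in metrics.groupby("class"):
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                for metric in ("mae", "rmse"):
                    va = sub.loc[sub["method"] == a].sort_values("trial")[metric].to_numpy()
                    vb = sub.loc[sub["method"] == b].sort_values("trial")[metric].to_numpy()
                    if (
                        len(va) != len(vb)
                        or len(va) < 5
                        or np.isnan(va).any()
                        or np.isnan(vb).any()
                    ):
                        p, sig = np.nan, False
                    else:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            p, sig = wilcoxon_compare(va, vb)
                    rows.append(
                        {
                            "class": cls,
                            "method_a": a,
                            "method_b": b,
                            "metric": metric,
                            "p_value": p,
                            "significant": sig,
                        }
                    )
    return pd.DataFrame(rows)
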