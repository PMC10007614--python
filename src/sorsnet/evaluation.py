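"""Evaluation protocol: 8:2 split, repeated refits, calibration metrics.

Metrics follow spectroscopic-calibration convention:

* ``R2 = 1 - SSE/SST`` (coefficient of determination),
* ``RMSE = sqrt(mean squared error)``,
* ``RPD = sd(truth) / RMSE`` (residual prediction deviation, sample
  standard deviation with n-1; an RPD above ~3 indicates a strong
  calibration).

``run_experiment`` holds a fixed random 8:2 train/test split, repeats the
train-and-predict cycle ``n_repeats`` times with fresh seeds, and reports
per-repeat and mean +/- sigma metrics, a pooled prediction table, and
per-true-day box-plot statistics (median, quartiles, 1.5 IQR whiskers,
outliers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baselines import BASELINE_KINDS, fit_baseline, predict_baseline, \
    select_optimal_offset
from .errors import InputError
from .model import AttentionLSTMRegressor, ModelSpec


@dataclass(frozen=True)
class EvalProtocol:
    test_fraction: float = 0.2
    k_folds: int = 5
    n_repeats: int = 5
    seed: int = 0
    offset_method: str = "cv_r2"   # baseline optimal-offset criterion
    sigma_over: str = "repeats"    # "repeats" | "folds"

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise InputError("test_fraction must lie in (0, 1)")
        if self.k_folds < 2:
            raise InputError("k_folds must be >= 2")
        if self.n_repeats < 1:
            raise InputError("n_repeats must be >= 1")


@dataclass
class EvalReport:
    per_repeat: pd.DataFrame         # model, repeat, r2, rmse, rpd
    summary: pd.DataFrame            # model, metric means and sigmas
    predictions: pd.DataFrame        # sample_id, truth, prediction, model, repeat
    day_boxplot: pd.DataFrame        # per (model, day) quartile statistics
    offset_selection: dict = field(default_factory=dict)

    def mean_metric(self, model: str, metric: str) -> float:
        row = self.summary[self.summary["model"] == model]
        return float(row[f"{metric}_mean"].iloc[0])


def split_dataset(n_samples: int, protocol: EvalProtocol
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, seeded train/test index split."""
    if n_samples < 5:
        raise InputError("need at least 5 samples to split")
    rng = np.random.default_rng(protocol.seed)
    order = rng.permutation(n_samples)
    n_test = int(round(protocol.test_fraction * n_samples))
    return np.sort(order[n_test:]), np.sort(order[:n_test])


def metric_rmse(truth: np.ndarray, pred: np.ndarray) -> float:
    truth, pred = _check_pair(truth, pred)
    return float(np.sqrt(np.mean((truth - pred) ** 2)))


def metric_r2(truth: np.ndarray, pred: np.ndarray) -> float:
    truth, pred = _check_pair(truth, pred)
    sst = float(np.sum((truth - truth.mean()) ** 2))
    if sst == 0:
        raise InputError("R2 undefined for constant truth")
    return 1.0 - float(np.sum((truth - pred) ** 2)) / sst


def metric_rpd(truth: np.ndarray, pred: np.ndarray) -> float:
    """sd(truth, ddof=1) / RMSE; infinite for a perfect prediction."""
    truth, pred = _check_pair(truth, pred)
    sd = float(np.std(truth, ddof=1))
    if sd == 0:
        raise InputError("RPD undefined for constant truth")
    rmse = metric_rmse(truth, pred)
    return float(np.inf) if rmse == 0 else sd / rmse


def _check_pair(truth, pred) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if truth.size != pred.size or truth.size < 2:
        raise InputError("truth and prediction must share a length >= 2")
    return truth, pred


def boxplot_stats(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per (model, true day) quartiles, whiskers and outlier counts."""
    rows = []
    for (model, day), grp in predictions.groupby(["model", "truth"]):
        v = grp["prediction"].to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo) & (v <= hi)]
        rows.append({"model": model, "day": day, "q1": q1, "median": med,
                     "q3": q3, "whisker_low": inside.min(),
                     "whisker_high": inside.max(),
                     "n_outliers": int(np.sum((v < lo) | (v > hi)))})
    return pd.DataFrame(rows)


def run_experiment(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
                   protocol: EvalProtocol,
                   ablations: tuple[frozenset, ...] = (),
                   baselines: tuple[str, ...] = BASELINE_KINDS,
                   band_centers: np.ndarray | None = None) -> EvalReport:
    """Fixed 8:2 split; per repeat, refit every model and predict the test set.

    ``X`` is (n, bands, offsets); the deep models consume the full matrix
    (wavebands as the sequence axis), the baselines only the selected
    optimal-offset column.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if np.unique(y).size < 2:
        raise InputError("labels are constant; the protocol is undefined")
    train_idx, test_idx = split_dataset(len(y), protocol)
    Xtr, ytr, Xte, yte = X[train_idx], y[train_idx], X[test_idx], y[test_idx]

    # the repetition axis: reseeded refits on the full training set
    # (default), or the k CV folds of the training set, each fold's
    # complement refit and scored on the fixed test set
    if protocol.sigma_over == "folds":
        rng = np.random.default_rng(protocol.seed)
        fold_of = rng.integers(0, protocol.k_folds, size=len(ytr))
        iterations = [np.flatnonzero(fold_of != k)
                      for k in range(protocol.k_folds)]
    else:
        iterations = [np.arange(len(ytr)) for _ in range(protocol.n_repeats)]

    selection = None
    if baselines:
        selection = select_optimal_offset(
            Xtr, ytr, method=protocol.offset_method,
            band_centers=band_centers, k_folds=protocol.k_folds,
            seed=protocol.seed)

    model_specs: dict[str, ModelSpec] = {"attention_lstm": spec}
    for abl in ablations:
        name = "drop_" + "+".join(sorted(abl)) if abl else "attention_lstm"
        model_specs[name] = replace(spec, ablation=frozenset(abl))

    rows, pred_rows = [], []
    for r, sub in enumerate(iterations):
        rseed = protocol.seed + 1000 * (r + 1)
        for name, mspec in model_specs.items():
            m = AttentionLSTMRegressor(replace(mspec, seed=rseed))
            m.fit(Xtr[sub], ytr[sub])
            pred = m.predict(Xte)
            rows.append(_metric_row(name, r, yte, pred))
            pred_rows.extend(_pred_rows(name, r, test_idx, yte, pred))
        for kind in baselines:
            j = selection.offset_index
            est = fit_baseline(kind, Xtr[sub][:, :, j], ytr[sub],
                               k_folds=protocol.k_folds, seed=rseed)
            pred = predict_baseline(est, Xte[:, :, j])
            rows.append(_metric_row(kind, r, yte, pred))
            pred_rows.extend(_pred_rows(kind, r, test_idx, yte, pred))

    per_repeat = pd.DataFrame(rows)
    predictions = pd.DataFrame(pred_rows)
    summary = _summarize(per_repeat)
    report = EvalReport(per_repeat=per_repeat, summary=summary,
                        predictions=predictions,
                        day_boxplot=boxplot_stats(predictions))
    if selection is not None:
        report.offset_selection = {
            "offset_index": selection.offset_index,
            "method": selection.method,
            "criterion_values": list(selection.criterion_values)}
    return report


def _metric_row(model: str, repeat: int, truth, pred) -> dict:
    return {"model": model, "repeat": repeat,
            "r2": metric_r2(truth, pred),
            "rmse": metric_rmse(truth, pred),
            "rpd": metric_rpd(truth, pred)}


def _pred_rows(model, repeat, idx, truth, pred):
    return [{"sample_id": int(i), "truth": float(t), "prediction": float(p),
             "model": model, "repeat": repeat}
            for i, t, p in zip(idx, truth, pred)]


def _summarize(per_repeat: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for model, grp in per_repeat.groupby("model", sort=False):
        row = {"model": model}
        for metric in ("r2", "rmse", "rpd"):
            row[f"{metric}_mean"] = float(grp[metric].mean())
            row[f"{metric}_sigma"] = (float(grp[metric].std(ddof=1))
                                      if len(grp) > 1 else 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
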