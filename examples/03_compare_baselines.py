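"""Optimal-offset selection and the chemometric baselines.

Selects the offset distance whose single spectrum best predicts storage
day under cross-validation, then fits PLSR / SVR / extra-trees on that
column and prints held-out metrics for each.
"""

import numpy as np

from sorsnet import (fit_baseline, metric_r2, metric_rmse, predict_baseline,
                     select_optimal_offset)
from sorsnet.benchmark import benchmark_data
from sorsnet.evaluation import EvalProtocol, split_dataset

X, y, centers = benchmark_data(seed=0, n_shrimp=16)
train_idx, test_idx = split_dataset(len(y), EvalProtocol(seed=0))

sel = select_optimal_offset(X[train_idx], y[train_idx], method="cv_r2",
                            seed=0)
print(f"optimal offset: bin {sel.offset_index} "
      f"({sel.offset_index * 0.5:.1f} mm from the laser point)")
print("per-offset CV R2:",
      np.round(sel.criterion_values, 3))

j = sel.offset_index
for kind in ("plsr", "svr", "et"):
    est = fit_baseline(kind, X[train_idx][:, :, j], y[train_idx], seed=0)
    pred = predict_baseline(est, X[test_idx][:, :, j])
    print(f"{kind:4s}: test R2 {metric_r2(y[test_idx], pred):.3f}  "
          f"RMSE {metric_rmse(y[test_idx], pred):.3f} days")
print("(each baseline sees only the one selected offset spectrum; the "
      "deep model consumes all 11 offsets at once)")
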