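"""Train the attention-based LSTM on a reduced synthetic study.

Uses 16 shrimp x 7 days (112 samples) and a short 60-epoch budget so the
script finishes in about a minute; expect a modest test R-squared at this
scale — the full benchmark uses 100 shrimp and 200 epochs.
"""

import numpy as np
from dataclasses import replace

from sorsnet import ModelSpec, build_model, metric_r2, metric_rmse
from sorsnet.benchmark import BENCHMARK_MODEL, benchmark_data
from sorsnet.evaluation import EvalProtocol, split_dataset

X, y, _ = benchmark_data(seed=0, n_shrimp=16)
train_idx, test_idx = split_dataset(len(y), EvalProtocol(seed=0))

spec = replace(BENCHMARK_MODEL, epochs=60, seed=0)
model = build_model(spec)
print("layer parameter counts:", model.layer_param_counts)

model.fit(X[train_idx], y[train_idx])
print(f"final training MSE: {model.loss_history[-1]:.3f}")

pred = model.predict(X[test_idx])
print(f"test R2:   {metric_r2(y[test_idx], pred):.3f}")
print(f"test RMSE: {metric_rmse(y[test_idx], pred):.3f} days")
print("(R2 near 1 means predicted storage day tracks the true day; "
      "RMSE is the typical prediction error in days)")
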