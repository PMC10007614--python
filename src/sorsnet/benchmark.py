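"""Scaled synthetic benchmark shared by the examples and acceptance runs.

The full study design (100 shrimp x 7 days, 1000-epoch training) is costly
on one CPU, so the benchmark keeps the study's structure — all seven
storage days, the complete preprocessing chain, the full model against its
three single-layer ablations and the three optimal-offset baselines —
while scaling the number of shrimp and the training epochs down to sizes a
desk run completes in minutes.  Sizes are parameters; nothing else about
the protocol changes.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .evaluation import EvalProtocol, EvalReport, run_experiment
from .model import ModelSpec
from .pipeline import ABLATION_VARIANTS, preprocess_dataset, samples_to_arrays
from .preprocess import PreprocessConfig
from .simulate import SimulationConfig, generate_dataset

# benchmark training settings: the adaptive-optimizer switch with a decayed
# step size and log-intensity inputs so the reduced epoch budget converges
BENCHMARK_MODEL = ModelSpec(optimizer="adam", learning_rate=1e-2,
                            lr_decay=0.99, epochs=200, batch_size=32,
                            input_transform="log")


def benchmark_data(seed: int = 0, n_shrimp: int = 100,
                   preprocess: PreprocessConfig | None = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate and preprocess the study; returns (X, y, band_centers)."""
    sim = replace(SimulationConfig(), n_shrimp=n_shrimp, seed=seed)
    dataset = generate_dataset(sim)
    samples = preprocess_dataset(dataset, preprocess or PreprocessConfig())
    return samples_to_arrays(samples)


def run_benchmark(seed: int = 0, n_shrimp: int = 100, epochs: int = 200,
                  n_repeats: int = 1,
                  ablations: tuple[frozenset, ...] = ABLATION_VARIANTS,
                  baselines: tuple[str, ...] = ("plsr", "svr", "et")
                  ) -> EvalReport:
    """End-to-end scaled experiment: full model vs ablations vs baselines."""
    X, y, band_centers = benchmark_data(seed=seed, n_shrimp=n_shrimp)
    spec = replace(BENCHMARK_MODEL, epochs=epochs, seed=seed)
    protocol = EvalProtocol(n_repeats=n_repeats, seed=seed)
    return run_experiment(X, y, spec, protocol, ablations=ablations,
                          baselines=baselines, band_centers=band_centers)
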