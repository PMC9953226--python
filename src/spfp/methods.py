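"""Factory registry wiring every predictor into the benchmark harness.

Each factory takes a seed and returns an unfitted model with the
uniform fit/predict interface. ``cvae_yrand`` is the y-randomization
control: it shuffles the training potencies (structures untouched)
before fitting the CVAE, giving a chance-level reference.
"""

from __future__ import annotations

import numpy as np

from .baselines import (
    DNN_GRID,
    KNN_K_GRID,
    RFR_GRID,
    SVR_C_GRID,
    MeanRegressor,
    TanimotoKNN,
    TanimotoSVR,
    _GridDNN,
    _GridRFR,
)
from .cvae import CVAEConfig, CVAERegressor
from .encoding import PotencyModuleSpec

__all__ = ["default_factories", "DESK_CVAE", "DESK_RFR_GRID", "DESK_DNN_GRID"]

#: Desk-scale CVAE settings for benchmark sweeps: smaller hidden stack
#: and epoch budget than the (512, 256, 128)/150-epoch default, which
#: the sweeps do not need to reach the same decoded accuracy.
DESK_CVAE = CVAEConfig(
    hidden_sizes=(128, 64, 32),
    latent_dim=16,
    batch_size=64,
    learning_rate=0.001,
    max_epochs=40,
    early_stop_patience=10,
    lr_patience=5,
)

#: Reduced baseline grids for sweep-scale runs (full grids stay the default).
DESK_RFR_GRID = {"n_estimators": [100], "min_samples_split": [2], "min_samples_leaf": [1]}
DESK_DNN_GRID = {
    "hidden_layer_sizes": [(100, 100)],
    "batch_size": [64],
    "learning_rate_init": [0.001],
}


class _YRandWrapper:
    """Shuffles training potencies before delegating to a model."""

    def __init__(self, inner, seed: int):
        self.inner = inner
        self.seed = seed

    def fit(self, X, y):
        rng = np.random.default_rng(self.seed)
        self.inner.fit(X, rng.permutation(np.asarray(y, dtype=float)))
        return self

    def predict(self, X):
        return self.inner.predict(X)


def default_factories(
    methods: list[str] | None = None,
    potency_bits: int = 100,
    desk_scale: bool = True,
    cvae_config: CVAEConfig | None = None,
):
    """Build the method-tag -> factory mapping for ``run_benchmark``.

    Known tags: cvae, svr, rfr, dnn, knn, mr, cvae_yrand. With
    ``desk_scale`` (default) the CVAE uses :data:`DESK_CVAE` and RFR/DNN
    single-point grids; otherwise the full hyperparameter grids apply.
    """
    from dataclasses import replace

    spec = PotencyModuleSpec(n_bits=potency_bits)
    base_cfg = cvae_config or (DESK_CVAE if desk_scale else CVAEConfig())
    rfr_grid = DESK_RFR_GRID if desk_scale else RFR_GRID
    dnn_grid = DESK_DNN_GRID if desk_scale else DNN_GRID

    registry = {
        "cvae": lambda seed: CVAERegressor(replace(base_cfg, seed=seed), spec),
        "svr": lambda seed: TanimotoSVR(c_grid=SVR_C_GRID, seed=seed),
        "rfr": lambda seed: _GridRFR(grid=rfr_grid, seed=seed),
        "dnn": lambda seed: _GridDNN(grid=dnn_grid, seed=seed),
        "knn": lambda seed: TanimotoKNN(k_grid=KNN_K_GRID, seed=seed),
        "mr": lambda seed: MeanRegressor(),
        "cvae_yrand": lambda seed: _YRandWrapper(
            CVAERegressor(replace(base_cfg, seed=seed), spec), seed
        ),
    }
    if methods is None:
        return registry
    unknown = set(methods) - registry.keys()
    if unknown:
        raise ValueError(f"unknown method tags: {sorted(unknown)}")
    return {m: registry[m] for m in methods}
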