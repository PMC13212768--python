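"""Desk-scale benchmark: train all three surrogates on an oracle-generated
cohort and compare held-out accuracy.

The desk preset (160 x 20 lattice, 140 x 20 analysis grid, 100 vessels,
60/20/20 split) runs the full compare on a single CPU in minutes; model
widths and epoch budgets are scaled down accordingly (reduced hidden sizes,
~30 epochs with early stopping).  The quantity compared is the pooled
node-wise Pearson R over all held-out test cases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import DESK_PRESET, generate_cohort
from .dataset import WSSDataset
from .evaluation import compute_metrics
from .models import TrainConfig, train_surrogate
from .models.training import TrainedSurrogate
from .oracle import FlowParams

#: per-kind desk-scale model sizes
DESK_MODEL_KWARGS = {
    "mlp": dict(bottleneck=64, conv_channels=(8, 16), ae_hidden=256),
    "unet": dict(base=8, depth=2),
    "pignn": dict(hidden_dim=64, n_layers=4, dropout=0.1),
}


def desk_train_config(kind: str, seed: int) -> TrainConfig:
    return TrainConfig(
        seed=seed,
        max_epochs=30,
        early_stop_patience=10,
        plateau_patience=5,
        batch_size=4,
        split=(0.6, 0.2, 0.2),
        ae_epochs=30,
        model_kwargs=dict(DESK_MODEL_KWARGS[kind]),
    )


def pooled_test_pearson(trained: TrainedSurrogate) -> float:
    """Pearson R over the concatenated nodes of every held-out test case."""
    test = trained.dataset.subset("test")
    preds = np.concatenate([trained.predict(s).ravel() for s in test])
    refs = np.concatenate([s.wss.values.ravel() for s in test])
    return compute_metrics(preds, refs).PearsonR


def run_benchmark(
    n_cases: int = 100,
    seeds: tuple[int, ...] = (0, 1, 2),
    cohort_seed: int = 1234,
    kinds: tuple[str, ...] = ("mlp", "unet", "pignn"),
    flow: FlowParams | None = None,
    dataset: WSSDataset | None = None,
    verbose: bool = False,
) -> pd.DataFrame:
    """Train every kind for every seed on one desk cohort; returns a frame
    with columns (kind, seed, pearson_r, epochs)."""
    flow = flow or FlowParams()
    if dataset is None:
        dataset, _ = generate_cohort(n_cases, DESK_PRESET, seed=cohort_seed,
                                     flow=flow)
    rows = []
    for seed in seeds:
        for kind in kinds:
            cfg = desk_train_config(kind, seed)
            trained = train_surrogate(dataset, kind, cfg, flow=flow,
                                      verbose=verbose)
            r = pooled_test_pearson(trained)
            rows.append({"kind": kind, "seed": seed, "pearson_r": r,
                         "epochs": len(trained.history)})
            if verbose:
                print(f"seed {seed} {kind}: R = {r:.4f}")
    return pd.DataFrame(rows)
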