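"""End-to-end pipeline: cohort dataset -> per-output blood-to-stroma maps."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (FEATURE_COLUMNS, TARGET_COLUMNS, CohortDataset,
                     split_dataset)
from .neuralnet import FitReport, MLPConfig, NeuralNet, train_with_restarts

__all__ = ["train_metric_maps", "fit_report_table", "predict_table"]


def train_metric_maps(dataset: CohortDataset,
                      config: MLPConfig | None = None,
                      split_fractions=(0.8, 0.2),
                      split_seed: int = 0,
                      targets=None,
                      test_dataset: CohortDataset | None = None,
                      ) -> dict[str, tuple[NeuralNet, FitReport]]:
    """Train one net per stromal output metric from the blood PK features.

    Two evaluation protocols:

    * ``test_dataset`` given — train on every row of ``dataset`` and
      evaluate/select on the independently simulated ``test_dataset``
      (the default pipeline: the canonical factorial trains, a fresh
      uniformly-sampled cohort tests).
    * otherwise — split ``dataset`` once with ``split_fractions`` and
      ``split_seed`` (same partition for every output).

    Every output uses the same restart seeds (config.seed, +1, ...);
    outputs are trained independently.  Returns
    ``target name -> (selected net, test-set FitReport)``.
    """
    config = config if config is not None else MLPConfig()
    targets = list(targets) if targets is not None else list(TARGET_COLUMNS)
    if test_dataset is not None:
        train, test = dataset, test_dataset
    else:
        train, test = split_dataset(dataset, split_fractions, split_seed)
    X_train = train.table[FEATURE_COLUMNS].to_numpy(float)
    X_test = test.table[FEATURE_COLUMNS].to_numpy(float)
    out: dict[str, tuple[NeuralNet, FitReport]] = {}
    for name in targets:
        net, report = train_with_restarts(
            X_train, train.table[name].to_numpy(float),
            X_test, test.table[name].to_numpy(float),
            config, feature_names=FEATURE_COLUMNS, target_name=name)
        out[name] = (net, report)
    return out


def fit_report_table(maps: dict[str, tuple[NeuralNet, FitReport]]) -> pd.DataFrame:
    """Tabulate per-metric linear fits: metric, slope, intercept, R^2, MSE."""
    rows = [{"metric": name, "slope": rep.slope, "intercept": rep.intercept,
             "r2": rep.r2, "test_mse": rep.mse, "n_test": rep.n}
            for name, (_, rep) in maps.items()]
    return pd.DataFrame(rows, columns=["metric", "slope", "intercept", "r2",
                                       "test_mse", "n_test"])


def predict_table(nets: dict[str, NeuralNet], blood: pd.DataFrame) -> pd.DataFrame:
    """Apply trained nets row-wise to a table of blood PK metrics.

    ``blood`` must contain the four feature columns; extra columns are
    carried through unchanged.  Adds one prediction column per net plus
    provenance columns naming each net's target and seed.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in blood.columns]
    if missing:
        raise ValueError(
            f"input is missing feature column(s): {', '.join(missing)}")
    out = blood.copy()
    X = blood[FEATURE_COLUMNS].to_numpy(float)
    for name, net in nets.items():
        if X.shape[0]:
            out[f"pred_{name}"] = np.asarray(net.forward(X))
        else:
            out[f"pred_{name}"] = pd.Series(dtype=float)
        out[f"pred_{name}_net_seed"] = net.seed
    return out
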