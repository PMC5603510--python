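"""Self-validation workflows with planted ground truth.

Two checks that exercise the modelling stack end to end:

* :func:`planted_surface_fit` — fits the network-selection machinery to a
  dataset drawn from a known smooth effect surface plus Gaussian noise and
  reports held-out performance.
* :func:`ranking_recovery` — runs the full synthetic screen pipeline on a
  dose-rich design (few compounds, many log-spaced concentrations) and
  compares the predicted compound ranking against the planted per-compound
  magnitude scores.

Both are deterministic given a seed and are used by the test suite and the
acceptance script.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from kinotox import ann, synth
from kinotox.pipeline import RunConfig, run_pipeline


def planted_surface_fit(
    seed: int,
    n: int = 240,
    noise_sd: float = 0.1,
    n_restarts: int = 3,
    max_epochs: int = 300,
) -> dict:
    """Fit candidate networks to a planted smooth surface; report held-out fit.

    Returns a dict with the selected architecture, held-out R² and RMSE,
    and the train/test sizes.
    """
    X, y = synth.planted_surface_dataset(n=n, noise_sd=noise_sd, seed=seed)
    candidates = [
        ((3,), ("tansig",)),
        ((5,), ("tansig",)),
        ((8,), ("tansig",)),
        ((5,), ("logsig",)),
        ((8,), ("logsig",)),
    ]
    ranked = ann.architecture_search(
        X,
        y,
        candidates,
        ann.LMConfig(max_epochs=max_epochs),
        seed=seed,
        n_restarts=n_restarts,
    )
    best = ranked[0]
    return {
        "architecture": best.network.architecture,
        "test_r2": float(best.test_r2),
        "test_rmse": float(best.test_rmse),
        "n_records": len(y),
    }


def recovery_config(out_dir: str | Path, seed: int) -> RunConfig:
    """Dose-rich screen for ranking recovery: 10 compounds on 10 targets
    at 24 log-spaced concentrations in triplicate (240 model records)."""
    return RunConfig(
        seed=seed,
        out_dir=str(out_dir),
        n_compounds=10,
        n_targets=10,
        concentrations=tuple(np.geomspace(0.1, 10.0, 24)),
        max_epochs=400,
        n_restarts=3,
        search_max_hidden_layers=1,
        search_sizes=(3, 5, 8),
        search_transfers=("tansig", "logsig"),
    )


def ranking_recovery(out_dir: str | Path, seed: int) -> dict:
    """Run the full pipeline on the dose-rich design and score the ranking.

    Returns the Spearman correlation between the predicted per-compound
    mean normalized peak magnitude and the planted magnitude score, plus
    the selected network's held-out metrics.
    """
    cfg = recovery_config(out_dir, seed)
    manifest = run_pipeline(cfg)
    out = Path(cfg.out_dir)
    ranked = pd.read_csv(out / "ranking.csv")
    truth = pd.read_csv(out / "planted_truth.csv")
    merged = ranked.merge(truth, on="compound_id")
    rho, _ = spearmanr(merged["mean_prediction"], merged["planted_magnitude_score"])
    train_metrics = manifest["stages"]["train"]["metrics"]
    return {
        "spearman": float(rho),
        "n_compounds": int(len(merged)),
        "test_r2": float(train_metrics["test_r2"]),
        "test_rmse": float(train_metrics["test_rmse"]),
        "architecture": train_metrics["best_architecture"],
        "planted_score_sd": float(truth["planted_magnitude_score"].std()),
    }
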