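"""Design-grid prediction and compound ranking.

The trained network is evaluated over a constrained Cartesian grid of
inputs — concentrations spanning the tested range while the normalized
frequency, viability and live-cell inputs are confined to near-neutral
intervals (no undesired side effects) — and each compound is scored by
its mean predicted normalized Ca2+ peak magnitude.  The compound with the
highest mean is the least detrimental, the lowest the most detrimental.

The default factorization is 13 log-spaced concentrations x 11 frequency
levels x 11 viability levels (live cells tied to viability), i.e. 1,573
grid rows per compound and 125,840 over an 80-compound registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from kinotox.ann import MLPNetwork, MODEL_INPUTS, forward
from kinotox.errors import InvalidArgumentError
from kinotox.synth import CompoundRegistry


def default_levels() -> dict[str, np.ndarray]:
    return {
        "concentration_uM": np.geomspace(0.1, 10.0, 13),
        "norm_frequency": np.linspace(-0.05, 0.05, 11),
        "norm_viability": np.linspace(0.0, 0.1, 11),
    }


@dataclass(frozen=True)
class DesignGrid:
    """Per-compound prediction inputs with their constraint intervals."""

    table: pd.DataFrame  # columns: compound_id + MODEL_INPUTS
    levels: Mapping[str, np.ndarray]

    @property
    def rows_per_compound(self) -> int:
        return int(np.prod([len(v) for v in self.levels.values()]))

    @property
    def n_rows(self) -> int:
        return len(self.table)

    @property
    def constraints(self) -> dict[str, tuple[float, float]]:
        return {k: (float(np.min(v)), float(np.max(v))) for k, v in self.levels.items()}


def build_grid(
    registry: CompoundRegistry,
    levels: Mapping[str, np.ndarray] | None = None,
) -> DesignGrid:
    """Cartesian product of the level sets, replicated per compound.

    The kinase-target input is fixed to each compound's own target code;
    normalized live cells are tied equal to normalized viability so the
    two cell endpoints move together.
    """
    if registry.n_compounds == 0:
        raise InvalidArgumentError("registry must be nonempty")
    lv = {k: np.asarray(v, dtype=float) for k, v in (levels or default_levels()).items()}
    for k, v in lv.items():
        if v.size < 1:
            raise InvalidArgumentError(f"dimension {k} needs >= 1 level")
    conc, freq, viab = (
        lv["concentration_uM"],
        lv["norm_frequency"],
        lv["norm_viability"],
    )
    cc, ff, vv = np.meshgrid(conc, freq, viab, indexing="ij")
    block = pd.DataFrame(
        {
            "concentration_uM": cc.ravel(),
            "norm_frequency": ff.ravel(),
            "norm_viability": vv.ravel(),
            "norm_live_cells": vv.ravel(),
        }
    )
    frames = []
    for comp in registry.compounds:
        df = block.copy()
        df.insert(0, "compound_id", comp.compound_id)
        df.insert(1, "kinase_target", float(comp.kinase_target))
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)[["compound_id", *MODEL_INPUTS]]
    return DesignGrid(table=table, levels=lv)


def predict_grid(net: MLPNetwork, grid: DesignGrid) -> pd.DataFrame:
    """Predicted normalized peak magnitude for every grid row."""
    X = grid.table[list(MODEL_INPUTS)].to_numpy(dtype=float)
    if X.shape[1] != net.n_inputs:
        raise InvalidArgumentError(
            f"grid has {X.shape[1]} inputs but network expects {net.n_inputs}"
        )
    out = grid.table[["compound_id"]].copy()
    out["predicted_norm_peak_magnitude"] = forward(net, X)
    return out


@dataclass(frozen=True)
class CompoundRanking:
    table: pd.DataFrame  # compound_id, kinase_target?, mean_prediction, rank
    least_detrimental: int
    most_detrimental: int


def rank_compounds(
    predictions: pd.DataFrame, registry: CompoundRegistry | None = None
) -> CompoundRanking:
    """Rank by mean predicted normalized peak magnitude, descending.

    Rank 1 is the least detrimental compound (largest mean predicted
    effect on transient magnitude); ties break by compound_id ascending.
    """
    if len(predictions) == 0:
        raise InvalidArgumentError("predictions must be nonempty")
    means = (
        predictions.groupby("compound_id")["predicted_norm_peak_magnitude"]
        .mean()
        .rename("mean_prediction")
        .reset_index()
    )
    means = means.sort_values(
        ["mean_prediction", "compound_id"], ascending=[False, True]
    ).reset_index(drop=True)
    means["rank"] = np.arange(1, len(means) + 1)
    if registry is not None:
        tmap = {c.compound_id: c.kinase_target for c in registry.compounds}
        means.insert(1, "kinase_target", means["compound_id"].map(tmap))
    return CompoundRanking(
        table=means,
        least_detrimental=int(means.iloc[0]["compound_id"]),
        most_detrimental=int(means.iloc[-1]["compound_id"]),
    )


def write_ranking_csv(ranking: CompoundRanking, path: str | Path) -> None:
    ranking.table.to_csv(path, index=False, float_format="%.10g")


def write_predictions_csv(predictions: pd.DataFrame, path: str | Path) -> None:
    predictions.to_csv(path, index=False, float_format="%.10g")
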