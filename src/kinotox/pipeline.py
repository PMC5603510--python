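"""End-to-end orchestration: generate -> traces -> screen -> train ->
predict -> rank, plus the engineered-tissue (biowire) metrics stage.

Every stage reads the previous stage's CSV outputs from the run directory
and writes its own, so stages can be re-run individually from the CLI;
``run_pipeline`` executes them in order and records a manifest with the
SHA-256 checksum of every artifact.  A single global seed fans out to
per-stage seeds by fixed offsets, making each stage individually
reproducible.  Numeric output is serialized with 10 significant digits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from kinotox import __version__, ann, ranking, stats, synth, traces
from kinotox.errors import InvalidArgumentError, StageInputError

log = logging.getLogger("kinotox")

STAGES = ("generate", "traces", "screen", "train", "predict", "rank", "biowire")

_SEED_OFFSETS = {name: i + 1 for i, name in enumerate(STAGES)}


def stage_seed(global_seed: int, stage: str) -> int:
    return (global_seed * 1_000_003 + _SEED_OFFSETS[stage]) % (2**31)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable configuration of a full screening-analysis run."""

    seed: int = 7
    out_dir: str = "results/run"

    # screen layout
    n_compounds: int = 80
    n_targets: int = 23
    concentrations: tuple[float, ...] = (0.1, 1.0, 10.0)
    replicates: int = 3
    n_blank: int = 6
    baseline_total_cells: int = 8000

    # calcium-trace morphology (control wells)
    trace_baseline: float = 100.0
    trace_amplitude: float = 25.0
    trace_frequency_hz: float = 1.0
    trace_peak_width_s: float = 0.1
    trace_noise_sd: float = 0.5
    trace_dt: float = 0.1
    trace_duration: float = 40.0

    # trace analysis
    noise_floor_multiplier: float = 3.0

    # ANN training / search
    train_fraction: float = 0.9
    max_epochs: int = 300
    n_restarts: int = 2
    search_max_hidden_layers: int = 1
    search_sizes: tuple[int, ...] = (3, 5, 8, 12)
    search_transfers: tuple[str, ...] = ("tansig", "logsig")

    # design grid
    grid_conc_levels: int = 13
    grid_freq_levels: int = 11
    grid_viab_levels: int = 11
    grid_conc_range: tuple[float, float] = (0.1, 10.0)
    grid_freq_range: tuple[float, float] = (-0.05, 0.05)
    grid_viab_range: tuple[float, float] = (0.0, 0.1)

    # biowire
    biowire_pacing_hz: float = 1.0
    biowire_duration_s: float = 10.0
    biowire_dt: float = 0.01
    biowire_amplitude_uN: float = 10.0
    biowire_contraction_slope: float = 100.0
    biowire_relaxation_slope: float = 50.0
    biowire_noise_sd: float = 0.05
    biowire_replicates: int = 3

    def to_dict(self) -> dict[str, Any]:
        def plain(v):
            if isinstance(v, (tuple, list)):
                return [plain(x) for x in v]
            if isinstance(v, np.integer):
                return int(v)
            if isinstance(v, np.floating):
                return float(v)
            return v

        return {k: plain(v) for k, v in dataclasses.asdict(self).items()}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise InvalidArgumentError(f"unknown config key {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def trace_params(self) -> synth.TraceParams:
        return synth.TraceParams(
            baseline=self.trace_baseline,
            amplitude=self.trace_amplitude,
            frequency_hz=self.trace_frequency_hz,
            peak_width_s=self.trace_peak_width_s,
            noise_sd=self.trace_noise_sd,
        )

    def grid_levels(self) -> dict[str, np.ndarray]:
        return {
            "concentration_uM": np.geomspace(*self.grid_conc_range, self.grid_conc_levels),
            "norm_frequency": np.linspace(*self.grid_freq_range, self.grid_freq_levels),
            "norm_viability": np.linspace(*self.grid_viab_range, self.grid_viab_levels),
        }

    def candidates(self) -> list[tuple[tuple[int, ...], tuple[str, ...]]]:
        return ann.default_candidate_grid(
            self.search_max_hidden_layers, self.search_sizes, self.search_transfers
        )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(out: Path, stage: str, *names: str) -> list[Path]:
    paths = []
    for name in names:
        p = out / name
        if not p.exists():
            raise StageInputError(stage, f"missing input {name}; run the earlier stages first")
        paths.append(p)
    return paths


def _registry_from_csv(path: Path) -> synth.CompoundRegistry:
    df = pd.read_csv(path)
    return synth.CompoundRegistry(
        tuple(
            synth.Compound(int(r.compound_id), int(r.kinase_target), str(r.target_name))
            for r in df.itertuples()
        )
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_generate(config: RunConfig) -> dict[str, Any]:
    """Synthesize the screen: registry, plate maps, traces, counts, truth."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(config.seed, "generate")
    registry = synth.make_registry(config.n_compounds, config.n_targets, seed)
    model = synth.sample_effect_model(registry, config.concentrations, seed + 1)
    plates = synth.make_plate_maps(
        registry, config.concentrations, config.replicates, config.n_blank
    )
    params = config.trace_params()

    # trace/count artifacts use plate-qualified well keys ("P01:A1") so the
    # long CSVs stay unambiguous across plates
    all_traces, all_counts = [], []
    well_index = 0
    for plate in plates:
        for well in plate.wells:
            wseed = seed + 10_000 + well_index
            key = f"{plate.plate_id}:{well.well_id}"
            tr = synth.well_trace(
                model, well, params, seed=wseed, dt=config.trace_dt,
                duration=config.trace_duration, well_id=key,
            )
            all_traces.append(tr)
            all_counts.append(
                synth.synthesize_counts(
                    model,
                    well.compound_id,
                    well.concentration_uM,
                    config.baseline_total_cells,
                    seed=wseed + 500_000,
                    well_id=key,
                    lethal=well.role == "lethal_control",
                )
            )
            well_index += 1

    registry.to_frame().to_csv(out / "registry.csv", index=False)
    synth.write_plate_maps_csv(plates, registry, out / "plate_maps.csv")
    synth.write_traces_csv(all_traces, out / "traces.csv")
    synth.write_counts_csv(all_counts, out / "counts.csv")
    truth = pd.DataFrame(
        [
            (c.compound_id, c.kinase_target, model.planted_magnitude_score(c.compound_id))
            for c in registry.compounds
        ],
        columns=["compound_id", "kinase_target", "planted_magnitude_score"],
    )
    truth.to_csv(out / "planted_truth.csv", index=False, float_format="%.10g")
    log.info("[generate] %d plates, %d wells", len(plates), well_index)
    return {"n_plates": len(plates), "n_wells": well_index, "seed": seed}


def stage_traces(config: RunConfig) -> dict[str, Any]:
    """Extract peak count and magnitude per well with a blank-derived floor.

    The minimum peak amplitude comes from the non-beating lethal-control
    wells (the screen's no-transient wells), as multiplier x pooled SD of
    their detrended samples.
    """
    out = Path(config.out_dir)
    traces_csv, plates_csv = _require(out, "traces", "traces.csv", "plate_maps.csv")
    all_traces = traces.read_traces_csv(traces_csv, dt=config.trace_dt)
    plate_df = pd.read_csv(plates_csv)
    flat_wells = {
        f"{r.plate_id}:{r.well_id}"
        for r in plate_df.loc[plate_df.role == "lethal_control"].itertuples()
    }
    flat = [t for t in all_traces if t.well_id in flat_wells]
    if not flat:
        raise StageInputError("traces", "no lethal-control wells to estimate the noise floor")
    floor = traces.estimate_noise_floor(flat, config.noise_floor_multiplier)
    feats = [traces.detect_peaks(t, floor) for t in all_traces]
    traces.write_features_csv(feats, out / "features.csv")
    log.info("[traces] noise floor %.4g over %d wells", floor, len(feats))
    return {"noise_floor": floor, "n_wells": len(feats)}


def stage_screen(config: RunConfig) -> dict[str, Any]:
    """Normalize endpoints against blank wells and code SD bands."""
    out = Path(config.out_dir)
    feats_csv, counts_csv, plates_csv, registry_csv = _require(
        out, "screen", "features.csv", "counts.csv", "plate_maps.csv", "registry.csv"
    )
    feats_df = pd.read_csv(feats_csv)
    features = {
        str(r.well_id): traces.PeakFeatures(
            str(r.well_id), int(r.peak_count), float(r.mean_peak_magnitude),
            np.array([]), np.array([]), float(r.noise_floor),
        )
        for r in feats_df.itertuples()
    }
    counts_df = pd.read_csv(counts_csv)
    counts = {
        str(r.well_id): synth.CellCounts(str(r.well_id), int(r.total_cells), int(r.dead_cells))
        for r in counts_df.itertuples()
    }
    registry = _registry_from_csv(registry_csv)
    plate_df = pd.read_csv(plates_csv)
    plates = []
    for pid, grp in plate_df.groupby("plate_id", sort=True):
        wells = tuple(
            synth.Well(
                str(r.well_id),
                str(r.role),
                None if pd.isna(r.compound_id) else int(r.compound_id),
                None if pd.isna(r.concentration_uM) else float(r.concentration_uM),
                None if pd.isna(r.replicate) else int(r.replicate),
            )
            for r in grp.itertuples()
        )
        plates.append(synth.PlateMap(str(pid), wells))

    screen = stats.summarize_screen(
        plates, features, counts,
        well_key=lambda plate, well: f"{plate.plate_id}:{well.well_id}",
    )
    screen.to_csv(out / "screen.csv", index=False, float_format="%.10g")
    heat = stats.heatmap_matrix(screen, registry.to_frame())
    heat.to_csv(out / "heatmap.csv", index=False)
    log.info("[screen] %d condition x endpoint rows", len(screen))
    return {"n_rows": len(screen)}


def model_records(screen: pd.DataFrame, registry: synth.CompoundRegistry) -> pd.DataFrame:
    """Prediction-network records: one per (compound, concentration)."""
    wide = screen.pivot_table(
        index=["compound_id", "concentration_uM"],
        columns="endpoint",
        values="normalized_mean",
        aggfunc="mean",
    ).reset_index()
    wide = wide.rename(
        columns={
            "frequency": "norm_frequency",
            "cell_viability": "norm_viability",
            "live_cell_count": "norm_live_cells",
            "peak_magnitude": "norm_peak_magnitude",
        }
    )
    tmap = {c.compound_id: c.kinase_target for c in registry.compounds}
    wide["kinase_target"] = wide["compound_id"].map(tmap).astype(float)
    cols = ["compound_id", *ann.MODEL_INPUTS, ann.MODEL_OUTPUT]
    return wide[cols].dropna().reset_index(drop=True)


def stage_train(config: RunConfig) -> dict[str, Any]:
    """Architecture search + final prediction network; 3 control networks."""
    out = Path(config.out_dir)
    screen_csv, registry_csv = _require(out, "train", "screen.csv", "registry.csv")
    screen = pd.read_csv(screen_csv)
    registry = _registry_from_csv(registry_csv)
    records = model_records(screen, registry)
    if len(records) < 2:
        raise StageInputError("train", "not enough model records to split")
    seed = stage_seed(config.seed, "train")
    lm = ann.LMConfig(max_epochs=config.max_epochs)
    candidates = config.candidates()
    if not candidates:
        raise InvalidArgumentError("candidate grid must be nonempty")

    X = records[list(ann.MODEL_INPUTS)].to_numpy(dtype=float)
    y = records[ann.MODEL_OUTPUT].to_numpy(dtype=float)
    results = ann.architecture_search(
        X, y, candidates, lm, config.train_fraction, seed, config.n_restarts
    )
    best = results[0]
    pd.DataFrame(
        [
            (r.architecture, r.train_rmse, r.test_rmse, r.test_r2, r.epochs, r.status)
            for r in results
        ],
        columns=["architecture", "train_rmse", "test_rmse", "test_r2", "epochs", "status"],
    ).to_csv(out / "search_report.csv", index=False, float_format="%.10g")
    save_model(best, out / "model.json", n_records=len(records))

    # control networks: one per concentration, viability from live cells + target
    control_metrics = {}
    for i, conc in enumerate(sorted(records["concentration_uM"].unique())):
        sub = records[records["concentration_uM"] == conc]
        Xc = sub[list(ann.CONTROL_INPUTS)].to_numpy(dtype=float)
        yc = sub[ann.CONTROL_OUTPUT].to_numpy(dtype=float)
        if len(yc) < 2:
            continue
        Xtr, ytr, Xte, yte = ann.split(Xc, yc, config.train_fraction, seed + 71 + i)
        res = ann.fit(Xtr, ytr, Xte, yte, hidden=(5,), config=lm, seed=seed + 911 + i,
                      n_restarts=config.n_restarts)
        control_metrics[f"{conc:g}uM"] = {
            "test_rmse": res.test_rmse,
            "test_r2": res.test_r2,
            "architecture": res.architecture,
        }
    (out / "control_models.json").write_text(
        json.dumps(control_metrics, indent=2, sort_keys=True), encoding="utf-8"
    )
    log.info(
        "[train] best %s: test RMSE %.4g, test R^2 %.4g",
        best.architecture, best.test_rmse, best.test_r2,
    )
    return {
        "n_records": len(records),
        "best_architecture": best.architecture,
        "train_rmse": best.train_rmse,
        "test_rmse": best.test_rmse,
        "test_r2": best.test_r2,
        "seed": seed,
    }


def save_model(result: ann.FitResult, path: str | Path, n_records: int | None = None) -> None:
    net = result.network
    payload = {
        "layer_sizes": list(net.layer_sizes),
        "transfers": net.transfers,
        "weights": [W.tolist() for W in net.weights],
        "biases": [b.tolist() for b in net.biases],
        "x_offset": net.x_offset.tolist() if net.x_offset is not None else None,
        "x_scale": net.x_scale.tolist() if net.x_scale is not None else None,
        "y_offset": net.y_offset,
        "y_scale": net.y_scale,
        "metrics": {
            "train_rmse": result.train_rmse,
            "test_rmse": result.test_rmse,
            "test_r2": result.test_r2,
            "epochs": result.epochs,
            "status": result.status,
        },
        "seed": result.seed,
        "n_records": n_records,
        "version": __version__,
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def load_model(path: str | Path) -> ann.MLPNetwork:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    return ann.MLPNetwork(
        [np.asarray(W, dtype=float) for W in d["weights"]],
        [np.asarray(b, dtype=float) for b in d["biases"]],
        list(d["transfers"]),
        np.asarray(d["x_offset"], dtype=float) if d["x_offset"] is not None else None,
        np.asarray(d["x_scale"], dtype=float) if d["x_scale"] is not None else None,
        float(d["y_offset"]),
        float(d["y_scale"]),
    )


def stage_predict(config: RunConfig) -> dict[str, Any]:
    """Evaluate the trained network over the constrained design grid."""
    out = Path(config.out_dir)
    model_json, registry_csv = _require(out, "predict", "model.json", "registry.csv")
    net = load_model(model_json)
    registry = _registry_from_csv(registry_csv)
    grid = ranking.build_grid(registry, config.grid_levels())
    preds = ranking.predict_grid(net, grid)
    ranking.write_predictions_csv(preds, out / "predictions.csv")
    log.info("[predict] %d rows (%d per compound)", grid.n_rows, grid.rows_per_compound)
    return {"rows_per_compound": grid.rows_per_compound, "n_rows": grid.n_rows}


def stage_rank(config: RunConfig) -> dict[str, Any]:
    """Order compounds by mean predicted normalized peak magnitude."""
    out = Path(config.out_dir)
    preds_csv, registry_csv = _require(out, "rank", "predictions.csv", "registry.csv")
    preds = pd.read_csv(preds_csv)
    registry = _registry_from_csv(registry_csv)
    result = ranking.rank_compounds(preds, registry)
    ranking.write_ranking_csv(result, out / "ranking.csv")
    log.info(
        "[rank] least detrimental #%d, most detrimental #%d",
        result.least_detrimental, result.most_detrimental,
    )
    return {
        "least_detrimental": result.least_detrimental,
        "most_detrimental": result.most_detrimental,
        "n_compounds": len(result.table),
    }


def stage_biowire(config: RunConfig) -> dict[str, Any]:
    """Contractility metrics for engineered tissues under dose conditions.

    Emulates an acute dose-response: amplitude and slopes scale down with
    dose; per-metric one-way ANOVA with Fisher LSD against the untreated
    tissues flags dose effects.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(config.seed, "biowire")
    doses = [0.0, *config.concentrations]
    dose_scale = {d: 1.0 / (1.0 + 0.15 * d) for d in doses}

    rows, metric_values = [], {}
    for di, dose in enumerate(doses):
        s = dose_scale[dose]
        for rep in range(config.biowire_replicates):
            tr = synth.synthesize_force_trace(
                amplitude=config.biowire_amplitude_uN * s,
                pacing_hz=config.biowire_pacing_hz,
                contraction_slope=config.biowire_contraction_slope * s,
                relaxation_slope=config.biowire_relaxation_slope * s,
                duration=config.biowire_duration_s,
                dt=config.biowire_dt,
                noise_sd=config.biowire_noise_sd,
                seed=seed + 100 * di + rep,
                tissue_id=f"tissue_d{dose:g}_r{rep + 1}",
            )
            m = traces.contraction_metrics(tr)
            rows.append((m.tissue_id, dose, m.active_tension, m.beat_duration,
                         m.contraction_slope, m.relaxation_slope))
            metric_values.setdefault(dose, []).append(m)
    df = pd.DataFrame(
        rows,
        columns=["tissue_id", "dose_uM", "active_tension", "beat_duration_s",
                 "contraction_slope", "relaxation_slope"],
    )
    df.to_csv(out / "biowire_metrics.csv", index=False, float_format="%.10g")

    anova_rows = []
    for metric in ("active_tension", "beat_duration_s", "contraction_slope", "relaxation_slope"):
        groups = [df.loc[df.dose_uM == d, metric].to_list() for d in doses]
        res = stats.anova_lsd(groups, control_index=0)
        for comp in res.comparisons:
            anova_rows.append(
                (metric, doses[comp.group_index], res.f_statistic, res.p_value,
                 comp.mean_diff, comp.p_value, comp.significant)
            )
    pd.DataFrame(
        anova_rows,
        columns=["metric", "dose_uM", "anova_F", "anova_p", "mean_diff_vs_control",
                 "lsd_p", "significant"],
    ).to_csv(out / "biowire_anova.csv", index=False, float_format="%.10g")
    log.info("[biowire] %d tissues over %d doses", len(df), len(doses))
    return {"n_tissues": len(df), "n_doses": len(doses), "seed": seed}


_STAGE_FUNCS = {
    "generate": stage_generate,
    "traces": stage_traces,
    "screen": stage_screen,
    "train": stage_train,
    "predict": stage_predict,
    "rank": stage_rank,
    "biowire": stage_biowire,
}

_STAGE_OUTPUTS = {
    "generate": ("registry.csv", "plate_maps.csv", "traces.csv", "counts.csv", "planted_truth.csv"),
    "traces": ("features.csv",),
    "screen": ("screen.csv", "heatmap.csv"),
    "train": ("model.json", "search_report.csv", "control_models.json"),
    "predict": ("predictions.csv",),
    "rank": ("ranking.csv",),
    "biowire": ("biowire_metrics.csv", "biowire_anova.csv"),
}


def run_stage(name: str, config: RunConfig) -> dict[str, Any]:
    if name not in _STAGE_FUNCS:
        raise InvalidArgumentError(f"unknown stage {name!r}")
    return _STAGE_FUNCS[name](config)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage in order and write the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    for name in STAGES:
        metrics = run_stage(name, config)
        outputs = {}
        for fname in _STAGE_OUTPUTS[name]:
            p = out / fname
            outputs[fname] = {"path": str(p), "sha256": _sha256(p)}
        manifest["stages"][name] = {
            "metrics": metrics,
            "outputs": outputs,
            "seed": stage_seed(config.seed, name),
        }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
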