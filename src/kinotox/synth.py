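"""Synthetic monolayer screen with a planted ground-truth effect model.

Everything downstream of the wet lab is testable against this module: it
generates the blinded compound registry (80 inhibitors over 23 kinase
targets by default), 384-well plate maps with the five reference-compound
roles, per-well calcium-flux traces (0.1 s sampling, 40 s window),
live/dead cell counts, and piecewise-linear engineered-tissue force
traces.  The planted effect model records the true per-compound effect on
every endpoint so that recovery can be asserted exactly at zero noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from kinotox.errors import InvalidArgumentError

#: the three screening concentrations, in micromolar
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (0.1, 1.0, 10.0)

#: well roles carried by every plate (reference compounds + medium blanks)
REFERENCE_ROLES: tuple[str, ...] = (
    "blank",
    "vehicle",
    "positive_chronotrope",
    "negative_chronotrope",
    "lethal_control",
)

ROLES: tuple[str, ...] = ("test",) + REFERENCE_ROLES

_PLATE_ROWS = tuple("ABCDEFGHIJKLMNOP")  # 16 rows
_PLATE_COLS = tuple(range(1, 25))  # 24 columns
_CONTROL_COLS = 2  # columns 1-2 reserved for reference/blank wells


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Compound:
    compound_id: int
    kinase_target: int
    target_name: str


@dataclass(frozen=True)
class CompoundRegistry:
    """Blinded compound labels mapped to integer-coded kinase targets."""

    compounds: tuple[Compound, ...]

    def __post_init__(self) -> None:
        ids = [c.compound_id for c in self.compounds]
        if len(set(ids)) != len(ids):
            raise InvalidArgumentError("compound_ids must be unique")

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def targets(self) -> tuple[int, ...]:
        return tuple(sorted({c.kinase_target for c in self.compounds}))

    def target_of(self, compound_id: int) -> int:
        for c in self.compounds:
            if c.compound_id == compound_id:
                return c.kinase_target
        raise KeyError(compound_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.compound_id, c.kinase_target, c.target_name) for c in self.compounds],
            columns=["compound_id", "kinase_target", "target_name"],
        )


def make_registry(n_compounds: int = 80, n_targets: int = 23, seed: int = 0) -> CompoundRegistry:
    """Create a blinded registry with every target covered by >= 1 compound.

    Compound ids are 1..n (the blinded experimental numbers); target codes
    are 0..n_targets-1.  Deterministic under ``seed``.
    """
    if n_targets < 1 or n_compounds < n_targets:
        raise InvalidArgumentError(
            f"need n_compounds >= n_targets >= 1, got {n_compounds}, {n_targets}"
        )
    rng = np.random.default_rng(seed)
    # one compound per target guarantees coverage; the rest are assigned at random
    assignment = list(range(n_targets))
    assignment += list(rng.integers(0, n_targets, size=n_compounds - n_targets))
    rng.shuffle(assignment)
    compounds = tuple(
        Compound(i + 1, int(t), f"kinase_target_{t:02d}") for i, t in enumerate(assignment)
    )
    return CompoundRegistry(compounds)


# ---------------------------------------------------------------------------
# effect model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EndpointEffects:
    """Multiplicative effects of one (compound, concentration) condition."""

    viability: float
    live_cells: float
    magnitude: float
    frequency: float

    def __post_init__(self) -> None:
        for name in ("viability", "live_cells", "magnitude", "frequency"):
            v = getattr(self, name)
            if not (v >= 0.0 and math.isfinite(v)):
                raise InvalidArgumentError(f"effect multiplier {name}={v} must be >= 0")


_NEUTRAL = EndpointEffects(1.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class EffectModel:
    """Planted ground truth: per-condition multipliers plus well-level noise.

    ``noise_cv`` holds a per-endpoint coefficient of variation for the
    log-normal well noise; identical seeds give bit-identical draws.
    """

    effects: Mapping[tuple[int, float], EndpointEffects]
    noise_cv: Mapping[str, float] = field(
        default_factory=lambda: {
            "viability": 0.02,
            "live_cells": 0.05,
            "magnitude": 0.05,
            "frequency": 0.02,
        }
    )
    seed: int = 0
    control_viability: float = 0.9

    def effect(self, compound_id: int | None, concentration: float | None) -> EndpointEffects:
        if compound_id is None or concentration is None:
            return _NEUTRAL
        return self.effects[(compound_id, float(concentration))]

    def planted_magnitude_score(self, compound_id: int) -> float:
        """Mean normalized-magnitude ground truth over the tested doses.

        At zero noise the normalized peak magnitude of a condition equals
        multiplier - 1, so the per-compound mean of that quantity is the
        planted counterpart of the design-grid ranking score.
        """
        vals = [
            e.magnitude - 1.0
            for (cid, _), e in self.effects.items()
            if cid == compound_id
        ]
        if not vals:
            raise KeyError(compound_id)
        return float(np.mean(vals))


def _smooth_target_profile(n_targets: int, rng: np.random.Generator) -> np.ndarray:
    """A smooth random signed effect strength over the target-code axis.

    Low-order Fourier series in the (arbitrary) target index, so the
    planted surface is learnable from the integer target code.
    """
    t = np.arange(n_targets) / max(n_targets, 1)
    out = np.zeros(n_targets)
    for k in (1, 2, 3):
        out += rng.normal(0, 1.0 / k) * np.sin(2 * np.pi * k * t + rng.uniform(0, 2 * np.pi))
    return out


def sample_effect_model(
    registry: CompoundRegistry,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    seed: int = 0,
    noise_cv: Mapping[str, float] | None = None,
    control_viability: float = 0.9,
) -> EffectModel:
    """Draw a planted effect model reproducing the observed effect classes.

    Per-target signed effect strengths vary smoothly with the target code;
    each compound scales its target's profile by a potency factor.  Dose
    response enters through h(c) = log10(c / c_min) so the 0.1/1/10 uM
    doses map to increasing effect.  Most conditions show no effect or a
    mild decrease in viability / live cells / frequency, while a subset of
    targets produces a strong increase in transient magnitude.
    """
    rng = np.random.default_rng(seed)
    n_t = len(registry.targets)
    mag_profile = 0.9 * _smooth_target_profile(n_t, rng)
    viab_profile = 0.15 * _smooth_target_profile(n_t, rng)
    freq_profile = 0.1 * _smooth_target_profile(n_t, rng)

    conc = [float(c) for c in concentrations]
    c_min = min(conc)

    effects: dict[tuple[int, float], EndpointEffects] = {}
    for comp in registry.compounds:
        t = comp.kinase_target
        # magnitude potency independent of the side-channel potency, so the
        # viability/frequency endpoints carry no extra magnitude information
        p_mag = rng.uniform(0.7, 1.3)
        p_side = rng.uniform(0.7, 1.3)
        for c in conc:
            h = math.log10(c / c_min) / 2.0 if c > c_min else 0.0
            viab = math.exp(viab_profile[t] * p_side * h)
            effects[(comp.compound_id, c)] = EndpointEffects(
                viability=min(viab, 1.0 / max(control_viability, 1e-9)),
                live_cells=math.exp((viab_profile[t] - 0.05) * p_side * h),
                magnitude=math.exp(mag_profile[t] * p_mag * h),
                frequency=math.exp(freq_profile[t] * p_side * h),
            )
    return EffectModel(
        effects=effects,
        noise_cv=dict(noise_cv) if noise_cv is not None else EffectModel.__dataclass_fields__[
            "noise_cv"
        ].default_factory(),
        seed=seed,
        control_viability=control_viability,
    )


# ---------------------------------------------------------------------------
# plate maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Well:
    well_id: str
    role: str
    compound_id: int | None
    concentration_uM: float | None
    replicate: int | None


@dataclass(frozen=True)
class PlateMap:
    plate_id: str
    wells: tuple[Well, ...]

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise InvalidArgumentError("well_ids must be unique within a plate")
        for w in self.wells:
            row, col = w.well_id[0], int(w.well_id[1:])
            if row not in _PLATE_ROWS or col not in _PLATE_COLS:
                raise InvalidArgumentError(f"well {w.well_id} outside the 384-well grid")

    def wells_by_role(self, role: str) -> list[Well]:
        return [w for w in self.wells if w.role == role]


def _well_id(index: int, start_col: int = 1) -> str:
    """Row-major well label over the 384-well grid starting at start_col."""
    n_cols = len(_PLATE_COLS) - (start_col - 1)
    row = _PLATE_ROWS[index // n_cols]
    col = start_col + index % n_cols
    return f"{row}{col}"


def make_plate_maps(
    registry: CompoundRegistry,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    replicates: int = 3,
    n_blank: int = 6,
    wells_per_reference: int = 3,
) -> list[PlateMap]:
    """Lay out the screen over as many 384-well plates as needed.

    Columns 1-2 of every plate are reserved for the blank wells and the
    four reference-compound roles; test wells fill the remaining columns
    row-major ordered by (compound, concentration, replicate).  Plates are
    split automatically when test demand exceeds capacity.
    """
    if replicates < 1:
        raise InvalidArgumentError("replicates must be >= 1")
    conc = [float(c) for c in concentrations]
    if not conc:
        raise InvalidArgumentError("concentrations must be nonempty")
    if n_blank < 3:
        raise InvalidArgumentError("need >= 3 blank wells per plate")

    control_wells: list[tuple[str, str]] = [("blank", "")] * n_blank
    for role in ("vehicle", "positive_chronotrope", "negative_chronotrope", "lethal_control"):
        control_wells += [(role, "")] * wells_per_reference
    control_capacity = len(_PLATE_ROWS) * _CONTROL_COLS
    if len(control_wells) > control_capacity:
        raise InvalidArgumentError("control block does not fit in the reserved columns")

    test_conditions = [
        (comp.compound_id, c, r)
        for comp in registry.compounds
        for c in conc
        for r in range(1, replicates + 1)
    ]
    test_capacity = len(_PLATE_ROWS) * (len(_PLATE_COLS) - _CONTROL_COLS)

    plates: list[PlateMap] = []
    for p_start in range(0, len(test_conditions), test_capacity):
        chunk = test_conditions[p_start : p_start + test_capacity]
        plate_id = f"P{len(plates) + 1:02d}"
        wells: list[Well] = []
        for i, (role, _) in enumerate(control_wells):
            row = _PLATE_ROWS[i % len(_PLATE_ROWS)]
            col = 1 + i // len(_PLATE_ROWS)
            wells.append(Well(f"{row}{col}", role, None, None, None))
        for i, (cid, c, r) in enumerate(chunk):
            wells.append(Well(_well_id(i, start_col=_CONTROL_COLS + 1), "test", cid, c, r))
        plates.append(PlateMap(plate_id, tuple(wells)))
    return plates


# ---------------------------------------------------------------------------
# calcium traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceParams:
    """Control-well calcium-transient morphology.

    Fluorescence is in arbitrary plate-reader units; the transient is a
    Gaussian bump (truncated at 4 widths) on a flat baseline.
    """

    baseline: float = 100.0
    amplitude: float = 25.0
    frequency_hz: float = 1.0
    peak_width_s: float = 0.1
    noise_sd: float = 0.5


@dataclass(frozen=True)
class CalciumTrace:
    well_id: str
    samples: np.ndarray
    dt: float = 0.1
    duration: float = 40.0
    truth: dict | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("trace samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt


def synthesize_trace(
    model: EffectModel | None,
    compound_id: int | None,
    concentration: float | None,
    params: TraceParams = TraceParams(),
    seed: int = 0,
    dt: float = 0.1,
    duration: float = 40.0,
    well_id: str = "",
) -> CalciumTrace:
    """Synthesize one calcium-flux trace with known planted peaks.

    The effective amplitude/frequency are the control parameters times the
    planted multipliers for (compound, concentration); a null compound
    gives a blank-well trace at control parameters.  Ground truth (peak
    count, amplitude, frequency) travels on ``trace.truth``.
    """
    if params.amplitude < 0 or params.noise_sd < 0:
        raise InvalidArgumentError("amplitude and noise sd must be >= 0")
    if params.frequency_hz < 0:
        raise InvalidArgumentError("frequency must be >= 0")
    n = round(duration / dt)
    if abs(n * dt - duration) > 1e-9:
        raise InvalidArgumentError("dt must divide duration")

    eff = model.effect(compound_id, concentration) if model is not None else _NEUTRAL
    amp = params.amplitude * eff.magnitude
    freq = params.frequency_hz * eff.frequency

    t = np.arange(n + 1) * dt  # includes t=0: 401 samples for 40 s at 0.1 s
    y = np.full_like(t, params.baseline, dtype=float)

    n_peaks = math.floor(duration * freq) if freq > 0 else 0
    centers = (np.arange(n_peaks) + 0.5) / freq if n_peaks else np.array([])
    w = params.peak_width_s
    for c in centers:
        mask = np.abs(t - c) <= 4.0 * w
        y[mask] += amp * np.exp(-0.5 * ((t[mask] - c) / w) ** 2)

    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, params.noise_sd, size=y.shape)

    truth = {
        "peak_count": int(n_peaks),
        "amplitude": float(amp),
        "frequency_hz": float(freq),
        "baseline": float(params.baseline),
    }
    return CalciumTrace(well_id=well_id, samples=y, dt=dt, duration=duration, truth=truth)


#: role-specific overrides for reference wells (relative to control params)
_ROLE_EFFECTS: dict[str, tuple[float, float]] = {
    # role: (amplitude multiplier, frequency multiplier)
    "blank": (1.0, 1.0),
    "vehicle": (1.0, 1.0),
    "positive_chronotrope": (1.0, 1.5),
    "negative_chronotrope": (0.2, 0.5),
    "lethal_control": (0.0, 0.0),  # 10% ethanol: loss of viability, no transients
}


def well_trace(
    model: EffectModel,
    well: Well,
    params: TraceParams = TraceParams(),
    seed: int = 0,
    dt: float = 0.1,
    duration: float = 40.0,
    well_id: str | None = None,
) -> CalciumTrace:
    """Trace for one plate well, honouring its role and planted effects."""
    if well.role == "test":
        base = params
        cid, conc = well.compound_id, well.concentration_uM
    else:
        amp_m, freq_m = _ROLE_EFFECTS[well.role]
        base = TraceParams(
            baseline=params.baseline,
            amplitude=params.amplitude * amp_m,
            frequency_hz=params.frequency_hz * freq_m,
            peak_width_s=params.peak_width_s,
            noise_sd=params.noise_sd,
        )
        cid, conc = None, None
    return synthesize_trace(
        model, cid, conc, base, seed=seed, dt=dt, duration=duration,
        well_id=well.well_id if well_id is None else well_id,
    )


# ---------------------------------------------------------------------------
# cell counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellCounts:
    well_id: str
    total_cells: int
    dead_cells: int

    def __post_init__(self) -> None:
        if self.total_cells < 0 or self.dead_cells < 0:
            raise InvalidArgumentError("counts must be nonnegative")
        if self.dead_cells > self.total_cells:
            raise InvalidArgumentError("dead_cells must be <= total_cells")


def synthesize_counts(
    model: EffectModel,
    compound_id: int | None,
    concentration: float | None,
    baseline_total: int = 8000,
    seed: int = 0,
    well_id: str = "",
    lethal: bool = False,
) -> CellCounts:
    """Total/dead nuclei counts for one well after 24 h exposure.

    Live cells scale with the planted live-cell multiplier and log-normal
    well noise; viability scales with the viability multiplier (clipped to
    [0, 1]).  At zero noise and unit multipliers the closed form holds:
    total = baseline_total, dead = (1 - control_viability) * total.
    """
    if baseline_total <= 0:
        raise InvalidArgumentError("baseline_total must be > 0")
    eff = model.effect(compound_id, concentration)
    rng = np.random.default_rng(seed)

    viab_mult = 0.0 if lethal else eff.viability
    live_mult = 0.0 if lethal else eff.live_cells
    cv_l = model.noise_cv.get("live_cells", 0.0)
    cv_v = model.noise_cv.get("viability", 0.0)
    noise_l = math.exp(rng.normal(0.0, cv_l)) if cv_l > 0 else 1.0
    noise_v = math.exp(rng.normal(0.0, cv_v)) if cv_v > 0 else 1.0

    v = float(np.clip(model.control_viability * viab_mult * noise_v, 0.0, 1.0))
    if v <= 0.0 or live_mult <= 0.0:
        total = int(round(baseline_total * max(noise_l, 0.0)))
        return CellCounts(well_id, total, total)

    live = baseline_total * model.control_viability * live_mult * noise_l
    total = int(round(live / v))
    dead = total - int(round(live))
    dead = max(0, min(dead, total))
    return CellCounts(well_id, total, dead)


# ---------------------------------------------------------------------------
# force traces (engineered tissue)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceTrace:
    tissue_id: str
    samples: np.ndarray
    dt: float
    pacing_frequency: float
    truth: dict | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("force samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt


def synthesize_force_trace(
    amplitude: float = 10.0,
    pacing_hz: float = 1.0,
    contraction_slope: float = 100.0,
    relaxation_slope: float = 50.0,
    duration: float = 10.0,
    dt: float = 0.01,
    noise_sd: float = 0.0,
    seed: int = 0,
    tissue_id: str = "",
) -> ForceTrace:
    """Piecewise-linear paced force trace in microNewtons.

    Each beat rises from baseline 0 at ``contraction_slope`` to
    ``amplitude`` then falls at ``relaxation_slope``; the implied beat
    duration (rise + fall) must fit within the pacing period.  Ground
    truth metrics travel on ``trace.truth``.
    """
    if contraction_slope <= 0 or relaxation_slope <= 0:
        raise InvalidArgumentError("slopes must be > 0")
    if amplitude < 0:
        raise InvalidArgumentError("amplitude must be >= 0")
    if pacing_hz <= 0:
        raise InvalidArgumentError("pacing frequency must be > 0")
    t_rise = amplitude / contraction_slope
    t_fall = amplitude / relaxation_slope
    period = 1.0 / pacing_hz
    if t_rise + t_fall > period + 1e-12:
        raise InvalidArgumentError(
            f"beat duration {t_rise + t_fall:.3f}s exceeds pacing period {period:.3f}s"
        )

    t = np.arange(round(duration / dt) + 1) * dt
    phase = np.mod(t, period)
    y = np.zeros_like(t)
    rise = phase <= t_rise
    fall = (phase > t_rise) & (phase <= t_rise + t_fall)
    if amplitude > 0:
        y[rise] = contraction_slope * phase[rise]
        y[fall] = amplitude - relaxation_slope * (phase[fall] - t_rise)
        # the fall expression can leave -1e-15-scale dust at the resting level
        y[np.abs(y) < 1e-12 * max(amplitude, 1.0)] = 0.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)

    truth = {
        "active_tension": float(amplitude),
        "beat_duration": float(0.9 * (t_rise + t_fall)) if amplitude > 0 else 0.0,
        "contraction_slope": float(contraction_slope),
        "relaxation_slope": float(relaxation_slope),
        "n_beats": int(math.floor(duration * pacing_hz)),
    }
    return ForceTrace(tissue_id, y, dt, pacing_hz, truth=truth)


# ---------------------------------------------------------------------------
# planted smooth surface (direct regression fixture)
# ---------------------------------------------------------------------------

def planted_surface_dataset(
    n: int = 240, seed: int = 0, noise_sd: float = 0.1, n_targets: int = 23
) -> tuple[np.ndarray, np.ndarray]:
    """Records drawn from a known smooth effect surface plus Gaussian noise.

    Columns follow the model-record layout (concentration uM, kinase
    target code, normalized frequency, normalized viability, normalized
    live cells); the response is a smooth function of all five, so a
    held-out fit quantifies how well the network recovers the surface.
    """
    rng = np.random.default_rng(seed)
    conc = 10.0 ** rng.uniform(-1, 1, size=n)
    target = rng.integers(0, n_targets, size=n).astype(float)
    freq = rng.normal(0.0, 0.05, size=n)
    viab = rng.normal(0.0, 0.05, size=n)
    live = viab + rng.normal(0.0, 0.02, size=n)
    X = np.column_stack([conc, target, freq, viab, live])
    # effect scale matches the screen's normalized-magnitude dynamic range
    # (multiplicative effects up to ~e^1.2 give normalized values in [-0.7, 2.3])
    y = (
        2.0 * np.sin(np.pi * target / n_targets) * np.tanh(np.log10(conc))
        + 3.0 * viab
        - 2.5 * freq
        + 1.0 * live
    )
    y = y + rng.normal(0.0, noise_sd, size=n)
    return X, y


# ---------------------------------------------------------------------------
# CSV writers (UTF-8, '.' decimal separator, exact headers)
# ---------------------------------------------------------------------------

def plate_maps_frame(plates: Iterable[PlateMap], registry: CompoundRegistry) -> pd.DataFrame:
    rows = []
    targets = {c.compound_id: c.kinase_target for c in registry.compounds}
    for plate in plates:
        for w in plate.wells:
            rows.append(
                (
                    plate.plate_id,
                    w.well_id,
                    w.role,
                    w.compound_id,
                    targets.get(w.compound_id) if w.compound_id is not None else None,
                    w.concentration_uM,
                    w.replicate,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "plate_id",
            "well_id",
            "role",
            "compound_id",
            "kinase_target",
            "concentration_uM",
            "replicate",
        ],
    )


def write_plate_maps_csv(plates: Iterable[PlateMap], registry: CompoundRegistry, path: str | Path) -> None:
    plate_maps_frame(plates, registry).to_csv(path, index=False, float_format="%.10g")


def traces_frame(traces: Iterable[CalciumTrace | ForceTrace], id_col: str = "well_id") -> pd.DataFrame:
    frames = []
    for tr in traces:
        ident = tr.well_id if isinstance(tr, CalciumTrace) else tr.tissue_id
        frames.append(pd.DataFrame({id_col: ident, "t_s": tr.times, "value": tr.samples}))
    return pd.concat(frames, ignore_index=True)


def write_traces_csv(traces: Iterable[CalciumTrace], path: str | Path) -> None:
    traces_frame(traces).to_csv(path, index=False, float_format="%.10g")


def write_counts_csv(counts: Iterable[CellCounts], path: str | Path) -> None:
    pd.DataFrame(
        [(c.well_id, c.total_cells, c.dead_cells) for c in counts],
        columns=["well_id", "total_cells", "dead_cells"],
    ).to_csv(path, index=False)
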