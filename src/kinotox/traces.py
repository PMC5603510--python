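"""Endpoint extraction from calcium-flux and tissue-force traces.

Calcium endpoints: peak count over the 40 s window and mean peak
magnitude, where a peak's magnitude is its maximum minus the local
baseline (the minimum of the preceding inter-peak valley) and only peaks
whose prominence clears a blank-derived noise floor are counted.

Force endpoints per beat: active tension (beat maximum minus beat
baseline), beat duration (time spent above baseline + 10% of active
tension), and the maximum instantaneous contraction/relaxation rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import detrend, find_peaks

from kinotox.errors import InvalidArgumentError, NoBeatsError
from kinotox.synth import CalciumTrace, ForceTrace


@dataclass(frozen=True)
class PeakFeatures:
    well_id: str
    peak_count: int
    mean_peak_magnitude: float  # NaN when peak_count == 0
    peak_times: np.ndarray
    peak_magnitudes: np.ndarray
    noise_floor_used: float

    def frequency(self, duration: float) -> float:
        """Peak count per second over a window of the given duration."""
        return self.peak_count / duration if duration > 0 else 0.0


@dataclass(frozen=True)
class ContractionMetrics:
    tissue_id: str
    active_tension: float
    beat_duration: float
    contraction_slope: float
    relaxation_slope: float
    n_beats: int


def estimate_noise_floor(blank_traces: Sequence[CalciumTrace], multiplier: float = 3.0) -> float:
    """Minimum peak amplitude implied by non-beating control wells.

    Returns ``multiplier`` times the pooled standard deviation of the
    linearly detrended samples of the given traces (the 3-sigma rule by
    default).  Constant traces give 0.
    """
    if len(blank_traces) == 0:
        raise InvalidArgumentError("need at least one blank trace")
    ss = 0.0
    dof = 0
    for tr in blank_traces:
        resid = detrend(np.asarray(tr.samples, dtype=float))
        n = len(resid)
        if n > 1:
            ss += float(np.sum((resid - resid.mean()) ** 2))
            dof += n - 1
    if dof == 0:
        return 0.0
    sd = float(np.sqrt(ss / dof))
    # Detrending a constant trace leaves machine-epsilon residue; snap
    # sub-epsilon spread (relative to signal level) to an exact zero.
    scale = max(float(np.max(np.abs(tr.samples))) for tr in blank_traces)
    if sd <= 1e-12 * max(scale, 1.0):
        return 0.0
    return multiplier * sd


def detect_peaks(
    trace: CalciumTrace, noise_floor: float = 0.0, smooth_window: int = 3
) -> PeakFeatures:
    """Count transients and measure their magnitudes above local baseline.

    A peak is a local maximum with prominence >= ``noise_floor``; its
    magnitude is the maximum minus the minimum of the valley separating it
    from the previous kept peak (trace start for the first peak).  Peaks
    whose maximum lies inside the window are counted, including partial
    edge transients.

    Peak *locations* are found on a centered moving average of
    ``smooth_window`` samples so that isolated noise excursions cannot
    register as transients, while magnitudes are always measured on the
    raw samples (a symmetric transient keeps its maximum under the
    centered average, so noiseless recovery stays exact).  Set
    ``smooth_window=1`` to disable the pre-filter.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise InvalidArgumentError("smooth_window must be a positive odd integer")
    y = np.asarray(trace.samples, dtype=float)
    if smooth_window > 1 and len(y) >= smooth_window:
        kernel = np.full(smooth_window, 1.0 / smooth_window)
        pad = smooth_window // 2
        padded = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
        y_det = np.convolve(padded, kernel, mode="valid")
    else:
        y_det = y
    prominence = noise_floor if noise_floor > 0 else None
    idx, _ = find_peaks(y_det, prominence=prominence)

    mags = []
    times = []
    prev = 0
    for p in idx:
        baseline = float(np.min(y[prev : p + 1]))
        mag = float(y[p] - baseline)
        if mag >= noise_floor:
            mags.append(mag)
            times.append(p * trace.dt)
            prev = p
    mags_arr = np.asarray(mags)
    times_arr = np.asarray(times)
    return PeakFeatures(
        well_id=trace.well_id,
        peak_count=len(mags),
        mean_peak_magnitude=float(np.mean(mags_arr)) if len(mags) else float("nan"),
        peak_times=times_arr,
        peak_magnitudes=mags_arr,
        noise_floor_used=float(noise_floor),
    )


def _crossing_time(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float | None:
    """Linearly interpolated first (rising) or last (falling) level crossing."""
    above = y >= level
    if rising:
        hits = np.nonzero(~above[:-1] & above[1:])[0]
        if len(hits) == 0:
            return float(t[0]) if above[0] else None
        i = hits[0]
    else:
        hits = np.nonzero(above[:-1] & ~above[1:])[0]
        if len(hits) == 0:
            return float(t[-1]) if above[-1] else None
        i = hits[-1]
    y0, y1 = y[i], y[i + 1]
    if y1 == y0:
        return float(t[i])
    frac = (level - y0) / (y1 - y0)
    return float(t[i] + frac * (t[i + 1] - t[i]))


def contraction_metrics(
    trace: ForceTrace,
    duration_threshold: float = 0.10,
    slope_method: str = "derivative",
    min_tension: float = 1e-9,
) -> ContractionMetrics:
    """Average per-beat contractility metrics of a paced force trace.

    Beats are segmented by the pacing period.  Per beat: active tension =
    max - min; beat duration = time above baseline + ``duration_threshold``
    of active tension; slopes are the extreme central-difference
    derivatives on the rise and fall (``slope_method='secant'`` uses the
    threshold-to-peak secant instead).  Metrics are averaged over beats;
    a trace with no beat above ``min_tension`` raises NoBeatsError.
    """
    if slope_method not in ("derivative", "secant"):
        raise InvalidArgumentError(f"unknown slope_method {slope_method!r}")
    y = np.asarray(trace.samples, dtype=float)
    t = trace.times
    period = 1.0 / trace.pacing_frequency
    per_beat = int(round(period / trace.dt))
    if per_beat < 3:
        raise InvalidArgumentError("pacing period must span >= 3 samples")
    n_beats = len(y) // per_beat
    if n_beats < 1:
        raise NoBeatsError("trace shorter than one pacing period")

    tensions, durations, up_slopes, down_slopes = [], [], [], []
    for b in range(n_beats):
        seg = y[b * per_beat : (b + 1) * per_beat + 1]
        ts = t[b * per_beat : (b + 1) * per_beat + 1]
        base = float(np.min(seg))
        tension = float(np.max(seg) - base)
        if tension < min_tension:
            continue
        level = base + duration_threshold * tension
        t_up = _crossing_time(ts, seg, level, rising=True)
        t_down = _crossing_time(ts, seg, level, rising=False)
        if t_up is None or t_down is None or t_down <= t_up:
            continue
        if slope_method == "derivative":
            grad = np.gradient(seg, trace.dt)
            up = float(np.max(grad))
            down = float(abs(np.min(grad)))
        else:
            p = int(np.argmax(seg))
            up = (seg[p] - level) / max(ts[p] - t_up, trace.dt)
            down = (seg[p] - level) / max(t_down - ts[p], trace.dt)
        tensions.append(tension)
        durations.append(t_down - t_up)
        up_slopes.append(up)
        down_slopes.append(down)

    if not tensions:
        raise NoBeatsError("no beat above the tension threshold")
    return ContractionMetrics(
        tissue_id=trace.tissue_id,
        active_tension=float(np.mean(tensions)),
        beat_duration=float(np.mean(durations)),
        contraction_slope=float(np.mean(up_slopes)),
        relaxation_slope=float(np.mean(down_slopes)),
        n_beats=len(tensions),
    )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_traces_csv(path: str | Path, dt: float | None = None, id_col: str = "well_id") -> list[CalciumTrace]:
    """Rebuild traces from the long-format trace CSV (well_id, t_s, value)."""
    df = pd.read_csv(path)
    out = []
    for wid, grp in df.groupby(id_col, sort=False):
        grp = grp.sort_values("t_s")
        tvals = grp["t_s"].to_numpy()
        step = dt if dt is not None else float(np.median(np.diff(tvals)))
        out.append(
            CalciumTrace(
                well_id=str(wid),
                samples=grp["value"].to_numpy(dtype=float),
                dt=step,
                duration=float(tvals[-1] - tvals[0]),
            )
        )
    return out


def features_frame(features: Iterable[PeakFeatures]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (f.well_id, f.peak_count, f.mean_peak_magnitude, f.noise_floor_used)
            for f in features
        ],
        columns=["well_id", "peak_count", "mean_peak_magnitude", "noise_floor"],
    )


def write_features_csv(features: Iterable[PeakFeatures], path: str | Path) -> None:
    features_frame(features).to_csv(path, index=False, float_format="%.10g")


def write_tissue_metrics_csv(metrics: Iterable[ContractionMetrics], path: str | Path) -> None:
    pd.DataFrame(
        [
            (m.tissue_id, m.active_tension, m.beat_duration, m.contraction_slope, m.relaxation_slope)
            for m in metrics
        ],
        columns=[
            "tissue_id",
            "active_tension",
            "beat_duration_s",
            "contraction_slope",
            "relaxation_slope",
        ],
    ).to_csv(path, index=False, float_format="%.10g")
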