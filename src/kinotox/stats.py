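"""Screen-level statistics: viability, blank normalization, SD bands, ANOVA.

Endpoints are normalized against the blank (medium-only) wells of the
same plate as (raw - blank mean) / blank mean, triplicates averaged, and
each (compound, concentration, endpoint) coded into a signed band
recording how many control standard deviations the triplicate mean sits
from the control mean (capped at +/-3).  Dose-response comparisons use
one-way ANOVA with Fisher's protected LSD against the control group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from kinotox.errors import DegenerateBlankError, InvalidArgumentError
from kinotox.synth import CellCounts, PlateMap
from kinotox.traces import PeakFeatures

ENDPOINTS = ("cell_viability", "live_cell_count", "peak_magnitude", "frequency")


def viability(counts: CellCounts) -> tuple[float, int]:
    """Viability fraction and live-cell count from total/dead nuclei."""
    if counts.total_cells <= 0:
        raise InvalidArgumentError("total_cells must be > 0")
    if counts.dead_cells > counts.total_cells:
        raise InvalidArgumentError("dead_cells must be <= total_cells")
    live = counts.total_cells - counts.dead_cells
    return live / counts.total_cells, live


def normalize(raw: float, blank_mean: float) -> float:
    """Dimensionless effect scale: (raw - blank mean) / blank mean."""
    if blank_mean == 0:
        raise DegenerateBlankError("blank mean is zero")
    return (raw - blank_mean) / blank_mean


def denormalize(normalized: float, blank_mean: float) -> float:
    return blank_mean * (normalized + 1.0)


def sd_band(triplicate_mean: float, control_mean: float, control_sd: float) -> int:
    """Signed 1/2/3-SD band of a triplicate mean relative to control."""
    if control_sd <= 0:
        raise InvalidArgumentError("control_sd must be > 0")
    z = (triplicate_mean - control_mean) / control_sd
    if z == 0:
        return 0
    return int(math.copysign(min(math.ceil(abs(z)), 3), z))


@dataclass(frozen=True)
class LsdComparison:
    group_index: int
    mean_diff: float
    t_statistic: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class AnovaLsdResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    ms_within: float
    comparisons: tuple[LsdComparison, ...]


def anova_lsd(
    groups: Sequence[Sequence[float]], control_index: int = 0, alpha: float = 0.05
) -> AnovaLsdResult:
    """One-way ANOVA with Fisher's protected LSD against the control group.

    Pairwise t statistics use the pooled within-group mean square; a
    comparison is flagged significant only when both the omnibus F test
    and the pairwise test reject at ``alpha`` (the protected variant).
    Degenerate all-constant data yields F = 0 and no significance.
    """
    if len(groups) < 2:
        raise InvalidArgumentError("need >= 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrs):
        raise InvalidArgumentError("every group needs >= 2 replicates")
    if not 0 <= control_index < len(arrs):
        raise InvalidArgumentError("control_index out of range")

    k = len(arrs)
    n_total = sum(len(a) for a in arrs)
    grand = float(np.concatenate(arrs).mean())
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs)
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w

    if ms_w == 0.0:
        if ms_b == 0.0:
            f_stat, p = 0.0, 1.0  # all values identical: nothing to test
        else:
            f_stat, p = float("inf"), 0.0
    else:
        f_stat = ms_b / ms_w
        p = float(sps.f.sf(f_stat, df_b, df_w))
    omnibus_reject = p < alpha

    comparisons = []
    ctrl = arrs[control_index]
    for i, a in enumerate(arrs):
        if i == control_index:
            continue
        diff = float(a.mean() - ctrl.mean())
        se = math.sqrt(ms_w * (1 / len(a) + 1 / len(ctrl))) if ms_w > 0 else 0.0
        if se == 0.0:
            t_stat = 0.0 if diff == 0 else math.copysign(float("inf"), diff)
            p_pair = 1.0 if diff == 0 else 0.0
        else:
            t_stat = diff / se
            p_pair = float(2 * sps.t.sf(abs(t_stat), df_w))
        comparisons.append(
            LsdComparison(i, diff, t_stat, p_pair, omnibus_reject and p_pair < alpha)
        )
    return AnovaLsdResult(f_stat, p, df_b, df_w, ms_w, tuple(comparisons))


# ---------------------------------------------------------------------------
# screen assembly
# ---------------------------------------------------------------------------

def well_endpoints(
    features: Mapping[str, PeakFeatures], counts: Mapping[str, CellCounts]
) -> pd.DataFrame:
    """Per-well raw endpoint table from trace features and cell counts.

    Frequency is the peak count over the 40 s window; peak magnitude is
    NaN for wells with zero detected peaks (excluded from averaging
    downstream rather than fabricated).
    """
    rows = []
    for wid, f in features.items():
        c = counts.get(wid)
        if c is None:
            continue
        v, live = viability(c)
        rows.append((wid, v, live, f.mean_peak_magnitude, f.peak_count))
    return pd.DataFrame(
        rows, columns=["well_id"] + list(ENDPOINTS)
    )


def summarize_screen(
    plates: Sequence[PlateMap],
    features: Mapping[str, PeakFeatures],
    counts: Mapping[str, CellCounts],
    control_role: str = "blank",
    well_key=None,
) -> pd.DataFrame:
    """Tidy per-condition table: raw mean, normalized mean, SD band.

    Control statistics (mean, SD) come from the ``control_role`` wells of
    the same plate.  One row per (compound, concentration, endpoint);
    replicate normalized values are averaged, and the band codes the
    triplicate mean against the control spread.  ``well_key`` maps
    (plate, well) to the key used in ``features``/``counts`` (defaults to
    the bare well id; multi-plate runs use plate-qualified keys).
    """
    if well_key is None:
        well_key = lambda plate, well: well.well_id
    endpoint_df = well_endpoints(features, counts).set_index("well_id")
    rows = []
    for plate in plates:
        ctrl_wells = [well_key(plate, w) for w in plate.wells_by_role(control_role)]
        ctrl = endpoint_df.loc[[w for w in ctrl_wells if w in endpoint_df.index]]
        if ctrl.empty:
            raise InvalidArgumentError(f"plate {plate.plate_id} has no {control_role} endpoint data")
        ctrl_mean = ctrl[list(ENDPOINTS)].mean()
        ctrl_sd = ctrl[list(ENDPOINTS)].std(ddof=1)

        test = [w for w in plate.wells if w.role == "test" and well_key(plate, w) in endpoint_df.index]
        by_cond: dict[tuple[int, float], list] = {}
        for w in test:
            by_cond.setdefault((w.compound_id, w.concentration_uM), []).append(well_key(plate, w))
        for (cid, conc), wids in sorted(by_cond.items()):
            sub = endpoint_df.loc[wids]
            for ep in ENDPOINTS:
                vals = sub[ep].dropna()  # zero-peak wells excluded for magnitude
                raw_mean = float(vals.mean()) if len(vals) else float("nan")
                bm = float(ctrl_mean[ep])
                if bm == 0:
                    raise DegenerateBlankError(f"blank mean for {ep} is zero")
                norm_mean = normalize(raw_mean, bm) if np.isfinite(raw_mean) else float("nan")
                sd = float(ctrl_sd[ep])
                band = (
                    sd_band(raw_mean, bm, sd)
                    if sd > 0 and np.isfinite(raw_mean)
                    else 0
                )
                rows.append(
                    (plate.plate_id, cid, conc, ep, raw_mean, norm_mean, band, len(vals))
                )
    return pd.DataFrame(
        rows,
        columns=[
            "plate_id",
            "compound_id",
            "concentration_uM",
            "endpoint",
            "raw_mean",
            "normalized_mean",
            "band",
            "n_replicates",
        ],
    )


def heatmap_matrix(screen: pd.DataFrame, registry_frame: pd.DataFrame) -> pd.DataFrame:
    """Band matrix: rows = compounds grouped by kinase target, columns =
    endpoint x concentration, entries in {-3..+3}."""
    wide = screen.pivot_table(
        index="compound_id",
        columns=["endpoint", "concentration_uM"],
        values="band",
        aggfunc="first",
    )
    wide.columns = [f"{ep}_{conc:g}uM" for ep, conc in wide.columns]
    merged = registry_frame.set_index("compound_id").join(wide, how="inner")
    return merged.sort_values(["kinase_target", "compound_id"]).reset_index()
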