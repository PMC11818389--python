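"""Raw ablation-trace processing: resampling, LI filtering, plateau
detection, per-lesion feature extraction and geometry.

The analysis time base is a uniform 997 Hz grid; raw traces (irregularly
sampled contact force, power, local impedance and catheter-tip
coordinates) are linearly interpolated onto it.  The local impedance (LI)
is smoothed with a 1.5 s moving-mean filter whose partially supported
left edge is trimmed; the LI-drop plateau — the LI-guided stopping point —
is the minimum of the filtered LI.  Per-lesion summaries collect the RF
application durations under the three stopping rules (time to AI >= 400,
time to LSI >= 4, time to LI plateau) together with the covariates used
in the downstream regression analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.signal import find_peaks
from sklearn.neighbors import NearestNeighbors

from .metrics import (
    IndexSeries,
    MetricConstants,
    ablation_index,
    lesion_size_index,
    rf_current,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AblationTrace",
    "FilteredTrace",
    "PlateauResult",
    "LesionSummary",
    "LESION_TABLE_COLUMNS",
    "resample_trace",
    "filter_li",
    "detect_plateau",
    "time_to_target",
    "mean_tip_position",
    "interlesion_distance",
    "summarize_lesion",
    "process_traces",
    "write_traces",
    "read_traces",
]

DEFAULT_FS_HZ = 997.0
DEFAULT_FILTER_WINDOW_S = 1.5
DEFAULT_AI_TARGET = 400.0
DEFAULT_LSI_TARGET = 4.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AblationTrace:
    """One lesion's multichannel time series.

    ``time_s`` may be irregular (raw export) or uniform (after
    :func:`resample_trace`); all channels share its length.  ``tip_mm``
    is an (n, 3) array of catheter-tip coordinates in millimetres.
    """

    procedure_id: str
    lesion_id: str
    time_s: NDArray[np.float64]
    cf_g: NDArray[np.float64]
    power_w: NDArray[np.float64]
    li_ohm: NDArray[np.float64]
    tip_mm: NDArray[np.float64]

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("cf_g", "power_w", "li_ohm"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"AblationTrace: channel {name} length != time length")
        if self.tip_mm.shape != (n, 3):
            raise ValueError("AblationTrace: tip_mm must have shape (n, 3)")
        if n >= 2 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("AblationTrace: time must be strictly increasing")
        if np.any(self.li_ohm <= 0):
            raise ValueError("AblationTrace: local impedance must be > 0")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass
class FilteredTrace:
    """A uniform-grid trace plus its filtered LI on the trimmed support.

    ``li_filtered_ohm[k]`` corresponds to ``trace.time_s[trim_samples + k]``;
    ``trim_offset_s`` (the filter window length) has been removed from the
    left edge where the moving mean is only partially supported.
    """

    trace: AblationTrace
    li_filtered_ohm: NDArray[np.float64]
    fs_hz: float
    trim_samples: int
    trim_offset_s: float

    @property
    def filtered_time_s(self) -> NDArray[np.float64]:
        return self.trace.time_s[self.trim_samples:]


@dataclass(frozen=True)
class PlateauResult:
    """LI-drop plateau: location and magnitude of the filtered-LI minimum."""

    t_plateau_s: float
    li_at_plateau_ohm: float
    li_start_ohm: float
    li_drop_ohm: float
    no_rebound: bool = False


@dataclass
class LesionSummary:
    """Per-lesion metrics: stopping-rule durations plus covariates.

    Missing values (target never reached / singleton procedure) are NaN.
    """

    procedure_id: str
    lesion_id: str
    duration_li_s: float
    duration_ai_s: float
    duration_lsi_s: float
    li_drop_ohm: float
    li_start_ohm: float
    cf_mean_g: float
    cf_start_g: float
    ai_at_plateau: float
    lsi_at_plateau: float
    ild_mm: float = float("nan")
    no_rebound: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


LESION_TABLE_COLUMNS = [
    "procedure_id", "lesion_id",
    "duration_li_s", "duration_ai_s", "duration_lsi_s",
    "li_drop_ohm", "li_start_ohm", "cf_mean_g", "cf_start_g",
    "ai_at_plateau", "lsi_at_plateau", "ild_mm", "no_rebound",
]


# ---------------------------------------------------------------------------
# resampling and filtering
# ---------------------------------------------------------------------------

def resample_trace(trace: AblationTrace, fs_hz: float = DEFAULT_FS_HZ) -> AblationTrace:
    """Linearly interpolate every channel onto a uniform ``fs_hz`` grid.

    The grid starts at the first raw sample and never extends beyond the
    last one (no extrapolation).  A trace already on the requested grid is
    returned unchanged up to floating-point identity.
    """
    t = np.asarray(trace.time_s, dtype=float)
    if t.size < 2:
        raise ValueError("resample_trace: need at least 2 raw samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("resample_trace: raw times must be strictly increasing")
    n_out = int(np.floor((t[-1] - t[0]) * fs_hz)) + 1
    grid = t[0] + np.arange(n_out) / fs_hz
    tip = np.column_stack([np.interp(grid, t, trace.tip_mm[:, j]) for j in range(3)])
    return AblationTrace(
        procedure_id=trace.procedure_id,
        lesion_id=trace.lesion_id,
        time_s=grid,
        cf_g=np.interp(grid, t, trace.cf_g),
        power_w=np.interp(grid, t, trace.power_w),
        li_ohm=np.interp(grid, t, trace.li_ohm),
        tip_mm=tip,
    )


def _moving_mean(x: NDArray[np.float64], half: int, mode: str) -> NDArray[np.float64]:
    """Centered or trailing moving mean with shrinking windows at edges."""
    n = len(x)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    if mode == "centered":
        lo = np.maximum(0, idx - half)
        hi = np.minimum(n - 1, idx + half)
    elif mode == "trailing":
        lo = np.maximum(0, idx - 2 * half)
        hi = idx
    else:  # pragma: no cover - guarded by caller
        raise ValueError(f"unknown filter mode {mode!r}")
    return (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)


def filter_li(
    trace: AblationTrace,
    window_s: float = DEFAULT_FILTER_WINDOW_S,
    fs_hz: float = DEFAULT_FS_HZ,
    mode: Literal["centered", "trailing"] = "centered",
) -> FilteredTrace:
    """Moving-mean filter of the local impedance on the uniform grid.

    The window spans ``round(window_s * fs_hz)`` samples, forced odd so the
    centered filter is symmetric.  One full window length is trimmed from
    the left edge, where the shrinking-window output is only partially
    supported; the right edge keeps shrinking-window means so the plateau
    stays defined up to the last sample.  Output never leaves the range of
    the input, and constant input passes through unchanged.
    """
    if trace.duration_s <= window_s:
        raise ValueError(
            f"filter_li: trace duration {trace.duration_s:.3f}s must exceed "
            f"the window length {window_s}s"
        )
    w = int(round(window_s * fs_hz))
    if w % 2 == 0:
        w += 1
    half = (w - 1) // 2
    smoothed = _moving_mean(np.asarray(trace.li_ohm, dtype=float), half, mode)
    trim = int(round(window_s * fs_hz))
    return FilteredTrace(
        trace=trace,
        li_filtered_ohm=smoothed[trim:],
        fs_hz=fs_hz,
        trim_samples=trim,
        trim_offset_s=trim / fs_hz,
    )


# ---------------------------------------------------------------------------
# plateau and target detection
# ---------------------------------------------------------------------------

def detect_plateau(
    filtered: FilteredTrace,
    method: Literal["global_min", "local_min"] = "global_min",
    prominence_ohm: float = 0.5,
) -> PlateauResult:
    """Locate the LI-drop plateau on the filtered impedance.

    The default takes the global minimum of the filtered LI: on a
    drop-then-rebound trace this *is* the interior local minimum, and the
    rule is deterministic.  ``method="local_min"`` instead takes the first
    strict local minimum with at least ``prominence_ohm`` prominence,
    falling back to the global minimum when none qualifies.  If the
    minimum falls on the last sample the drop has not rebounded within
    the trace and ``no_rebound`` is flagged (the plateau could not be
    visually confirmed in the clinical sense).

    Times are reported relative to the start of RF delivery (first sample
    of the underlying uniform trace).
    """
    li = filtered.li_filtered_ohm
    if li.size == 0:
        raise ValueError("detect_plateau: empty filtered series")
    tseg = filtered.filtered_time_s
    t0 = float(filtered.trace.time_s[0])

    i_min = int(np.argmin(li))
    if method == "local_min":
        peaks, _ = find_peaks(-li, prominence=prominence_ohm)
        if peaks.size:
            i_min = int(peaks[0])
    elif method != "global_min":
        raise ValueError(f"unknown plateau method {method!r}")

    li_start = float(li[0])
    li_min = float(li[i_min])
    return PlateauResult(
        t_plateau_s=float(tseg[i_min] - t0),
        li_at_plateau_ohm=li_min,
        li_start_ohm=li_start,
        li_drop_ohm=max(li_start - li_min, 0.0),
        no_rebound=(i_min == li.size - 1),
    )


def time_to_target(index: IndexSeries, target: float) -> float:
    """First grid time at which the index reaches ``target``.

    No interpolation between grid points is attempted (at 997 Hz the
    induced error is below one millisecond).  Returns NaN when the target
    is never reached within the trace.
    """
    if target <= 0:
        raise ValueError(f"target must be > 0, got {target}")
    v = np.asarray(index.value)
    if v.size == 0:
        raise ValueError("time_to_target: empty index series")
    hits = np.nonzero(v >= target)[0]
    if hits.size == 0:
        return float("nan")
    return float(index.time_s[hits[0]] - index.time_s[0])


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def mean_tip_position(trace: AblationTrace) -> NDArray[np.float64]:
    """Component-wise mean catheter-tip position during RF delivery."""
    if trace.tip_mm.shape[0] == 0:
        raise ValueError("mean_tip_position: no coordinate samples")
    return trace.tip_mm.mean(axis=0)


def interlesion_distance(positions: pd.DataFrame) -> pd.Series:
    """Nearest-neighbour interlesion distance (ILD) per lesion.

    ``positions`` holds one row per lesion with columns ``procedure_id``,
    ``lesion_id``, ``x_mm``, ``y_mm``, ``z_mm`` (mean tip positions).  For
    each lesion the ILD is the Euclidean distance to the nearest *other*
    lesion of the same procedure (k-nearest-neighbour search with k = 1,
    self excluded); singleton procedures get NaN.  Coincident lesions
    yield ILD 0 (flagged via a log warning).
    """
    required = {"procedure_id", "lesion_id", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(positions.columns):
        raise ValueError(f"positions table must have columns {sorted(required)}")
    ild = pd.Series(np.nan, index=positions.index, dtype=float)
    for _, grp in positions.groupby("procedure_id", sort=False):
        if len(grp) < 2:
            continue
        xyz = grp[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        nn = NearestNeighbors(n_neighbors=2).fit(xyz)
        dist, _ = nn.kneighbors(xyz)
        ild.loc[grp.index] = dist[:, 1]
    if (ild == 0).any():
        logger.warning("interlesion_distance: coincident lesion positions (ILD = 0)")
    return ild


# ---------------------------------------------------------------------------
# per-lesion summary
# ---------------------------------------------------------------------------

def summarize_lesion(
    filtered: FilteredTrace,
    plateau: PlateauResult,
    ai_series: IndexSeries,
    lsi_series: IndexSeries,
    *,
    ai_target: float = DEFAULT_AI_TARGET,
    lsi_target: float = DEFAULT_LSI_TARGET,
    cf_start_window_s: float = 1.0,
) -> LesionSummary:
    """Collect the per-lesion metrics used by the cohort comparison.

    The contact-force summaries use the full uniform trace; ``cf_start``
    is the mean over the first second (a single first sample would be
    noise-dominated).  The indices at the plateau are the AI/LSI series
    values read off at the plateau time.  Index series must share the
    trace's uniform grid.
    """
    trace = filtered.trace
    for s, name in ((ai_series, "AI"), (lsi_series, "LSI")):
        if len(s.time_s) != len(trace.time_s) or not np.allclose(
            s.time_s, trace.time_s, rtol=0, atol=1e-9
        ):
            raise ValueError(f"summarize_lesion: {name} series grid mismatch")

    t0 = trace.time_s[0]
    i_plateau = int(round(plateau.t_plateau_s * filtered.fs_hz))
    i_plateau = min(i_plateau, len(trace.time_s) - 1)
    n_start = max(1, int(round(cf_start_window_s * filtered.fs_hz)))
    return LesionSummary(
        procedure_id=trace.procedure_id,
        lesion_id=trace.lesion_id,
        duration_li_s=plateau.t_plateau_s,
        duration_ai_s=time_to_target(ai_series, ai_target),
        duration_lsi_s=time_to_target(lsi_series, lsi_target),
        li_drop_ohm=plateau.li_drop_ohm,
        li_start_ohm=plateau.li_start_ohm,
        cf_mean_g=float(np.mean(trace.cf_g)),
        cf_start_g=float(np.mean(trace.cf_g[:n_start])),
        ai_at_plateau=float(ai_series.value[i_plateau]),
        lsi_at_plateau=float(lsi_series.value[i_plateau]),
        no_rebound=plateau.no_rebound,
    )


IndexFn = Callable[[AblationTrace], tuple[IndexSeries, IndexSeries]]


def oracle_index_fn(constants: MetricConstants) -> IndexFn:
    """Index provider evaluating the ground-truth formulas on a trace."""

    def compute(trace: AblationTrace) -> tuple[IndexSeries, IndexSeries]:
        ai = ablation_index(trace.cf_g, trace.power_w, trace.time_s, constants.ai)
        current = rf_current(trace.power_w, trace.li_ohm)
        lsi = lesion_size_index(trace.cf_g, current, trace.time_s, constants.lsi)
        return ai, lsi

    return compute


def process_traces(
    traces: Iterable[AblationTrace],
    index_fn: IndexFn,
    *,
    fs_hz: float = DEFAULT_FS_HZ,
    filter_window_s: float = DEFAULT_FILTER_WINDOW_S,
    ai_target: float = DEFAULT_AI_TARGET,
    lsi_target: float = DEFAULT_LSI_TARGET,
) -> pd.DataFrame:
    """Run the per-lesion pipeline over a cohort of raw traces.

    Each trace is resampled to the analysis grid, LI-filtered, plateau-
    detected, indexed via ``index_fn`` (either the ground-truth oracle or
    trained surrogate models) and summarized; interlesion distances are
    filled in per procedure.  Returns the lesion table (one row per
    lesion, schema :data:`LESION_TABLE_COLUMNS`).
    """
    rows: list[dict] = []
    pos_rows: list[dict] = []
    for raw in traces:
        uni = resample_trace(raw, fs_hz)
        filt = filter_li(uni, filter_window_s, fs_hz)
        plateau = detect_plateau(filt)
        ai_series, lsi_series = index_fn(uni)
        summary = summarize_lesion(
            filt, plateau, ai_series, lsi_series,
            ai_target=ai_target, lsi_target=lsi_target,
        )
        rows.append(summary.as_dict())
        x, y, z = mean_tip_position(uni)
        pos_rows.append({
            "procedure_id": uni.procedure_id, "lesion_id": uni.lesion_id,
            "x_mm": x, "y_mm": y, "z_mm": z,
        })
    lesions = pd.DataFrame(rows)
    positions = pd.DataFrame(pos_rows)
    lesions["ild_mm"] = interlesion_distance(positions).to_numpy()
    return lesions[LESION_TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

TRACE_COLUMNS = [
    "procedure_id", "lesion_id", "time_s", "cf_g", "power_w", "li_ohm",
    "x_mm", "y_mm", "z_mm",
]


def write_traces(traces: Sequence[AblationTrace], path: str | Path) -> None:
    """Write a cohort of traces as one long-format delimited table."""
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "procedure_id": tr.procedure_id,
            "lesion_id": tr.lesion_id,
            "time_s": tr.time_s,
            "cf_g": tr.cf_g,
            "power_w": tr.power_w,
            "li_ohm": tr.li_ohm,
            "x_mm": tr.tip_mm[:, 0],
            "y_mm": tr.tip_mm[:, 1],
            "z_mm": tr.tip_mm[:, 2],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path: str | Path) -> list[AblationTrace]:
    """Read traces written by :func:`write_traces`."""
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace table missing columns {sorted(missing)}")
    out = []
    for (pid, lid), grp in df.groupby(["procedure_id", "lesion_id"], sort=False):
        out.append(AblationTrace(
            procedure_id=str(pid),
            lesion_id=str(lid),
            time_s=grp["time_s"].to_numpy(dtype=float),
            cf_g=grp["cf_g"].to_numpy(dtype=float),
            power_w=grp["power_w"].to_numpy(dtype=float),
            li_ohm=grp["li_ohm"].to_numpy(dtype=float),
            tip_mm=grp[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        ))
    return out
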