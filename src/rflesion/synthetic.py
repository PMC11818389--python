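"""Synthetic ablation cohort generator.

The clinical exports behind the stopping-rule comparison (per-lesion
contact-force / power / local-impedance time series from an LI-guided
atrial ablation procedure) are not publicly available, so this module
generates traces with the statistical structure the analysis assumes and
— crucially — with *known ground truth*: every simulated lesion carries
the parameters of its own LI model, and the AI/LSI oracles of
:mod:`rflesion.metrics` provide exact index series for it.  Every later
pipeline stage can therefore be verified by parameter recovery.

Local-impedance model
---------------------
The noiseless LI is an exponential drop with a linear post-drop drift::

    LI(t) = li0 - drop * (1 - exp(-t / tau_drop)) + rebound * t

which has exactly one interior local minimum at
``t* = tau_drop * ln(drop / (rebound * tau_drop))`` whenever
``rebound > 0`` and ``t*`` lies inside the trace — a guaranteed, tunable
plateau for the detector to find.  Additive white noise (per raw sample)
and irregular raw sampling emulate the exports' measurement properties.

Contact force is an AR(1)-smoothed wobble around the per-lesion mean, so
6 s windowed CF means genuinely differ from instantaneous CF.  Lesion
centres sit on a ring (plus jitter) whose chord length sets the
interlesion distances; the default layout (30 lesions on a 17.5 mm ring)
gives nearest-neighbour distances near 3.66 mm, the scale reported for
clinical pulmonary-vein encirclement.

Default parameter ranges are chosen so the cohort reproduces the
qualitative stopping-rule ordering observed clinically: time to
AI >= 400 (~5-9 s) < time to LI plateau (~7-13 s) < time to LSI >= 4
(~16-26 s), with a tail of lesions whose LSI never reaches target within
the trace (the source of missing LSI durations downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from pathlib import Path
from typing import Callable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .processing import AblationTrace

__all__ = [
    "TraceParams",
    "ProcedureLayout",
    "MissingnessSpec",
    "SimulatedProcedure",
    "simulate_trace",
    "simulate_procedure",
    "simulate_cohort",
    "inject_missingness",
    "default_trace_sampler",
    "noiseless_li",
    "noiseless_minimum_time",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceParams:
    """Ground-truth parameters of one simulated lesion trace.

    Defaults are the study conditions of the synthetic cohort (impedances
    around the clinically reported ~147 ohm start / ~20 ohm drop, contact
    force around 18 g, 40-50 W power).
    """

    duration_s: float = 28.0
    cf_mean_g: float = 18.0
    cf_sd_g: float = 2.5
    power_w: float = 40.0
    li0_ohm: float = 146.6
    drop_ohm: float = 24.0
    tau_drop_s: float = 2.75
    rebound_ohm_per_s: float = 0.35
    noise_sd_ohm: float = 0.5
    sample_hz: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("TraceParams: duration_s must be > 0")
        if not self.li0_ohm > self.drop_ohm > 0:
            raise ValueError(
                f"TraceParams: need li0_ohm > drop_ohm > 0, got "
                f"li0={self.li0_ohm}, drop={self.drop_ohm}"
            )
        if self.tau_drop_s <= 0:
            raise ValueError("TraceParams: tau_drop_s must be > 0")
        if self.cf_mean_g < 0:
            raise ValueError("TraceParams: cf_mean_g must be >= 0")
        if self.rebound_ohm_per_s < 0:
            raise ValueError("TraceParams: rebound_ohm_per_s must be >= 0")
        if self.noise_sd_ohm < 0:
            raise ValueError("TraceParams: noise_sd_ohm must be >= 0")
        if self.sample_hz <= 0:
            raise ValueError("TraceParams: sample_hz must be > 0")


@dataclass(frozen=True)
class ProcedureLayout:
    """Geometry of one simulated procedure: lesions on a jittered ring."""

    n_lesions: int = 30
    ring_radius_mm: float = 17.5
    spacing_jitter_mm: float = 0.3
    tip_jitter_mm: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 1:
            raise ValueError("ProcedureLayout: n_lesions must be >= 1")
        if self.ring_radius_mm <= 0:
            raise ValueError("ProcedureLayout: ring_radius_mm must be > 0")


@dataclass(frozen=True)
class MissingnessSpec:
    """Missingness mechanism for the LSI-duration column.

    MCAR deletes uniformly at ``rate``; MAR deletes with probability
    increasing in ``driver_column`` (rank-linear), keeping the expected
    overall rate.
    """

    mechanism: Literal["MCAR", "MAR"] = "MCAR"
    rate: float = 0.1
    driver_column: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate < 1.0:
            raise ValueError(f"MissingnessSpec: rate must lie in [0, 1), got {self.rate}")
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"MissingnessSpec: unknown mechanism {self.mechanism!r}")
        if self.mechanism == "MAR" and not self.driver_column:
            raise ValueError("MissingnessSpec: MAR requires a driver_column")
        if self.mechanism == "MCAR" and self.driver_column:
            raise ValueError("MissingnessSpec: driver_column only applies to MAR")


# ---------------------------------------------------------------------------
# single-trace simulation
# ---------------------------------------------------------------------------

def noiseless_li(params: TraceParams, t: NDArray[np.float64]) -> NDArray[np.float64]:
    """The generator's noise-free LI curve at times ``t``."""
    t = np.asarray(t, dtype=float)
    return (
        params.li0_ohm
        - params.drop_ohm * (1.0 - np.exp(-t / params.tau_drop_s))
        + params.rebound_ohm_per_s * t
    )


def noiseless_minimum_time(params: TraceParams) -> float:
    """Analytic location of the noiseless LI minimum (the true plateau).

    NaN when the curve has no interior minimum within the trace (no
    rebound, or the minimum falls outside ``[0, duration_s]``).
    """
    if params.rebound_ohm_per_s <= 0:
        return float("nan")
    ratio = params.drop_ohm / (params.rebound_ohm_per_s * params.tau_drop_s)
    if ratio <= 1.0:
        return float("nan")
    t_star = params.tau_drop_s * np.log(ratio)
    if t_star >= params.duration_s:
        return float("nan")
    return float(t_star)


def _irregular_times(params: TraceParams, rng: np.random.Generator) -> NDArray[np.float64]:
    """Strictly increasing sample times with ±30% uniform gap jitter."""
    nominal = 1.0 / params.sample_hz
    n_max = int(params.duration_s * params.sample_hz * 1.5) + 2
    gaps = nominal * rng.uniform(0.7, 1.3, n_max)
    t = np.concatenate(([0.0], np.cumsum(gaps)))
    return t[t <= params.duration_s]


def _ar1_wobble(n: int, sd: float, rho: float, rng: np.random.Generator) -> NDArray[np.float64]:
    """Stationary AR(1) noise with marginal SD ``sd``."""
    if n == 0 or sd == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), n)
    w = np.empty(n)
    w[0] = rng.normal(0.0, sd)
    for k in range(1, n):
        w[k] = rho * w[k - 1] + innov[k]
    return w


def simulate_trace(
    params: TraceParams,
    *,
    center_mm: Sequence[float] = (0.0, 0.0, 0.0),
    tip_jitter_mm: float = 0.5,
    procedure_id: str = "P1",
    lesion_id: str = "L1",
    cf_corr_time_s: float = 1.0,
) -> AblationTrace:
    """Simulate one lesion's raw (irregularly sampled) ablation trace.

    CF(t) = max(0, cf_mean + AR(1) wobble); power is the constant setting;
    LI(t) is the exponential-drop / linear-rebound model plus white noise;
    tip coordinates scatter isotropically around ``center_mm``.  Identical
    ``params`` (including seed) give bit-identical traces.
    """
    rng = np.random.default_rng(params.seed)
    t = _irregular_times(params, rng)
    n = len(t)
    if n < 2:
        raise ValueError("simulate_trace: duration too short for the sampling rate")

    rho = float(np.exp(-1.0 / (params.sample_hz * cf_corr_time_s)))
    cf = np.maximum(0.0, params.cf_mean_g + _ar1_wobble(n, params.cf_sd_g, rho, rng))
    power = np.full(n, params.power_w, dtype=float)
    li = noiseless_li(params, t)
    if params.noise_sd_ohm > 0:
        li = li + rng.normal(0.0, params.noise_sd_ohm, n)
    li = np.maximum(li, 1.0)  # impedance stays physical under extreme noise
    tip = np.asarray(center_mm, dtype=float) + rng.normal(0.0, tip_jitter_mm, (n, 3))
    return AblationTrace(
        procedure_id=procedure_id,
        lesion_id=lesion_id,
        time_s=t,
        cf_g=cf,
        power_w=power,
        li_ohm=li,
        tip_mm=tip,
    )


# ---------------------------------------------------------------------------
# cohort-level sampling
# ---------------------------------------------------------------------------

def default_trace_sampler(rng: np.random.Generator) -> TraceParams:
    """Draw per-lesion trace parameters for the synthetic study cohort.

    Marginals are matched to the clinically reported summaries: contact
    force log-normal around 18 g, power from the 40-50 W settings, LI
    start around 146.6 ohm, LI drop log-normal around 24 ohm.  Decay and
    rebound ranges put the LI minimum between the AI and LSI crossing
    times.
    """
    cf_mean = float(np.clip(np.exp(rng.normal(np.log(18.0), 0.35)), 6.0, 40.0))
    power = float(rng.choice([40.0, 45.0, 50.0]))
    li0 = float(np.clip(rng.normal(146.6, 8.0), 120.0, 175.0))
    drop = float(np.clip(np.exp(rng.normal(np.log(24.0), 0.25)), 10.0, 0.4 * li0))
    return TraceParams(
        duration_s=28.0,
        cf_mean_g=cf_mean,
        cf_sd_g=2.5,
        power_w=power,
        li0_ohm=li0,
        drop_ohm=drop,
        tau_drop_s=float(rng.uniform(2.0, 3.5)),
        rebound_ohm_per_s=float(rng.uniform(0.25, 0.5)),
        noise_sd_ohm=0.5,
        sample_hz=400.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


@dataclass
class SimulatedProcedure:
    """Traces of one procedure plus their ground-truth parameters."""

    procedure_id: str
    traces: list[AblationTrace]
    params: dict[str, TraceParams]
    centers_mm: NDArray[np.float64]

    def __iter__(self) -> Iterator[AblationTrace]:
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)


def simulate_procedure(
    layout: ProcedureLayout,
    trace_params_sampler: Callable[[np.random.Generator], TraceParams] | None = None,
    seed: int = 0,
    procedure_id: str = "P1",
) -> SimulatedProcedure:
    """Simulate one procedure: a jittered ring of independently drawn lesions.

    Lesion centres are placed at equal angles on a ring of
    ``ring_radius_mm`` plus isotropic Gaussian jitter of
    ``spacing_jitter_mm``, so consecutive-centre chords are controlled by
    the radius and the lesion count.  Lesion IDs are ``L01, L02, ...``
    within the shared ``procedure_id``.
    """
    sampler = trace_params_sampler or default_trace_sampler
    rng = np.random.default_rng(seed)
    n = layout.n_lesions
    angles = 2.0 * np.pi * np.arange(n) / n
    centers = np.column_stack([
        layout.ring_radius_mm * np.cos(angles),
        layout.ring_radius_mm * np.sin(angles),
        np.zeros(n),
    ])
    if layout.spacing_jitter_mm > 0:
        centers = centers + rng.normal(0.0, layout.spacing_jitter_mm, (n, 3))

    width = max(2, len(str(n)))
    traces: list[AblationTrace] = []
    params: dict[str, TraceParams] = {}
    for k in range(n):
        lesion_id = f"L{k + 1:0{width}d}"
        p = sampler(rng)
        traces.append(simulate_trace(
            p,
            center_mm=centers[k],
            tip_jitter_mm=layout.tip_jitter_mm,
            procedure_id=procedure_id,
            lesion_id=lesion_id,
        ))
        params[lesion_id] = p
    return SimulatedProcedure(
        procedure_id=procedure_id, traces=traces, params=params, centers_mm=centers
    )


def simulate_cohort(
    n_lesions: int,
    layout: ProcedureLayout | None = None,
    seed: int = 0,
    trace_params_sampler: Callable[[np.random.Generator], TraceParams] | None = None,
) -> list[SimulatedProcedure]:
    """Simulate a multi-procedure cohort totalling ``n_lesions`` lesions.

    Lesions are grouped into procedures of the layout's size (default 30,
    the last procedure possibly smaller), mirroring how clinical cohorts
    pool lesions across patients.
    """
    base = layout or ProcedureLayout()
    rng = np.random.default_rng(seed)
    procedures: list[SimulatedProcedure] = []
    remaining, p_idx = n_lesions, 0
    while remaining > 0:
        p_idx += 1
        size = min(base.n_lesions, remaining)
        procedures.append(simulate_procedure(
            replace(base, n_lesions=size),
            trace_params_sampler,
            seed=int(rng.integers(0, 2**31 - 1)),
            procedure_id=f"P{p_idx:03d}",
        ))
        remaining -= size
    return procedures


def cohort_traces(procedures: Sequence[SimulatedProcedure]) -> list[AblationTrace]:
    """Flatten a cohort into a single trace list."""
    return [tr for proc in procedures for tr in proc.traces]


def write_manifest(procedures: Sequence[SimulatedProcedure], path: str | Path) -> None:
    """Write the per-lesion ground-truth parameters as a delimited table."""
    rows = []
    for proc in procedures:
        for lesion_id, p in proc.params.items():
            row = {"procedure_id": proc.procedure_id, "lesion_id": lesion_id}
            row.update(asdict(p))
            row["t_plateau_true_s"] = noiseless_minimum_time(p)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# missingness injection
# ---------------------------------------------------------------------------

def inject_missingness(
    table: pd.DataFrame,
    spec: MissingnessSpec,
    target_column: str = "duration_lsi_s",
) -> tuple[pd.DataFrame, pd.Series]:
    """Delete entries of ``target_column`` under the requested mechanism.

    Returns ``(table_with_missing, mask)`` where ``mask`` is a boolean
    Series marking the deleted cells, so recovery tests can compare
    imputations against the truth.  Under MAR the per-row deletion
    probability is rank-linear in ``driver_column`` with the requested
    expected overall rate.  Observed cells are never altered.
    """
    if target_column not in table.columns:
        raise ValueError(f"inject_missingness: no column {target_column!r}")
    out = table.copy()
    n = len(out)
    rng = np.random.default_rng(spec.seed)
    if spec.rate == 0 or n == 0:
        return out, pd.Series(False, index=out.index)

    if spec.mechanism == "MCAR":
        prob = np.full(n, spec.rate)
    else:
        driver = out[spec.driver_column]
        if driver.isna().any():
            raise ValueError("inject_missingness: MAR driver column has missing values")
        ranks = driver.rank(method="average").to_numpy()
        prob = np.clip(2.0 * spec.rate * (ranks - 0.5) / n, 0.0, 1.0)
    mask = pd.Series(rng.uniform(size=n) < prob, index=out.index)
    out.loc[mask, target_column] = np.nan
    return out, mask
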