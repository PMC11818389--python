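"""Reference implementations of the Ablation Index and Lesion Size Index.

Both indices are proprietary lesion metrics used to guide radiofrequency
(RF) ablation of atrial fibrillation.  Their published functional forms
combine contact force (CF, grams), delivered power (P, watts), RF current
(I, milliamperes) and application duration (tau, seconds), but the actual
coefficient values belong to the respective mapping-system vendors.  This
module therefore evaluates the formulas with *configurable stand-in
constants*: the constants define a ground-truth oracle for the synthetic
cohort, never a claim about the clinical indices.

Formulas implemented
--------------------
Ablation Index (AI)::

    AI(tau) = K * ( \\int_0^tau CF(s)^a * P(s)^b ds )^c

with the cumulative integral evaluated by composite Simpson quadrature on
the uniform analysis grid.

Lesion Size Index (LSI)::

    LSI(tau) = [ b0*(1 - e^{-F/b1}) + b2*(1 - e^{-I^2/b3}) ]
               * [ (1 - b4) + b4 * (1 - e^{-tau/b5}) / (1 - e^{-60/b5}) ]

where F and I are 6 s trailing sliding-window means of contact force and
RF current.  The time factor is normalized so that it equals exactly 1 at
tau = 60 s; the saturating force/current terms bound LSI by b0 + b2.

RF current is derived from power and local impedance (LI) by the AC
analogue of Ohm's law, I = sqrt(P / Z), reported in mA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.integrate import cumulative_simpson

__all__ = [
    "AIConstants",
    "LSIConstants",
    "MetricConstants",
    "IndexSeries",
    "force_time_integral",
    "rf_current",
    "sliding_window_mean",
    "ablation_index",
    "lesion_size_index",
    "calibrate_constants",
]

#: reference 60 s horizon at which the LSI time factor is normalized to 1
LSI_TIME_NORM_S = 60.0


# ---------------------------------------------------------------------------
# constants containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AIConstants:
    """Stand-in constants for the Ablation Index formula.

    Parameters
    ----------
    K : float
        Overall scale (arbitrary index units); K > 0.
    a : float
        Contact-force exponent (dimensionless); a >= 0.
    b : float
        Power exponent (dimensionless); b >= 0.
    c : float
        Outer exponent applied to the time integral; c > 0.
    """

    K: float
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError(f"AIConstants: K must be > 0, got {self.K}")
        if not self.c > 0:
            raise ValueError(f"AIConstants: c must be > 0, got {self.c}")
        if self.a < 0 or self.b < 0:
            raise ValueError(
                f"AIConstants: exponents a, b must be >= 0, got a={self.a}, b={self.b}"
            )


@dataclass(frozen=True)
class LSIConstants:
    """Stand-in constants for the Lesion Size Index formula.

    b0, b2 scale the saturating force and current terms (index units);
    b1 (grams) and b3 (mA^2) are the corresponding e-folding constants;
    b4 in [0, 1] mixes the time-independent and time-dependent parts;
    b5 (seconds) is the time e-folding constant.
    """

    b0: float
    b1: float
    b2: float
    b3: float
    b4: float
    b5: float

    def __post_init__(self) -> None:
        if self.b1 <= 0 or self.b3 <= 0 or self.b5 <= 0:
            raise ValueError("LSIConstants: b1, b3, b5 must be > 0")
        if not 0.0 <= self.b4 <= 1.0:
            raise ValueError(f"LSIConstants: b4 must lie in [0, 1], got {self.b4}")
        if self.b0 < 0 or self.b2 < 0:
            raise ValueError("LSIConstants: b0, b2 must be >= 0")

    @property
    def saturation(self) -> float:
        """Upper bound of LSI as F, I -> infinity at tau >= 60 s."""
        return self.b0 + self.b2


@dataclass(frozen=True)
class MetricConstants:
    """The full set of oracle constants: one AI set, one LSI set."""

    ai: AIConstants
    lsi: LSIConstants


@dataclass(frozen=True)
class IndexSeries:
    """A lesion index evaluated on a uniform time grid.

    ``kind`` is ``"AI"`` or ``"LSI"``; ``value`` has one entry per point of
    ``time_s``.  For non-negative inputs both indices are non-decreasing.
    """

    time_s: NDArray[np.float64]
    value: NDArray[np.float64]
    kind: Literal["AI", "LSI"]

    def __post_init__(self) -> None:
        if len(self.time_s) != len(self.value):
            raise ValueError("IndexSeries: time and value lengths differ")
        if self.kind not in ("AI", "LSI"):
            raise ValueError(f"IndexSeries: kind must be 'AI' or 'LSI', got {self.kind!r}")


# ---------------------------------------------------------------------------
# grid helpers
# ---------------------------------------------------------------------------

def _check_uniform_grid(time_s: NDArray[np.float64], rtol: float = 1e-6) -> float:
    """Return the grid step; reject non-uniform or too-short grids."""
    time_s = np.asarray(time_s, dtype=float)
    if time_s.ndim != 1 or time_s.size < 2:
        raise ValueError("time grid must be 1-D with at least 2 samples")
    dt = np.diff(time_s)
    if dt[0] <= 0 or not np.allclose(dt, dt[0], rtol=rtol, atol=1e-12):
        raise ValueError("time grid must be uniform and strictly increasing; resample first")
    return float(np.mean(dt))


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def force_time_integral(cf_g: ArrayLike, time_s: ArrayLike) -> NDArray[np.float64]:
    """Cumulative force-time integral (FTI) by composite Simpson quadrature.

    Parameters
    ----------
    cf_g : array
        Contact force in grams, sampled on a uniform time grid.
    time_s : array
        The uniform grid, seconds; >= 2 samples.

    Returns
    -------
    ndarray
        FTI at every timepoint in g*s; 0 at the first timepoint and
        non-decreasing whenever the force is non-negative.  On polynomial
        integrands of degree <= 3 the values at even (paired-interval)
        indices are exact to round-off.
    """
    cf = np.asarray(cf_g, dtype=float)
    t = np.asarray(time_s, dtype=float)
    _check_uniform_grid(t)
    if cf.shape != t.shape:
        raise ValueError("cf and time grids must have equal length")
    return cumulative_simpson(cf, x=t, initial=0.0)


def rf_current(power_w: ArrayLike, li_ohm: ArrayLike) -> NDArray[np.float64] | float:
    """RF current from power and local impedance via Ohm's law for AC.

    I = 1000 * sqrt(P / Z) in mA; the round trip I^2 * Z / 1e6 recovers P.
    Scalar in, scalar out; arrays broadcast.
    """
    p = np.asarray(power_w, dtype=float)
    z = np.asarray(li_ohm, dtype=float)
    if np.any(z <= 0):
        raise ValueError("local impedance must be > 0 ohm")
    if np.any(p < 0):
        raise ValueError("power must be >= 0 W")
    i_ma = 1000.0 * np.sqrt(p / z)
    if np.isscalar(power_w) and np.isscalar(li_ohm):
        return float(i_ma)
    return i_ma


def sliding_window_mean(
    series: ArrayLike, time_s: ArrayLike, window_s: float = 6.0
) -> NDArray[np.float64]:
    """Trailing sliding-window mean, truncated at the trace start.

    At time t the mean is taken over the most recent ``min(t, window_s)``
    seconds of samples (the current sample included), i.e. over the last
    ``min(i + 1, round(window_s * fs))`` grid samples.  A constant series
    is a fixed point.
    """
    x = np.asarray(series, dtype=float)
    t = np.asarray(time_s, dtype=float)
    dt = _check_uniform_grid(t)
    if x.shape != t.shape:
        raise ValueError("series and time grid must have equal length")
    if window_s <= 0:
        raise ValueError(f"window_s must be > 0, got {window_s}")
    m = max(1, int(round(window_s / dt)))
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(len(x))
    lo = np.maximum(0, idx - m + 1)
    return (csum[idx + 1] - csum[lo]) / (idx + 1 - lo)


def ablation_index(
    cf_g: ArrayLike,
    power_w: ArrayLike,
    time_s: ArrayLike,
    constants: AIConstants,
) -> IndexSeries:
    """Evaluate the Ablation Index series AI(tau) = K * (int CF^a P^b)^c.

    The integrand CF^a * P^b is integrated cumulatively by Simpson's rule
    on the uniform grid; the outer exponent c and scale K are applied to
    the running integral.  AI(0) = 0 and the series is non-decreasing for
    non-negative CF and P.
    """
    cf = np.asarray(cf_g, dtype=float)
    p = np.asarray(power_w, dtype=float)
    t = np.asarray(time_s, dtype=float)
    if np.any(cf < 0) or np.any(p < 0):
        raise ValueError("contact force and power must be non-negative")
    integrand = cf**constants.a * p**constants.b
    integral = force_time_integral(integrand, t)
    value = constants.K * np.maximum(integral, 0.0) ** constants.c
    return IndexSeries(time_s=t, value=value, kind="AI")


def _lsi_time_factor(time_s: NDArray[np.float64], constants: LSIConstants) -> NDArray[np.float64]:
    b4, b5 = constants.b4, constants.b5
    norm = 1.0 - np.exp(-LSI_TIME_NORM_S / b5)
    return (1.0 - b4) + b4 * (1.0 - np.exp(-np.asarray(time_s, float) / b5)) / norm


def lesion_size_index(
    cf_g: ArrayLike,
    current_ma: ArrayLike,
    time_s: ArrayLike,
    constants: LSIConstants,
    *,
    window_s: float = 6.0,
    windowed: bool = False,
) -> IndexSeries:
    """Evaluate the Lesion Size Index series.

    ``cf_g`` and ``current_ma`` are the raw per-sample contact force and
    RF current; the 6 s trailing window means F and I entering the formula
    are computed here unless ``windowed=True`` (inputs already windowed).

    The force and current terms saturate at b0 and b2; the time factor
    rises from (1 - b4) at tau = 0 to exactly 1 at tau = 60 s.
    """
    t = np.asarray(time_s, dtype=float)
    cf = np.asarray(cf_g, dtype=float)
    cur = np.asarray(current_ma, dtype=float)
    if np.any(cf < 0) or np.any(cur < 0):
        raise ValueError("contact force and current must be non-negative")
    if windowed:
        f_win, i_win = cf, cur
        _check_uniform_grid(t)
    else:
        f_win = sliding_window_mean(cf, t, window_s)
        i_win = sliding_window_mean(cur, t, window_s)
    amp = constants.b0 * (1.0 - np.exp(-f_win / constants.b1)) + constants.b2 * (
        1.0 - np.exp(-(i_win**2) / constants.b3)
    )
    value = amp * _lsi_time_factor(t, constants)
    return IndexSeries(time_s=t, value=value, kind="LSI")


def lsi_point(
    f_g: float, i_ma: float, tau_s: float, constants: LSIConstants
) -> float:
    """Single-point LSI from already-windowed F (g), I (mA) at time tau."""
    amp = constants.b0 * (1.0 - np.exp(-f_g / constants.b1)) + constants.b2 * (
        1.0 - np.exp(-(i_ma**2) / constants.b3)
    )
    return float(amp * _lsi_time_factor(np.array([tau_s]), constants)[0])


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_constants(
    *,
    target_ai: float = 400.0,
    t_ai_s: float = 7.0,
    target_lsi: float = 4.0,
    t_lsi_s: float = 20.0,
    cf_ref_g: float = 15.0,
    power_ref_w: float = 40.0,
    current_ref_ma: float = 500.0,
    a: float = 0.6,
    b: float = 1.4,
    c: float = 0.35,
    b1: float = 10.0,
    b3: float = 2.5e5,
    b4: float = 0.75,
    b5: float = 20.0,
    b0_base: float = 1.0,
    b2_base: float = 1.0,
    saturation_cap: float = 20.0,
) -> MetricConstants:
    """Solve for the free scales so the oracles cross their targets on time.

    Given the shape constants (a, b, c for AI; b1, b3, b4, b5 and the base
    ratio b0_base : b2_base for LSI) and constant reference inputs, this
    returns constants for which

    * AI crosses ``target_ai`` at ``t_ai_s`` under CF = cf_ref_g and
      P = power_ref_w (solves K);
    * LSI crosses ``target_lsi`` at ``t_lsi_s`` under windowed F = cf_ref_g
      and I = current_ref_ma (scales (b0, b2) jointly).

    ``saturation_cap`` bounds the admissible b0 + b2: a target requiring a
    steeper saturating amplitude than the cap is rejected as infeasible.
    """
    if min(target_ai, t_ai_s, target_lsi, t_lsi_s) <= 0:
        raise ValueError("targets and crossing times must be > 0")
    if min(cf_ref_g, power_ref_w, current_ref_ma) <= 0:
        raise ValueError("reference CF/P/I levels must be > 0")

    # AI: closed form for constant inputs, AI(t) = K * (CF^a P^b t)^c.
    integral = cf_ref_g**a * power_ref_w**b * t_ai_s
    K = target_ai / integral**c
    ai = AIConstants(K=K, a=a, b=b, c=c)

    # LSI: scale (b0, b2) jointly so amp * time_factor(t_lsi) = target.
    lsi_shape = LSIConstants(b0=b0_base, b1=b1, b2=b2_base, b3=b3, b4=b4, b5=b5)
    f_term = float(b0_base * (1.0 - np.exp(-cf_ref_g / b1)))
    i_term = float(b2_base * (1.0 - np.exp(-(current_ref_ma**2) / b3)))
    tf = float(_lsi_time_factor(np.array([t_lsi_s]), lsi_shape)[0])
    amp_needed = target_lsi / tf
    base_amp = f_term + i_term
    if base_amp <= 0:
        raise ValueError("reference F/I terms vanish; cannot calibrate LSI scales")
    scale = amp_needed / base_amp
    b0, b2 = float(scale * b0_base), float(scale * b2_base)
    if b0 + b2 > saturation_cap:
        raise ValueError(
            f"LSI target {target_lsi} at t={t_lsi_s}s needs saturation b0+b2="
            f"{b0 + b2:.3f} > cap {saturation_cap}; target exceeds the "
            "admissible saturation bound"
        )
    lsi = LSIConstants(b0=b0, b1=b1, b2=b2, b3=b3, b4=b4, b5=b5)
    return MetricConstants(ai=ai, lsi=lsi)
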