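"""Nonsteady-state gas-exchange analysis.

Covers shade-to-sun induction metrics, exponential fitting of stomatal
conductance transients, time-resolved carboxylation capacity and stomatal
limitation from multi-CO2 induction sets, and empirical stomatal-model
(slope/intercept) fitting from light-response curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import constants as k
from .gasex import GasExTrace

__all__ = [
    "InductionMetrics",
    "KineticsFit",
    "BallBerryParams",
    "DynamicAciResult",
    "induction_metrics",
    "fit_stomatal_kinetics",
    "dynamic_aci",
    "ball_berry_fit",
]


@dataclass(frozen=True)
class InductionMetrics:
    """Summary metrics of one shade-to-sun induction trace.

    Times are minutes from the light transition.  ``ccf`` is the sum of the
    10-s assimilation samples over the first 5 min (instrument-sample
    convention); ``ccf_integral`` is the corresponding true time integral in
    umol m-2.
    """

    t50a: float
    t90a: float
    ccf: float
    t50gs: float
    gs_t0: float
    a_final: float
    gs_final: float
    ccf_integral: float = math.nan
    provisional: bool = False

    def __post_init__(self) -> None:
        if not (math.isnan(self.t50a) or math.isnan(self.t90a)) and self.t50a > self.t90a:
            raise ValueError("t50a must not exceed t90a")


@dataclass(frozen=True)
class KineticsFit:
    """Exponential fit of a stomatal conductance transient.

    ``k_min`` is the fitted time constant in minutes (exponent -t/k);
    ``g0``/``gmax`` are the smaller/larger of the fitted asymptote and start.
    """

    g0: float
    gmax: float
    k_min: float
    direction: str  # 'opening' or 'closing'
    rmse: float
    degenerate: bool = False
    warning: Optional[str] = None


@dataclass(frozen=True)
class BallBerryParams:
    """Slope and intercept of the empirical stomatal-conductance target."""

    slope: float
    intercept: float
    r_squared: float = math.nan
    physiological: bool = True


@dataclass
class DynamicAciResult:
    """Time course of apparent carboxylation capacity and stomatal limitation."""

    data: pd.DataFrame  # columns: time_s, vcmax_t, sl_t, n_points
    ci_ref: float


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """Time of first upward crossing of ``level``, linear interpolation."""
    above = y >= level
    if above[0]:
        return float(t[0])
    idx = np.nonzero(above)[0]
    if len(idx) == 0:
        return math.nan
    i = idx[0]
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))


def _value_at(t: np.ndarray, y: np.ndarray, when: float) -> float:
    return float(np.interp(when, t, y))


def induction_metrics(
    trace: GasExTrace,
    high_light_start: float,
    final_at_s: float = 1800.0,
    baseline_subtract: bool = False,
) -> InductionMetrics:
    """Induction metrics from a shade-to-sun trace.

    ``high_light_start`` is the trace time (s) of the step to high light.
    The reference ("final") values are taken at ``final_at_s`` seconds after
    the transition (30 min by convention); shorter traces yield provisional
    metrics referenced to the last sample.
    """
    t_all = trace.column("time_s")
    a_all = trace.column("a_umol_m2_s")
    gs_all = trace.column("gsw_mol_m2_s")

    pre = t_all <= high_light_start
    gs_t0 = float(gs_all[pre][-1]) if pre.any() else math.nan

    post = t_all >= high_light_start
    t = t_all[post] - high_light_start
    a = a_all[post]
    gs = gs_all[post]
    if len(t) < 2:
        raise ValueError("trace has no samples after the light transition")

    provisional = t[-1] < final_at_s
    t_ref = min(final_at_s, t[-1])
    a_final = _value_at(t, a, t_ref)
    gs_final = _value_at(t, gs, t_ref)

    a_base = a[0] if baseline_subtract else 0.0
    gs_base = gs[0] if baseline_subtract else 0.0
    t50a = _first_crossing(t, a, a_base + 0.5 * (a_final - a_base)) / 60.0
    t90a = _first_crossing(t, a, a_base + 0.9 * (a_final - a_base)) / 60.0
    t50gs = _first_crossing(t, gs, gs_base + 0.5 * (gs_final - gs_base)) / 60.0

    # sum of samples strictly after the transition, up to and including 5 min
    in_window = (t > 0) & (t <= 300.0)
    ccf = float(np.sum(a[in_window]))
    int_window = t <= 300.0
    ccf_integral = float(np.trapezoid(a[int_window], t[int_window]))

    return InductionMetrics(
        t50a=t50a,
        t90a=t90a,
        ccf=ccf,
        t50gs=t50gs,
        gs_t0=gs_t0,
        a_final=a_final,
        gs_final=gs_final,
        ccf_integral=ccf_integral,
        provisional=provisional,
    )


def fit_stomatal_kinetics(
    segment: GasExTrace,
    rmse_warn: float = 0.02,
) -> KineticsFit:
    """Fit gs(t) = (g_start - g_end) exp(-t/k) + g_end to a transient.

    ``segment`` must start at the light transition.  The exponent uses a
    time-over-time-constant convention, so larger ``k`` means slower
    stomata; ``k`` is reported in minutes.
    """
    t = segment.column("time_s")
    gs = segment.column("gsw_mol_m2_s")
    if len(t) < 20:
        raise ValueError("need at least 20 samples to fit stomatal kinetics")
    t = t - t[0]

    g_start0, g_end0 = gs[0], gs[-1]
    span = g_end0 - g_start0
    if abs(span) < 1e-6 or np.ptp(gs) < 1e-6:
        return KineticsFit(
            g0=float(min(gs)), gmax=float(max(gs)), k_min=math.nan,
            direction="opening" if span >= 0 else "closing",
            rmse=float(np.std(gs)), degenerate=True,
            warning="conductance constant; time constant not identifiable",
        )

    def model(tt, g_start, g_end, k_s):
        return (g_start - g_end) * np.exp(-tt / k_s) + g_end

    k0 = max(t[-1] / 4.0, 30.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(
            model, t, gs, p0=[g_start0, g_end0, k0],
            bounds=([0.0, 0.0, 1.0], [10.0, 10.0, 1e6]),
            maxfev=20000,
        )
    g_start, g_end, k_s = popt
    resid = gs - model(t, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    warn = None
    if rmse > rmse_warn:
        warn = f"fit RMSE {rmse:.3g} above threshold {rmse_warn}; segment may be non-monotone"
    return KineticsFit(
        g0=float(min(g_start, g_end)),
        gmax=float(max(g_start, g_end)),
        k_min=float(k_s / 60.0),
        direction="opening" if g_end > g_start else "closing",
        rmse=rmse,
        warning=warn,
    )


def dynamic_aci(
    inductions: Dict[float, GasExTrace],
    gamma_star: float,
    rd: float,
    km: float,
    ci_ref: Optional[float] = None,
    reference_ca: float = 400.0,
    min_levels: int = 4,
) -> DynamicAciResult:
    """Time-resolved carboxylation capacity and stomatal limitation.

    ``inductions`` maps ambient CO2 level -> induction trace, all aligned so
    time zero is the shade-to-sun transition.  At each shared time point the
    (Ci, A) pairs across CO2 levels are fitted with the Rubisco-limited
    demand expression (``gamma_star``, ``rd``, ``km`` fixed, same units and
    temperature basis as the traces) to give a capacity ``vcmax_t``.

    Stomatal limitation compares the fitted curve at a reference Ci (the
    steady-state operating Ci of the ``reference_ca`` trace unless given)
    with the instantaneous Ci of that trace.
    """
    if reference_ca not in inductions:
        raise ValueError(f"no induction trace at the reference CO2 {reference_ca}")
    ref_trace = inductions[reference_ca]
    if ci_ref is None:
        ci_ref = float(ref_trace.column("ci_umol_mol")[-1])

    times = ref_trace.column("time_s")
    rows = []
    for ti in times:
        ci_pts, a_pts = [], []
        for trace in inductions.values():
            t = trace.column("time_s")
            j = np.searchsorted(t, ti)
            if j >= len(t) or abs(t[j] - ti) > 1e-6:
                continue
            ci = trace.column("ci_umol_mol")[j]
            if ci <= gamma_star + 1.0:
                continue
            ci_pts.append(ci)
            a_pts.append(trace.column("a_umol_m2_s")[j])
        if len(ci_pts) < min_levels:
            continue
        ci_arr = np.asarray(ci_pts)
        a_arr = np.asarray(a_pts)
        x = (ci_arr - gamma_star) / (ci_arr + km)
        vcmax_t = float(np.sum(x * (a_arr + rd)) / np.sum(x * x))

        def a_hat(ci_val: float) -> float:
            return vcmax_t * (ci_val - gamma_star) / (ci_val + km) - rd

        t_ref = ref_trace.column("time_s")
        ci_t = float(np.interp(ti, t_ref, ref_trace.column("ci_umol_mol")))
        a_ref = a_hat(ci_ref)
        sl = (a_ref - a_hat(ci_t)) / a_ref if a_ref > 0 else math.nan
        if not math.isnan(sl):
            sl = min(max(sl, 0.0), 1.0)
        rows.append({"time_s": ti, "vcmax_t": vcmax_t, "sl_t": sl,
                     "n_points": len(ci_pts)})
    return DynamicAciResult(data=pd.DataFrame(rows), ci_ref=ci_ref)


def ball_berry_fit(light_curve: GasExTrace, cs: Optional[float] = None) -> BallBerryParams:
    """Ordinary least squares of gs on A * h_s / c_s over a light curve.

    Surface humidity ``h_s`` is derived from cuvette VPD and leaf
    temperature (large boundary-layer conductance assumed); ``c_s`` defaults
    to the ambient CO2 column.  Only points with positive assimilation are
    used; at least 5 light levels are required.
    """
    df = light_curve.data
    use = df["a_umol_m2_s"] > 0
    if use.sum() < 5:
        raise ValueError("need at least 5 light levels with positive assimilation")
    a = df.loc[use, "a_umol_m2_s"].to_numpy(dtype=float)
    gs = df.loc[use, "gsw_mol_m2_s"].to_numpy(dtype=float)
    hs = np.array([
        k.relative_humidity_from_vpd(v, t)
        for v, t in zip(df.loc[use, "vpd_kpa"], df.loc[use, "tleaf_c"])
    ])
    cs_arr = (np.full(len(a), cs) if cs is not None
              else df.loc[use, "ca_umol_mol"].to_numpy(dtype=float))
    x = a * hs / cs_arr
    if np.ptp(x) < 1e-12:
        return BallBerryParams(slope=0.0, intercept=float(np.mean(gs)),
                               r_squared=0.0, physiological=False)
    slope, intercept = np.polyfit(x, gs, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((gs - pred) ** 2))
    ss_tot = float(np.sum((gs - gs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    return BallBerryParams(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        physiological=bool(slope > 0),
    )
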