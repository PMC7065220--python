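"""Steady-state CO2-response analysis.

Fits the biochemical demand model to CO2-response curves, estimates the
compensation point and day respiration from paired fluorescence, derives
mesophyll conductance by the variable-J method, refits carboxylation
capacity on a chloroplast-CO2 basis, and partitions the total limitation of
assimilation into stomatal, mesophyll and biochemical shares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import constants as k
from .fvcb import PhotoParams, TempResponse, electron_transport, normalize_to_25
from .gasex import GasExTrace

__all__ = [
    "ACiCurve",
    "FitResult",
    "GammaRdResult",
    "MesophyllResult",
    "LimitationPartition",
    "InconsistentFluxesError",
    "fit_aci",
    "leak_correct",
    "estimate_gamma_rd",
    "estimate_gamma_rd_gm",
    "fluorescence_j",
    "variable_j_gm",
    "fit_vcmax_cc",
    "limitation_partition",
    "operating_point",
    "iwue",
    "analyze_curve",
]


class InconsistentFluxesError(ValueError):
    """Electron transport too small to support the measured CO2 fluxes."""


@dataclass
class ACiCurve:
    """Ordered CO2-response observations from one leaf.

    Columns: ``ca_umol_mol`` (set/chamber CO2), ``ci_umol_mol``,
    ``a_umol_m2_s``, ``gsw_mol_m2_s``, ``ppfd``, ``tleaf_c``, ``vpd_kpa``
    and optionally ``phipsii``.
    """

    data: pd.DataFrame
    cultivar: str = ""
    replicate: int = 0

    LOW_CI = 250.0
    HIGH_CI = 700.0

    def __post_init__(self) -> None:
        required = ("ca_umol_mol", "ci_umol_mol", "a_umol_m2_s",
                    "gsw_mol_m2_s", "ppfd", "tleaf_c")
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"curve missing column(s): {', '.join(missing)}")
        ci = self.data["ci_umol_mol"].to_numpy(dtype=float)
        if len(ci) < 8:
            raise ValueError("a CO2-response curve needs at least 8 observations")
        if not np.all(ci > 0):
            raise ValueError("all Ci must be positive")
        if int((ci < self.LOW_CI).sum()) < 3:
            raise ValueError("need at least 3 points with Ci < 250 umol mol-1")
        if int((ci > self.HIGH_CI).sum()) < 2:
            raise ValueError("need at least 2 points with Ci > 700 umol mol-1")
        self.data = self.data.reset_index(drop=True)

    @property
    def t_leaf(self) -> float:
        return float(self.data["tleaf_c"].mean())

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


@dataclass
class FitResult:
    """Demand-model fit of one CO2-response curve.

    Fitted capacities are reported both at leaf temperature (``at_leaf``)
    and normalised to 25 C (``params``).  ``states`` labels the limiting
    process of each observation; ``transition_ci`` is the Ci where the
    carboxylation- and regeneration-limited rates cross.
    """

    params: PhotoParams
    at_leaf: Dict[str, float]
    states: List[str]
    rmse: float
    stderr: Dict[str, float]
    transition_ci: float
    transition_in_range: bool
    tpu_fitted: bool
    t_leaf: float


@dataclass(frozen=True)
class GammaRdResult:
    """Joint estimate of the compensation point and day respiration.

    Values are on the Ci basis at leaf temperature.  ``calibration`` scales
    fluorescence-derived electron transport to gas-exchange units.
    """

    gamma_star: float
    rd: float
    calibration: float
    flagged: bool


@dataclass
class MesophyllResult:
    """Variable-J mesophyll conductance and the implied chloroplast CO2."""

    gm: float
    cc: np.ndarray
    gamma_star: float
    rd: float
    vcmax_cc: Optional[float] = None


@dataclass(frozen=True)
class LimitationPartition:
    """Relative stomatal / mesophyll / biochemical limitation shares."""

    l_s: float
    l_m: float
    l_b: float

    def __post_init__(self) -> None:
        for name in ("l_s", "l_m", "l_b"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.l_s + self.l_m + self.l_b - 1.0) > 1e-9:
            raise ValueError("limitation shares must sum to 1")


def _model_a(ci: np.ndarray, q: np.ndarray, vcmax: float, jmax: float,
             tpu: Optional[float], rd: float, eff) -> np.ndarray:
    """Demand-model prediction on a Ci basis (infinite gm)."""
    j = np.array([electron_transport(qi, jmax, eff.alpha, eff.theta) for qi in q])
    wc = vcmax * (ci - eff.gamma_star) / (ci + eff.km)
    wj = j * (ci - eff.gamma_star) / (4.0 * ci + 8.0 * eff.gamma_star)
    w = np.minimum(wc, wj)
    if tpu is not None:
        w = np.where(ci > eff.gamma_star, np.minimum(w, 3.0 * tpu), w)
    return w - rd


def _states_of(ci: np.ndarray, q: np.ndarray, vcmax: float, jmax: float,
               tpu: Optional[float], eff) -> List[str]:
    out = []
    for cii, qi in zip(ci, q):
        j = electron_transport(qi, jmax, eff.alpha, eff.theta)
        rates = {
            "rubisco": vcmax * (cii - eff.gamma_star) / (cii + eff.km),
            "rubp_regen": j * (cii - eff.gamma_star) / (4.0 * cii + 8.0 * eff.gamma_star),
        }
        if tpu is not None and cii > eff.gamma_star:
            rates["tpu"] = 3.0 * tpu
        out.append(min(rates, key=rates.get))
    return out


def leak_correct(curve: ACiCurve, k_leak: float,
                 chamber_ambient: float = 400.0) -> ACiCurve:
    """Correct assimilation for diffusive leaks between cuvette and room air.

    ``A_corr = A + k_leak (Ca - chamber_ambient)``; ``k_leak`` is
    instrument-specific (mol m-2 s-1 per mole-fraction difference) and the
    correction is off unless explicitly requested.
    """
    if k_leak < 0:
        raise ValueError("k_leak must be non-negative")
    df = curve.data.copy()
    df["a_umol_m2_s"] = (df["a_umol_m2_s"]
                         + k_leak * (df["ca_umol_mol"] - chamber_ambient))
    return ACiCurve(data=df, cultivar=curve.cultivar, replicate=curve.replicate)


def fit_aci(
    curve: ACiCurve,
    fit_rd: bool = True,
    rd_fixed: float = 1.5,
    tpu_threshold: float = 0.02,
    params_template: Optional[PhotoParams] = None,
) -> FitResult:
    """Fit carboxylation/regeneration/TPU capacities to a CO2-response curve.

    The carboxylation-to-regeneration breakpoint is grid-searched over
    candidate partitions of the Ci-sorted points; each candidate is fitted
    by nonlinear least squares and the partition with minimum total SSE
    wins.  A triose-phosphate ceiling is added only when the high-Ci points
    flatten below the regeneration-limited prediction by more than
    ``tpu_threshold`` (relative), or when paired fluorescence shows electron
    transport declining with Ci; otherwise the capacity is reported absent.

    Fitting happens at leaf temperature; capacities are then normalised to
    25 C with the shipped temperature responses.
    """
    template = params_template or PhotoParams(vcmax25=100.0, jmax25=160.0, tpu25=11.0)
    t_leaf = curve.t_leaf
    eff = template.effective(t_leaf)

    order = np.argsort(curve.column("ci_umol_mol"))
    ci = curve.column("ci_umol_mol")[order]
    a = curve.column("a_umol_m2_s")[order]
    q = curve.column("ppfd")[order]
    n = len(ci)

    def two_branch_residuals(theta_vec, k_break):
        vcmax, jmax = theta_vec[0], theta_vec[1]
        rd = theta_vec[2] if fit_rd else rd_fixed
        j = np.array([electron_transport(qi, jmax, eff.alpha, eff.theta) for qi in q])
        wc = vcmax * (ci - eff.gamma_star) / (ci + eff.km)
        wj = j * (ci - eff.gamma_star) / (4.0 * ci + 8.0 * eff.gamma_star)
        pred = np.where(np.arange(n) < k_break, wc, wj) - rd
        return pred - a

    x0 = [100.0, 160.0] + ([1.5] if fit_rd else [])
    bounds = ([1.0, 1.0] + ([0.0] if fit_rd else []),
              [500.0, 800.0] + ([10.0] if fit_rd else []))

    best = None
    for k_break in range(3, n - 1):
        try:
            sol = least_squares(two_branch_residuals, x0, bounds=bounds,
                                args=(k_break,), method="trf")
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, k_break, sol)
    if best is None:
        raise RuntimeError("CO2-response fit failed for every candidate partition")
    _, k_break, sol = best
    vcmax, jmax = sol.x[0], sol.x[1]
    rd = sol.x[2] if fit_rd else rd_fixed

    # --- decide whether a TPU ceiling is warranted ---------------------------
    high = ci > curve.HIGH_CI
    pred_no_tpu = _model_a(ci, q, vcmax, jmax, None, rd, eff)
    flattening = False
    if high.any():
        rel_short = (np.mean(pred_no_tpu[high]) - np.mean(a[high])) / max(np.mean(a[high]), 1e-9)
        flattening = rel_short > tpu_threshold
    if not flattening and "phipsii" in curve.data.columns:
        phi = curve.column("phipsii")[order]
        if high.sum() >= 2 and np.isfinite(phi[high]).all():
            mid = (ci > 400) & (~high)
            if mid.any() and np.mean(phi[high]) < 0.98 * np.mean(phi[mid]):
                flattening = True

    tpu: Optional[float] = None
    if flattening:
        def full_residuals(theta_vec):
            vc, jm, tp = theta_vec[0], theta_vec[1], theta_vec[2]
            rd_l = theta_vec[3] if fit_rd else rd_fixed
            return _model_a(ci, q, vc, jm, tp, rd_l, eff) - a

        tpu0 = max((np.max(a) + rd) / 3.0, 1.0)
        x0_full = [vcmax, jmax, tpu0] + ([rd] if fit_rd else [])
        bounds_full = ([1.0, 1.0, 0.5] + ([0.0] if fit_rd else []),
                       [500.0, 800.0, 60.0] + ([10.0] if fit_rd else []))
        sol = least_squares(full_residuals, x0_full, bounds=bounds_full, method="trf")
        vcmax, jmax, tpu = sol.x[0], sol.x[1], sol.x[2]
        rd = sol.x[3] if fit_rd else rd_fixed

    resid = sol.fun
    rmse = float(np.sqrt(np.mean(resid**2)))
    stderr = _stderr_from_jac(sol, ["vcmax", "jmax"] + (["tpu"] if tpu is not None else [])
                              + (["rd"] if fit_rd else []))

    # transition Ci where the two limiting rates cross (at the curve's PPFD)
    j_sat = electron_transport(float(np.median(q)), jmax, eff.alpha, eff.theta)
    denom = 4.0 * vcmax - j_sat
    if denom > 0:
        transition_ci = (j_sat * eff.km - 8.0 * eff.gamma_star * vcmax) / denom
    else:
        transition_ci = math.inf
    in_range = bool(ci.min() <= transition_ci <= ci.max())

    states = _states_of(ci, q, vcmax, jmax, tpu, eff)
    at_leaf = {"vcmax": vcmax, "jmax": jmax, "rd": rd,
               "tpu": tpu if tpu is not None else math.nan}

    tmap = template.temp
    vcmax25 = normalize_to_25(tmap["vcmax"], vcmax, t_leaf)
    jmax25 = normalize_to_25(tmap["jmax"], jmax, t_leaf)
    rd25 = normalize_to_25(tmap["rd"], rd, t_leaf)
    tpu25 = (normalize_to_25(tmap["tpu"], tpu, t_leaf) if tpu is not None
             else math.nan)
    fitted = PhotoParams(
        vcmax25=vcmax25, jmax25=jmax25,
        tpu25=tpu25 if tpu is not None else template.tpu25,
        rd25=rd25, gamma_star25=template.gamma_star25, kc25=template.kc25,
        ko25=template.ko25, o2=template.o2, alpha=template.alpha,
        theta=template.theta, temp=template.temp,
    )
    return FitResult(
        params=fitted, at_leaf=at_leaf, states=states, rmse=rmse,
        stderr=stderr, transition_ci=float(transition_ci),
        transition_in_range=in_range, tpu_fitted=tpu is not None,
        t_leaf=t_leaf,
    )


def _stderr_from_jac(sol, names: Sequence[str]) -> Dict[str, float]:
    try:
        jac = sol.jac
        dof = max(len(sol.fun) - len(sol.x), 1)
        s2 = float(np.sum(sol.fun**2)) / dof
        cov = np.linalg.inv(jac.T @ jac) * s2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        return dict(zip(names, se.tolist()))
    except np.linalg.LinAlgError:
        return {name: math.nan for name in names}


def fluorescence_j(
    phipsii: float | np.ndarray,
    q: float | np.ndarray,
    absorptance: float = k.ABSORPTANCE_DEFAULT,
    beta: float = k.BETA_DEFAULT,
) -> float | np.ndarray:
    """Fluorescence-derived electron transport: J = phiPSII * Q * abs * beta."""
    phi = np.asarray(phipsii, dtype=float)
    if np.any((phi < 0) | (phi > 1)):
        raise ValueError("phiPSII must lie in [0, 1]")
    out = phi * np.asarray(q, dtype=float) * absorptance * beta
    return float(out) if out.ndim == 0 else out


def estimate_gamma_rd(
    curve: ACiCurve,
    absorptance: float = k.ABSORPTANCE_DEFAULT,
    beta: float = k.BETA_DEFAULT,
    low_ci_max: float = 250.0,
) -> GammaRdResult:
    """Joint estimate of the compensation point and day respiration.

    Over the low-Ci region the measured assimilation is regressed on the
    fluorescence-derived electron transport through
    ``A = s*Jf/4 * (Ci - G) / (Ci + 2G) - Rd`` with the compensation point
    ``G``, respiration ``Rd`` and a fluorescence calibration ``s`` free.
    This is a stand-in construction for the cited joint gas-exchange /
    fluorescence procedure; estimates are on the Ci basis at leaf
    temperature.
    """
    if "phipsii" not in curve.data.columns:
        raise ValueError("compensation-point estimation needs paired fluorescence")
    ci = curve.column("ci_umol_mol")
    mask = (ci < low_ci_max) & np.isfinite(curve.column("phipsii"))
    if int(mask.sum()) < 4:
        raise ValueError(
            f"need >= 4 low-Ci (< {low_ci_max:g}) points with fluorescence; "
            f"got {int(mask.sum())}"
        )
    ci_l = ci[mask]
    a_l = curve.column("a_umol_m2_s")[mask]
    jf = fluorescence_j(curve.column("phipsii")[mask], curve.column("ppfd")[mask],
                        absorptance, beta)

    def residuals(theta_vec):
        g, rd, s = theta_vec
        return (s * jf / 4.0) * (ci_l - g) / (ci_l + 2.0 * g) - rd - a_l

    sol = least_squares(residuals, [45.0, 1.5, 1.0],
                        bounds=([5.0, 0.0, 0.2], [120.0, 10.0, 5.0]), method="trf")
    g, rd, s = sol.x
    flagged = not (20.0 <= g <= 80.0) or rd <= 0.0
    return GammaRdResult(gamma_star=float(g), rd=float(rd), calibration=float(s),
                         flagged=bool(flagged))


def estimate_gamma_rd_gm(
    curve: ACiCurve,
    absorptance: float = k.ABSORPTANCE_DEFAULT,
    beta: float = k.BETA_DEFAULT,
    max_ci: float = 500.0,
    rd: Optional[float] = None,
) -> Tuple[float, float, float]:
    """Joint estimate of compensation point, respiration and mesophyll conductance.

    Fits ``A = Jf/4 (Cc - G)/(Cc + 2G) - Rd`` with ``Cc = Ci - A/gm`` over
    all points below ``max_ci`` (the fluorescence identity holds whatever
    process limits, so mid-range points may be included).  Multistart
    nonlinear least squares; returns ``(gamma_star, rd, gm)`` on the leaf
    temperature basis.

    The three-parameter problem has a shallow ridge (G up / Rd down / gm up)
    that noise exploits; anchoring ``rd`` (e.g. from the demand-model fit of
    the same curve) makes the estimate markedly more robust.
    """
    if "phipsii" not in curve.data.columns:
        raise ValueError("joint estimation needs paired fluorescence")
    ci = curve.column("ci_umol_mol")
    sel = (ci < max_ci) & np.isfinite(curve.column("phipsii"))
    if int(sel.sum()) < 5:
        raise ValueError("need >= 5 points with fluorescence below the Ci cutoff")
    ci_s = ci[sel]
    a_s = curve.column("a_umol_m2_s")[sel]
    jf = fluorescence_j(curve.column("phipsii")[sel], curve.column("ppfd")[sel],
                        absorptance, beta)

    def model_minus_obs(g, rd_v, gm):
        cc = ci_s - a_s / gm
        return (jf / 4.0) * (cc - g) / (cc + 2.0 * g) - rd_v - a_s

    best = None
    if rd is None:
        def residuals(theta_vec):
            return model_minus_obs(theta_vec[0], theta_vec[1], theta_vec[2])
        starts = ([45.0, 1.5, 0.3], [60.0, 0.5, 1.0], [35.0, 3.0, 0.15],
                  [50.0, 1.0, 0.6])
        lo, hi = [5.0, 0.0, 0.01], [120.0, 10.0, 10.0]
    else:
        def residuals(theta_vec):
            return model_minus_obs(theta_vec[0], rd, theta_vec[1])
        starts = ([45.0, 0.3], [60.0, 1.0], [35.0, 0.15], [50.0, 0.6])
        lo, hi = [5.0, 0.01], [120.0, 10.0]
    for x0 in starts:
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    if rd is None:
        g, rd_out, gm = best.x
    else:
        g, gm = best.x
        rd_out = rd
    return float(g), float(rd_out), float(gm)


def variable_j_gm(
    a: float,
    ci: float,
    j: float,
    gamma_star: float,
    rd: float,
) -> float:
    """Mesophyll conductance from one paired gas-exchange/fluorescence point.

    ``gm = A / (Ci - G*[J + 8(A+Rd)] / [J - 4(A+Rd)])``.  Raises
    :class:`InconsistentFluxesError` when ``J <= 4(A+Rd)`` (electron
    transport cannot support the carboxylation flux, as happens under a
    triose-phosphate limitation).  Returns ``nan`` when the implied
    chloroplast CO2 is not below Ci, ``inf`` for exactly zero drawdown.
    """
    denom = j - 4.0 * (a + rd)
    if denom <= 0.0:
        raise InconsistentFluxesError(
            f"J={j:.3g} <= 4(A+Rd)={4 * (a + rd):.3g}: electron transport "
            "inconsistent with fluxes"
        )
    cc = gamma_star * (j + 8.0 * (a + rd)) / denom
    drawdown = ci - cc
    if abs(drawdown) < 1e-9:
        return math.inf
    if drawdown < 0.0 or cc <= 0.0:
        return math.nan
    return a / drawdown


def fit_vcmax_cc(
    curve: ACiCurve,
    gm: float,
    gamma_star: float,
    rd: float,
    max_ci: Optional[float] = None,
    params_template: Optional[PhotoParams] = None,
) -> MesophyllResult:
    """Carboxylation capacity refitted on a chloroplast-CO2 basis.

    ``Cc = Ci - A/gm`` pointwise; the carboxylation-limited demand
    expression is then fitted over the low-Ci points (``Ci < max_ci``,
    default the curve's low-Ci bound).  ``gamma_star``/``rd`` are taken on
    the same basis and temperature as the curve.  Returns the capacity
    normalised to 25 C.
    """
    if not (gm > 0) or not math.isfinite(gm):
        raise ValueError("finite positive gm required")
    template = params_template or PhotoParams(vcmax25=100.0, jmax25=160.0, tpu25=11.0)
    t_leaf = curve.t_leaf
    eff = template.effective(t_leaf)
    max_ci = max_ci if max_ci is not None else curve.LOW_CI

    ci = curve.column("ci_umol_mol")
    a = curve.column("a_umol_m2_s")
    mask = ci < max_ci
    if int(mask.sum()) < 3:
        raise ValueError("need at least 3 carboxylation-limited points")
    cc = ci[mask] - a[mask] / gm
    if np.any(cc <= gamma_star):
        mask2 = cc > gamma_star
        cc, a_use = cc[mask2], a[mask][mask2]
    else:
        a_use = a[mask]
    if len(cc) < 3:
        raise ValueError("too few points above the compensation point on a Cc basis")

    x = (cc - gamma_star) / (cc + eff.km)
    vcmax_leaf = float(np.sum(x * (a_use + rd)) / np.sum(x * x))
    vcmax25 = normalize_to_25(template.temp["vcmax"], vcmax_leaf, t_leaf)
    cc_all = ci - a / gm
    return MesophyllResult(gm=gm, cc=cc_all, gamma_star=gamma_star, rd=rd,
                           vcmax_cc=vcmax25)


def limitation_partition(
    vcmax: float,
    gsc: float,
    gm: float,
    cc: float,
    kc: float = k.KC25,
    ko: float = k.KO25,
    o2: float = k.O2_DEFAULT,
    gamma_star: float = k.GAMMA_STAR25,
) -> LimitationPartition:
    """Relative stomatal / mesophyll / biochemical limitation shares.

    All inputs at the operating point and a common temperature basis:
    ``vcmax`` the carboxylation capacity, ``gsc`` the stomatal CO2
    conductance, ``gm`` mesophyll conductance, ``cc`` chloroplast CO2.
    Shares sum to one by construction.
    """
    if not (gsc > 0) or not (gm > 0):
        raise ValueError("conductances must be positive")
    km = kc * (1.0 + o2 / ko)
    dadc = vcmax * (gamma_star + km) / (cc + km) ** 2
    g_tot = 1.0 / (1.0 / gsc + 1.0 / gm)
    denom = g_tot + dadc
    l_s = (g_tot / gsc) * dadc / denom
    l_m = (g_tot / gm) * dadc / denom
    l_b = g_tot / denom
    return LimitationPartition(l_s=l_s, l_m=l_m, l_b=l_b)


def operating_point(curve: ACiCurve, ca_target: float = 400.0,
                    tol: float = 5.0) -> Tuple[float, float, float]:
    """Mean (A, gsw, Ci) over the curve's points at the ambient CO2 setpoint."""
    ca = curve.column("ca_umol_mol")
    mask = np.abs(ca - ca_target) <= tol
    if not mask.any():
        raise ValueError(f"curve has no points at chamber CO2 {ca_target:g}")
    a = float(curve.column("a_umol_m2_s")[mask].mean())
    gsw = float(curve.column("gsw_mol_m2_s")[mask].mean())
    ci = float(curve.column("ci_umol_mol")[mask].mean())
    return a, gsw, ci


def iwue(a: float | Sequence[float], gsw: float | Sequence[float],
         convention: str = "mean_of_ratios") -> float:
    """Intrinsic water-use efficiency, A / gs (umol CO2 per mol H2O).

    For replicate arrays, ``mean_of_ratios`` averages per-replicate ratios
    (the reporting convention of the summary tables); ``ratio_of_means``
    divides mean A by mean gs.
    """
    a_arr = np.atleast_1d(np.asarray(a, dtype=float))
    g_arr = np.atleast_1d(np.asarray(gsw, dtype=float))
    if a_arr.shape != g_arr.shape:
        raise ValueError("a and gsw must have matching shapes")
    if convention == "mean_of_ratios":
        return float(np.mean(a_arr / g_arr))
    if convention == "ratio_of_means":
        return float(a_arr.mean() / g_arr.mean())
    raise ValueError(f"unknown convention {convention!r}")


@dataclass
class CurveAnalysis:
    """Full steady-state analysis of one CO2-response curve."""

    fit: FitResult
    gamma_rd: GammaRdResult
    gm: float
    vcmax_cc: Optional[float]
    partition: Optional[LimitationPartition]
    operating: Tuple[float, float, float]
    iwue: float


def analyze_curve(
    curve: ACiCurve,
    absorptance: float = k.ABSORPTANCE_DEFAULT,
    beta: float = k.BETA_DEFAULT,
) -> CurveAnalysis:
    """Run the whole steady-state chain on one curve.

    Demand-model fit, compensation-point/respiration estimation, variable-J
    mesophyll conductance at the ambient-CO2 operating point, Cc-basis
    capacity refit, and the limitation partition at the operating point.
    """
    fit = fit_aci(curve)
    a_op, gsw_op, ci_op = operating_point(curve)

    # joint fluorescence estimate with Rd anchored by the demand-model fit;
    # this pins down gamma_star and gm together (see estimate_gamma_rd_gm)
    g_joint, rd_joint, gm = estimate_gamma_rd_gm(curve, absorptance, beta,
                                                 rd=fit.at_leaf["rd"])
    gr = GammaRdResult(gamma_star=g_joint, rd=rd_joint, calibration=1.0,
                       flagged=not (20.0 <= g_joint <= 80.0))

    vcmax_cc = None
    partition = None
    if math.isfinite(gm) and gm > 0:
        meso = fit_vcmax_cc(curve, gm, gr.gamma_star, gr.rd)
        vcmax_cc = meso.vcmax_cc
        t_leaf = curve.t_leaf
        eff = fit.params.effective(t_leaf)
        vcmax_cc_leaf = vcmax_cc * eff.vcmax / fit.params.vcmax25
        cc_op = ci_op - a_op / gm
        partition = limitation_partition(
            vcmax_cc_leaf, gsw_op / k.GSW_TO_GSC, gm, cc_op,
            kc=eff.kc, ko=eff.ko, o2=eff.o2, gamma_star=eff.gamma_star,
        )
    return CurveAnalysis(
        fit=fit, gamma_rd=gr, gm=gm, vcmax_cc=vcmax_cc, partition=partition,
        operating=(a_op, gsw_op, ci_op), iwue=iwue(a_op, gsw_op),
    )
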