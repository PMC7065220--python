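"""Steady-state biochemical model of C3 leaf photosynthesis.

The kernel couples three potential limitations of net CO2 assimilation
(carboxylation capacity, electron-transport-limited RuBP regeneration and
triose-phosphate utilisation) to the CO2 diffusion path through stomata and
mesophyll.  All other modules evaluate photosynthesis through the functions
defined here.

Units follow gas-exchange convention throughout: fluxes in umol m-2 s-1,
mole fractions in umol mol-1 (O2 in mmol mol-1), conductances in
mol m-2 s-1.  Stomatal conductance is carried on the water-vapour basis and
converted to a CO2 basis internally where needed; mesophyll conductance is a
CO2 conductance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, NamedTuple, Optional

from . import constants as k

__all__ = [
    "TempResponse",
    "PhotoParams",
    "DemandResult",
    "SupplyDemandError",
    "arrhenius_scale",
    "normalize_to_25",
    "electron_transport",
    "co2_demand",
    "solve_supply_demand",
    "default_temp_map",
]


class SupplyDemandError(RuntimeError):
    """Raised when the supply/demand intersection cannot be bracketed."""


@dataclass(frozen=True)
class TempResponse:
    """Temperature response of one parameter.

    ``value25`` is the value at 25 C.  ``ha`` is the activation energy
    (kJ mol-1).  If ``hd`` (deactivation energy) is given, ``ds`` (entropy
    term, kJ mol-1 K-1) must be given too and the peaked form is used.
    """

    value25: float
    ha: float
    hd: Optional[float] = None
    ds: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.value25 > 0):
            raise ValueError("value25 must be positive")
        if (self.hd is None) != (self.ds is None):
            raise ValueError("hd and ds must be given together")


def default_temp_map() -> Dict[str, TempResponse]:
    """Shipped temperature responses (value25 placeholders are scale factors).

    The ``value25`` of each entry is 1.0: entries are used as pure scale
    functions applied to the parameter values held in :class:`PhotoParams`.
    """
    return {
        "vcmax": TempResponse(1.0, k.VCMAX_HA, k.HD_DEFAULT, k.DS_DEFAULT),
        "jmax": TempResponse(1.0, k.JMAX_HA, k.HD_DEFAULT, k.DS_DEFAULT),
        "tpu": TempResponse(1.0, k.TPU_HA),
        "rd": TempResponse(1.0, k.RD_HA),
        "gamma_star": TempResponse(1.0, k.GAMMA_STAR_HA),
        "kc": TempResponse(1.0, k.KC_HA),
        "ko": TempResponse(1.0, k.KO_HA),
    }


def _check_temperature(t_leaf: float) -> None:
    if not math.isfinite(t_leaf):
        raise ValueError("leaf temperature must be finite")
    if not (0.0 <= t_leaf <= 50.0):
        raise ValueError(f"leaf temperature {t_leaf} C outside [0, 50]")


def arrhenius_scale(tr: TempResponse, t_leaf: float) -> float:
    """Value of a parameter at leaf temperature ``t_leaf`` (C).

    Plain Arrhenius scaling from 25 C; when deactivation terms are present
    the peaked correction is applied on top.
    """
    _check_temperature(t_leaf)
    tk = t_leaf + 273.15
    out = tr.value25 * math.exp(tr.ha * (tk - k.T_REF_K) / (k.T_REF_K * k.R_GAS * tk))
    if tr.hd is not None:
        num = 1.0 + math.exp((k.T_REF_K * tr.ds - tr.hd) / (k.T_REF_K * k.R_GAS))
        den = 1.0 + math.exp((tk * tr.ds - tr.hd) / (tk * k.R_GAS))
        out *= num / den
    return out


def normalize_to_25(tr: TempResponse, value_at_t: float, t_leaf: float) -> float:
    """Invert :func:`arrhenius_scale`: value at ``t_leaf`` -> value at 25 C."""
    scale = arrhenius_scale(replace(tr, value25=1.0), t_leaf)
    return value_at_t / scale


@dataclass(frozen=True)
class PhotoParams:
    """Biochemical capacities and kinetic constants of one leaf at 25 C."""

    vcmax25: float
    jmax25: float
    tpu25: float
    rd25: float = 1.5
    gamma_star25: float = k.GAMMA_STAR25
    kc25: float = k.KC25
    ko25: float = k.KO25
    o2: float = k.O2_DEFAULT
    alpha: float = k.ALPHA_DEFAULT
    theta: float = k.THETA_DEFAULT
    temp: Dict[str, TempResponse] = field(default_factory=default_temp_map)

    def __post_init__(self) -> None:
        for name in ("vcmax25", "jmax25", "tpu25", "rd25"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.theta <= 1):
            raise ValueError("theta must lie in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    def _scale(self, name: str, t_leaf: float) -> float:
        tr = self.temp.get(name)
        if tr is None:
            return 1.0
        return arrhenius_scale(replace(tr, value25=1.0), t_leaf)

    def effective(self, t_leaf: float = 25.0) -> "EffectiveParams":
        """Parameter values at leaf temperature ``t_leaf``."""
        _check_temperature(t_leaf)
        return EffectiveParams(
            vcmax=self.vcmax25 * self._scale("vcmax", t_leaf),
            jmax=self.jmax25 * self._scale("jmax", t_leaf),
            tpu=self.tpu25 * self._scale("tpu", t_leaf),
            rd=self.rd25 * self._scale("rd", t_leaf),
            gamma_star=self.gamma_star25 * self._scale("gamma_star", t_leaf),
            kc=self.kc25 * self._scale("kc", t_leaf),
            ko=self.ko25 * self._scale("ko", t_leaf),
            o2=self.o2,
            alpha=self.alpha,
            theta=self.theta,
        )


class EffectiveParams(NamedTuple):
    vcmax: float
    jmax: float
    tpu: float
    rd: float
    gamma_star: float
    kc: float
    ko: float
    o2: float
    alpha: float
    theta: float

    @property
    def km(self) -> float:
        """Effective Michaelis constant for CO2 in air, umol mol-1."""
        return self.kc * (1.0 + self.o2 / self.ko)


@dataclass(frozen=True)
class DemandResult:
    """Net assimilation and the process limiting it at one chloroplast CO2."""

    a: float
    state: str  # one of 'rubisco', 'rubp_regen', 'tpu'


def electron_transport(q: float, jmax: float, alpha: float, theta: float) -> float:
    """Potential electron transport rate under incident PPFD ``q``.

    Smaller root of the non-rectangular hyperbola
    ``theta J^2 - (alpha q + jmax) J + alpha q jmax = 0``; theta == 0 falls
    back to the rectangular-hyperbola limit.
    """
    if q < 0:
        raise ValueError("PPFD must be non-negative")
    if q == 0.0 or jmax == 0.0:
        return 0.0
    aq = alpha * q
    if theta == 0.0:
        return aq * jmax / (aq + jmax)
    b = aq + jmax
    disc = b * b - 4.0 * theta * aq * jmax
    return (b - math.sqrt(max(disc, 0.0))) / (2.0 * theta)


def co2_demand(
    cc: float,
    p: PhotoParams | EffectiveParams,
    j: float,
    f_act: float = 1.0,
    t_leaf: float = 25.0,
) -> DemandResult:
    """Net assimilation demanded by the biochemistry at chloroplast CO2 ``cc``.

    ``j`` is the operating electron transport rate (umol m-2 s-1);
    ``f_act`` scales carboxylation capacity for Rubisco activation state.
    """
    if not (cc > 0):
        raise ValueError("cc must be positive")
    if not (0.0 <= f_act <= 1.0):
        raise ValueError("f_act must lie in [0, 1]")
    eff = p if isinstance(p, EffectiveParams) else p.effective(t_leaf)

    wc = f_act * eff.vcmax * (cc - eff.gamma_star) / (cc + eff.km)
    wj = j * (cc - eff.gamma_star) / (4.0 * cc + 8.0 * eff.gamma_star)
    rates = {"rubisco": wc, "rubp_regen": wj}
    if cc > eff.gamma_star:
        # TPU sets a ceiling only once gross fixation is positive
        rates["tpu"] = 3.0 * eff.tpu
    state = min(rates, key=rates.get)
    return DemandResult(a=rates[state] - eff.rd, state=state)


def _branch_cc(a_cap: float, b_half: float, gamma_star: float, rd: float,
               g_tot: float, ca: float) -> float:
    """Chloroplast CO2 where a saturating demand branch meets the supply line.

    Demand branch: A = a_cap (Cc - gamma_star)/(Cc + b_half) - rd.
    Supply line:   A = g_tot (Ca - Cc).
    Returns the positive root of the resulting quadratic.
    """
    bq = a_cap - rd - g_tot * (ca - b_half)
    cq = g_tot * ca * b_half + a_cap * gamma_star + rd * b_half
    disc = bq * bq + 4.0 * g_tot * cq
    return (-bq + math.sqrt(disc)) / (2.0 * g_tot)


def solve_supply_demand(
    ca: float,
    gsc: float,
    gm: float,
    p: PhotoParams | EffectiveParams,
    q: float,
    f_act: float = 1.0,
    t_leaf: float = 25.0,
    j: Optional[float] = None,
) -> tuple[float, float, float]:
    """Intersect biochemical demand with the CO2 diffusion supply path.

    Solves A = gsc (Ca - Ci) = gm (Ci - Cc) = demand(Cc) and returns
    ``(A, Ci, Cc)``.  ``gsc`` is the stomatal conductance to CO2; pass
    ``math.inf`` for either conductance to remove that resistance.

    Each demand branch meets the linear supply path at a closed-form root;
    the governing branch is the one yielding the smallest assimilation.  A
    residual check (1e-4 umol m-2 s-1) guards the algebra; failure raises
    :class:`SupplyDemandError` rather than silently clamping.
    """
    if not (ca > 0):
        raise ValueError("ca must be positive")
    if not (gsc > 0) or not (gm > 0):
        raise ValueError("conductances must be positive (use math.inf to omit)")
    eff = p if isinstance(p, EffectiveParams) else p.effective(t_leaf)
    if j is None:
        j = electron_transport(q, eff.jmax, eff.alpha, eff.theta)

    if math.isinf(gsc) and math.isinf(gm):
        res = co2_demand(ca, eff, j, f_act)
        return res.a, ca, ca

    g_tot = 1.0 / (1.0 / gsc + 1.0 / gm)

    cc_c = _branch_cc(f_act * eff.vcmax, eff.km, eff.gamma_star, eff.rd, g_tot, ca)
    cc_j = _branch_cc(j / 4.0, 2.0 * eff.gamma_star, eff.gamma_star, eff.rd, g_tot, ca)
    # governing branch = smallest A = largest Cc on the supply line
    cc = max(cc_c, cc_j)
    a = g_tot * (ca - cc)
    if cc > eff.gamma_star and a > 3.0 * eff.tpu - eff.rd:
        a = 3.0 * eff.tpu - eff.rd
        cc = ca - a / g_tot

    demand = co2_demand(cc, eff, j, f_act)
    if abs(demand.a - a) > 1e-4:
        raise SupplyDemandError(
            f"supply/demand residual {demand.a - a:.3e} exceeds tolerance "
            f"(ca={ca}, gsc={gsc}, gm={gm}, q={q})"
        )
    ci = ca - a / gsc if math.isfinite(gsc) else ca
    cc_out = ci - a / gm if math.isfinite(gm) else ci
    return a, ci, cc_out
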