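"""Synthetic gas-exchange data generated from known parameters.

Every input the analysis modules consume — CO2-response curves, shade-to-sun
induction traces, sun-shade-sun relaxation traces and light-response
curves — can be produced here from a :class:`~cassleaf.simulator.CultivarPreset`
plus Gaussian instrument noise, so the whole pipeline is testable without
instrument files.

Noise is homoscedastic Gaussian from numpy's default PCG64 generator; a
fixed seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import constants as k
from .dynamics import BallBerryParams
from .fvcb import PhotoParams
from .gasex import GasExTrace
from .simulator import (
    CultivarPreset,
    Environment,
    LightRegime,
    f_act_steady,
    simulate,
    steady_state_point,
)
from .steady_state import ACiCurve
from .tables import load_induction_traits, load_steady_state_traits

__all__ = [
    "NoiseModel",
    "CO2_SEQUENCE",
    "make_preset",
    "preset_names",
    "generate_aci",
    "generate_induction",
    "generate_relaxation",
    "generate_dynamic_aci_set",
    "generate_light_curve",
]

# 13-step chamber CO2 protocol for CO2-response curves, umol mol-1
CO2_SEQUENCE: Tuple[float, ...] = (
    400, 270, 150, 100, 75, 50, 400, 400, 600, 800, 1100, 1300, 1500,
)

LN2 = math.log(2.0)

# Trait envelopes used when drawing random presets
_RANGES = {
    "vcmax": (95.0, 118.0),
    "jmax": (149.0, 184.0),
    "tpu": (9.9, 11.7),
    "gs": (0.25, 0.34),
    "gst0": (0.005, 0.054),
    "t50gs": (5.7, 10.6),
}

# friendly aliases for the contrasting shipped presets
_ALIASES = {"fast": "TMS98/0505", "slow": "TME693"}

# closing is faster than opening on average; kd is derived from ki with this
# ratio when no independent estimate is available
_KD_OVER_KI = 0.6


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian instrument-noise magnitudes and the RNG seed."""

    sigma_a: float = 0.3        # umol m-2 s-1
    sigma_gs: float = 0.01      # mol m-2 s-1
    sigma_phi: float = 0.01     # dimensionless
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.sigma_a, self.sigma_gs, self.sigma_phi) < 0:
            raise ValueError("noise magnitudes must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


NOISELESS = NoiseModel(0.0, 0.0, 0.0, seed=0)


def preset_names() -> Tuple[str, ...]:
    names = tuple(load_steady_state_traits()["cultivar"])
    return names + tuple(_ALIASES)


def _build_preset(name: str, vcmax: float, jmax: float, tpu: float, gs: float,
                  gst0: float, t50gs: float, env: Optional[Environment] = None,
                  rd: float = 1.5, gm: float = 0.4) -> CultivarPreset:
    env = env or Environment()
    params = PhotoParams(vcmax25=vcmax, jmax25=jmax, tpu25=tpu, rd25=rd)
    ki = t50gs / LN2
    kd = _KD_OVER_KI * ki
    # slope chosen so the empirical target reproduces the observed
    # light-saturated gs at the observed light-saturated A
    from .fvcb import solve_supply_demand
    a_sat, _, _ = solve_supply_demand(env.ca, gs / k.GSW_TO_GSC, gm, params,
                                      q=1500.0, t_leaf=env.tleaf_c,
                                      f_act=f_act_steady(1500.0, 0.3))
    intercept = gst0
    slope = (gs - intercept) * env.ca / (env.hs * a_sat)
    bb = BallBerryParams(slope=slope, intercept=intercept)
    return CultivarPreset(
        name=name, params=params, ki_min=ki, kd_min=kd, bb=bb,
        gm=gm, gs_ref=gs, gst0=gst0,
    )


def make_preset(name: Optional[str] = None, seed: Optional[int] = None,
                env: Optional[Environment] = None) -> CultivarPreset:
    """A shipped per-cultivar preset by name, or a random one from a seed.

    Shipped presets are built from the bundled trait tables: biochemical
    capacities and light-saturated conductance from the steady-state table,
    stomatal kinetics from the induction table (``ki = T50gs / ln 2``).
    ``"fast"`` and ``"slow"`` alias the cultivars with the largest and
    smallest dark-adapted conductance.
    """
    if name is None and seed is None:
        raise ValueError("give a preset name or a seed for a random preset")
    if name is not None:
        name = _ALIASES.get(name, name)
        traits = load_steady_state_traits().set_index("cultivar")
        induct = load_induction_traits().set_index("cultivar")
        if name not in traits.index:
            known = ", ".join(preset_names())
            raise KeyError(f"unknown preset {name!r}; known presets: {known}")
        t = traits.loc[name]
        i = induct.loc[name]
        return _build_preset(name, t["vcmax"], t["jmax"], t["vtpu"], t["gs"],
                             i["gst0"], i["t50gs"], env=env)
    rng = np.random.default_rng(seed)
    draw = {key: rng.uniform(*bounds) for key, bounds in _RANGES.items()}
    return _build_preset(f"random-{seed}", draw["vcmax"], draw["jmax"],
                         draw["tpu"], draw["gs"], draw["gst0"], draw["t50gs"],
                         env=env)


def _actual_j(a: float, cc: float, eff) -> float:
    """Electron transport consistent with net assimilation at this Cc."""
    return 4.0 * (a + eff.rd) * (cc + 2.0 * eff.gamma_star) / (cc - eff.gamma_star)


def generate_aci(
    preset: CultivarPreset,
    noise: NoiseModel = NOISELESS,
    ca_sequence: Sequence[float] = CO2_SEQUENCE,
    q: float = 1500.0,
    env: Optional[Environment] = None,
    absorptance: float = k.ABSORPTANCE_DEFAULT,
    beta: float = k.BETA_DEFAULT,
    replicate: int = 1,
) -> ACiCurve:
    """CO2-response curve with paired fluorescence at fixed gs and gm.

    Each point is the supply/demand solution at one chamber CO2 level; the
    emitted PSII efficiency is consistent with the electron transport
    actually required to support the modelled assimilation, so it declines
    with CO2 once the triose-phosphate ceiling binds.
    """
    from .fvcb import solve_supply_demand

    env = env or Environment()
    rng = noise.rng()
    eff = preset.params.effective(env.tleaf_c)
    gsc = preset.gs_ref / k.GSW_TO_GSC

    rows = []
    for i, ca in enumerate(ca_sequence):
        a, ci, cc = solve_supply_demand(ca, gsc, preset.gm, preset.params,
                                        q=q, t_leaf=env.tleaf_c)
        j_act = _actual_j(a, cc, eff)
        phi = j_act / (q * absorptance * beta)
        a_obs = a + rng.normal(0.0, noise.sigma_a)
        gs_obs = max(preset.gs_ref + rng.normal(0.0, noise.sigma_gs), 1e-4)
        phi_obs = min(max(phi + rng.normal(0.0, noise.sigma_phi), 0.0), 1.0)
        ci_obs = ca - a_obs * k.GSW_TO_GSC / gs_obs
        rows.append({
            "time_s": 120.0 * i, "ppfd": q, "ca_umol_mol": ca,
            "a_umol_m2_s": a_obs, "gsw_mol_m2_s": gs_obs,
            "ci_umol_mol": ci_obs, "tleaf_c": env.tleaf_c,
            "vpd_kpa": env.vpd_kpa, "phipsii": phi_obs,
        })
    df = pd.DataFrame(rows)
    return ACiCurve(data=df, cultivar=preset.name, replicate=replicate)


def _simulate_phases(
    preset: CultivarPreset,
    phases: Sequence[Tuple[float, float, Environment]],
    init_state: Tuple[float, float],
    dt: float,
    sample_every_s: float,
) -> pd.DataFrame:
    """Chain constant-environment simulations, carrying state across phases.

    ``phases`` is a list of (duration_s, ppfd, env); needed because the
    chamber CO2 may change between phases (e.g. the low-CO2 shade variant).
    """
    frames = []
    t_offset = 0.0
    state = init_state
    for i, (dur, ppfd, env) in enumerate(phases):
        regime = LightRegime(steps=((dur, ppfd),), env=env)
        trace = simulate(preset, regime, dt=dt, sample_every_s=sample_every_s,
                         init_state=state)
        df = trace.data.copy()
        state = (float(df["gs"].iloc[-1]), float(df["f_act"].iloc[-1]))
        if i < len(phases) - 1:
            df = df.iloc[:-1]  # next phase re-records the boundary sample
        df["time_s"] += t_offset
        df["ppfd"] = ppfd
        df["ca"] = env.ca
        df["vpd_kpa"] = env.vpd_kpa
        df["tleaf_c"] = env.tleaf_c
        frames.append(df)
        t_offset += dur
    return pd.concat(frames, ignore_index=True)


def _to_trace(sim_df: pd.DataFrame, preset: CultivarPreset, noise: NoiseModel,
              rng: np.random.Generator, protocol: str, replicate: int) -> GasExTrace:
    n = len(sim_df)
    a_obs = sim_df["a"].to_numpy() + rng.normal(0.0, noise.sigma_a, n)
    gs_obs = np.maximum(sim_df["gs"].to_numpy() + rng.normal(0.0, noise.sigma_gs, n),
                        1e-4)
    ca = sim_df["ca"].to_numpy()
    ci_obs = ca - a_obs * k.GSW_TO_GSC / gs_obs
    df = pd.DataFrame({
        "time_s": sim_df["time_s"].to_numpy(),
        "ppfd": sim_df["ppfd"].to_numpy(),
        "ca_umol_mol": ca,
        "a_umol_m2_s": a_obs,
        "gsw_mol_m2_s": gs_obs,
        "ci_umol_mol": ci_obs,
        "tleaf_c": sim_df["tleaf_c"].to_numpy(),
        "vpd_kpa": sim_df["vpd_kpa"].to_numpy(),
    })
    return GasExTrace(data=df, cultivar=preset.name, replicate=replicate,
                      protocol=protocol)


def generate_induction(
    preset: CultivarPreset,
    noise: NoiseModel = NOISELESS,
    ca: float = 400.0,
    shade_ca: Optional[float] = None,
    shade_ppfd: float = 50.0,
    shade_s: float = 300.0,
    high_ppfd: float = 1500.0,
    high_s: float = 1800.0,
    preopen: bool = False,
    dt: float = 0.5,
    env: Optional[Environment] = None,
    replicate: int = 1,
) -> GasExTrace:
    """Dark-adapted shade-to-sun induction trace sampled every 10 s.

    The default protocol is 5 min of deep shade followed by 30 min of high
    light.  ``shade_ca`` sets a different chamber CO2 during the shade phase
    (the classic low-CO2 pre-opening protocol); ``preopen`` starts the leaf
    at the shade steady state instead of the dark-adapted state, emulating
    stomata held open before the transition.
    """
    env = env or Environment()
    shade_env = env if shade_ca is None else Environment(
        ca=shade_ca, vpd_kpa=env.vpd_kpa, tleaf_c=env.tleaf_c, patm_kpa=env.patm_kpa)
    high_env = Environment(ca=ca, vpd_kpa=env.vpd_kpa, tleaf_c=env.tleaf_c,
                           patm_kpa=env.patm_kpa)
    if preopen:
        # stomata held open during shade (the low-CO2 protocol): start at the
        # high-light conductance rather than the empirical shade target
        gs0, _ = steady_state_point(preset, high_ppfd, high_env)
        init = (gs0, f_act_steady(shade_ppfd, preset.f_act_dark))
    else:
        init = (preset.gst0, preset.f_act_dark)
    sim = _simulate_phases(
        preset,
        [(shade_s, shade_ppfd, shade_env), (high_s, high_ppfd, high_env)],
        init_state=init, dt=dt, sample_every_s=10.0,
    )
    return _to_trace(sim, preset, noise, noise.rng(), "induction", replicate)


def generate_relaxation(
    preset: CultivarPreset,
    noise: NoiseModel = NOISELESS,
    high_ppfd: float = 1500.0,
    low_ppfd: float = 150.0,
    phase_s: float = 2400.0,
    dt: float = 0.5,
    env: Optional[Environment] = None,
    replicate: int = 1,
) -> GasExTrace:
    """Sun-shade-sun trace (40 min per phase) starting from the sun steady state."""
    env = env or Environment()
    gs0, _ = steady_state_point(preset, high_ppfd, env)
    init = (gs0, f_act_steady(high_ppfd, preset.f_act_dark))
    sim = _simulate_phases(
        preset,
        [(phase_s, high_ppfd, env), (phase_s, low_ppfd, env),
         (phase_s, high_ppfd, env)],
        init_state=init, dt=dt, sample_every_s=10.0,
    )
    return _to_trace(sim, preset, noise, noise.rng(), "relaxation", replicate)


def generate_dynamic_aci_set(
    preset: CultivarPreset,
    noise: NoiseModel = NOISELESS,
    ca_levels: Sequence[float] = (75.0, 150.0, 270.0, 400.0, 600.0),
    **kwargs,
) -> Dict[float, GasExTrace]:
    """One induction trace per chamber CO2 level, time-aligned at the transition.

    Traces are returned rebased so time zero is the shade-to-sun step, as
    expected by :func:`cassleaf.dynamics.dynamic_aci`.
    """
    shade_s = kwargs.pop("shade_s", 300.0)
    out: Dict[float, GasExTrace] = {}
    for i, ca in enumerate(ca_levels):
        sub_noise = noise if noise.seed is None else NoiseModel(
            noise.sigma_a, noise.sigma_gs, noise.sigma_phi, seed=noise.seed + i)
        trace = generate_induction(preset, sub_noise, ca=ca, shade_ca=ca,
                                   shade_s=shade_s, **kwargs)
        df = trace.data[trace.data["time_s"] >= shade_s].copy()
        df["time_s"] -= shade_s
        out[ca] = GasExTrace(data=df.reset_index(drop=True), cultivar=trace.cultivar,
                             replicate=trace.replicate, protocol="dynamic-aci")
    return out


def generate_light_curve(
    preset: CultivarPreset,
    noise: NoiseModel = NOISELESS,
    levels: Sequence[float] = (50, 100, 200, 400, 600, 900, 1200, 1500, 2000),
    env: Optional[Environment] = None,
    replicate: int = 1,
) -> GasExTrace:
    """Steady-state light-response curve (one row per PPFD level)."""
    env = env or Environment()
    rng = noise.rng()
    rows = []
    for i, q in enumerate(sorted(levels)):
        gs_ss, a_ss = steady_state_point(preset, float(q), env)
        a_obs = a_ss + rng.normal(0.0, noise.sigma_a)
        gs_obs = max(gs_ss + rng.normal(0.0, noise.sigma_gs), 1e-4)
        rows.append({
            "time_s": 300.0 * i, "ppfd": float(q), "ca_umol_mol": env.ca,
            "a_umol_m2_s": a_obs, "gsw_mol_m2_s": gs_obs,
            "ci_umol_mol": env.ca - a_obs * k.GSW_TO_GSC / gs_obs,
            "tleaf_c": env.tleaf_c, "vpd_kpa": env.vpd_kpa,
        })
    return GasExTrace(data=pd.DataFrame(rows), cultivar=preset.name,
                      replicate=replicate, protocol="light-curve")
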