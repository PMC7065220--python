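"""Shipped per-cultivar trait tables (mean +- SE, 13 cassava cultivars).

Three fixture tables are bundled as package data:

* ``steady_state_traits`` — light-saturated assimilation, carboxylation and
  electron-transport capacities (Ci and Cc basis), triose-phosphate
  utilisation, stomatal conductance, intrinsic water-use efficiency and
  operating Ci.
* ``rubisco_biochem`` — Rubisco content, activities, activation state and
  activase fractions measured in vitro.
* ``induction_traits`` — shade-to-sun induction metrics (T50A, T90A,
  cumulative fixation over 5 min, conductance at the transition, T50gs).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_steady_state_traits",
    "load_rubisco_biochem",
    "load_induction_traits",
    "CULTIVARS",
]


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("cassleaf.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_steady_state_traits() -> pd.DataFrame:
    return _load("steady_state_traits.csv")


def load_rubisco_biochem() -> pd.DataFrame:
    return _load("rubisco_biochem.csv")


def load_induction_traits() -> pd.DataFrame:
    return _load("induction_traits.csv")


CULTIVARS = tuple(load_steady_state_traits()["cultivar"])
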