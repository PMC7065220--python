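"""Readers/writers for tabular gas-exchange data and summary tables.

The native on-disk format is plain CSV preceded by a ``#``-prefixed
``key: value`` metadata block, e.g.::

    # cultivar: TME693
    # replicate: 1
    # protocol: induction
    time_s,ppfd,ca_umol_mol,a_umol_m2_s,gsw_mol_m2_s,ci_umol_mol,tleaf_c,vpd_kpa,phipsii
    0,50,400,1.2,0.05,350,28,1.5,0.71

A second dialect maps the column names used by a common portable IRGA's
tabular export onto the native schema.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = ["GasExTrace", "read_trace", "write_trace", "summarize", "TraceValidationError"]

REQUIRED_COLUMNS = (
    "time_s",
    "ppfd",
    "ca_umol_mol",
    "a_umol_m2_s",
    "gsw_mol_m2_s",
    "ci_umol_mol",
    "tleaf_c",
    "vpd_kpa",
)
OPTIONAL_COLUMNS = ("phipsii",)

# vendor tabular export -> native schema
LI6400_COLUMN_MAP: Dict[str, str] = {
    "Time": "time_s",
    "PARi": "ppfd",
    "CO2R": "ca_umol_mol",
    "Photo": "a_umol_m2_s",
    "Cond": "gsw_mol_m2_s",
    "Ci": "ci_umol_mol",
    "Tleaf": "tleaf_c",
    "VpdL": "vpd_kpa",
    "PhiPS2": "phipsii",
}


class TraceValidationError(ValueError):
    """A trace failed schema or monotonicity validation."""


@dataclass
class GasExTrace:
    """One time-stamped gas-exchange record set from a single leaf."""

    data: pd.DataFrame
    cultivar: str = ""
    replicate: int = 0
    protocol: str = ""
    meta: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise TraceValidationError(f"missing required column(s): {', '.join(missing)}")
        t = self.data["time_s"].to_numpy(dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise TraceValidationError("time_s must be strictly increasing")
        self.data = self.data.reset_index(drop=True)
        numeric = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS
                   if c in self.data.columns]
        self.data[numeric] = self.data[numeric].astype(float)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_fluorescence(self) -> bool:
        return "phipsii" in self.data.columns and self.data["phipsii"].notna().any()

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def segment(self, t_start: float, t_end: float = math.inf) -> "GasExTrace":
        """Sub-trace with ``t_start <= time_s < t_end``."""
        mask = (self.data["time_s"] >= t_start) & (self.data["time_s"] < t_end)
        return GasExTrace(
            data=self.data.loc[mask].reset_index(drop=True),
            cultivar=self.cultivar,
            replicate=self.replicate,
            protocol=self.protocol,
            meta=dict(self.meta),
        )


def read_trace(path: str | Path, dialect: str = "native") -> GasExTrace:
    """Load a gas-exchange trace from ``path``.

    ``dialect`` selects column naming: ``"native"`` or ``"li6400-tabular"``.
    """
    path = Path(path)
    if dialect not in ("native", "li6400-tabular"):
        raise ValueError(f"unknown dialect {dialect!r}")
    meta: Dict[str, str] = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if ":" in stripped:
                    key, _, val = stripped.partition(":")
                    meta[key.strip()] = val.strip()
            else:
                body_lines.append(line)
    df = pd.read_csv(io.StringIO("".join(body_lines)))
    if dialect == "li6400-tabular":
        df = df.rename(columns=LI6400_COLUMN_MAP)
    return GasExTrace(
        data=df,
        cultivar=meta.get("cultivar", ""),
        replicate=int(meta.get("replicate", 0) or 0),
        protocol=meta.get("protocol", ""),
        meta=meta,
    )


def write_trace(trace: GasExTrace, path: str | Path, float_format: str = "%.6g") -> None:
    """Write a trace in the native CSV-with-metadata-header format."""
    path = Path(path)
    meta = dict(trace.meta)
    meta.setdefault("cultivar", trace.cultivar)
    meta.setdefault("replicate", str(trace.replicate))
    meta.setdefault("protocol", trace.protocol)
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        trace.data.to_csv(fh, index=False, float_format=float_format)


def summarize(
    results: pd.DataFrame,
    group_col: str = "cultivar",
    metrics: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Per-group mean and standard error of per-replicate metric columns.

    Single-replicate groups get a blank (NaN) SE rather than zero.
    Returns a frame with ``<metric>_mean`` / ``<metric>_se`` columns.
    """
    if results.empty:
        return pd.DataFrame()
    if metrics is None:
        metrics = [c for c in results.columns
                   if c != group_col and pd.api.types.is_numeric_dtype(results[c])]
    rows = []
    for name, grp in results.groupby(group_col, sort=True):
        row: Dict[str, object] = {group_col: name}
        for m in metrics:
            vals = grp[m].dropna().to_numpy(dtype=float)
            row[f"{m}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{m}_se"] = (vals.std(ddof=1) / math.sqrt(len(vals))
                              if len(vals) > 1 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
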