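"""Mixed-type panel containers and I/O.

A *mixed panel* holds observations of ``p`` variables of heterogeneous
nature (quantitative, binary, multi-state categorical) on ``n`` entities
at each of ``N`` ordered time points.  The canonical on-disk form is a
long CSV with columns ``entity,time,variable,value`` plus a metadata file
(YAML or JSON) declaring every variable's type and source group.

Orderings are deterministic: variables follow metadata order, entities
follow first appearance in the data file, times are sorted
lexicographically (time labels are opaque strings; no date parsing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "MixedPanel",
    "PanelError",
    "MetadataError",
    "DuplicateCellError",
    "MissingCellError",
    "ValueTypeError",
    "ShapeError",
    "read_metadata",
    "read_panel",
    "write_panel",
    "write_matrix",
    "read_matrix",
]

VTYPES = ("quantitative", "binary", "categorical")


class PanelError(ValueError):
    """Base class for panel validation failures."""


class MetadataError(PanelError):
    """Variable metadata missing, duplicated, or inconsistent with data."""


class DuplicateCellError(PanelError):
    """The same (entity, time, variable) triple appears more than once."""


class MissingCellError(PanelError):
    """A required (entity, time, variable) cell is absent."""


class ValueTypeError(PanelError):
    """A value does not conform to its declared variable type."""


class ShapeError(PanelError):
    """A matrix is not square or labels are inconsistent."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one panel variable.

    Parameters
    ----------
    name : str
        Column identifier used in the data file.
    vtype : {"quantitative", "binary", "categorical"}
        Determines which component distance consumes the variable.
    source : str
        Source-group label (e.g. ``"health"``); groups of variables are
        combined as separate components of the joint metric.
    """

    name: str
    vtype: str
    source: str

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise MetadataError(
                f"variable {self.name!r}: vtype must be one of {VTYPES}, got {self.vtype!r}"
            )


class MixedPanel:
    """In-memory mixed-type panel: ``n`` entities x ``N`` times x ``p`` variables.

    Values are stored as one wide ``n x p`` DataFrame per time point
    (index = entity labels, columns = variable names).  Quantitative
    columns are float, binary columns are int in {0, 1}, categorical
    columns are strings.
    """

    def __init__(
        self,
        entities: Iterable[str],
        times: Iterable[str],
        variables: Iterable[VariableSpec],
        frames: Mapping[str, pd.DataFrame],
    ):
        self.entities = list(entities)
        self.times = list(times)
        self.variables = list(variables)
        self._frames = {t: frames[t] for t in self.times}
        self._validate()

    # -- basic shape ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.entities)

    @property
    def N(self) -> int:
        return len(self.times)

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def sources(self) -> list[str]:
        """Source labels in order of first appearance in the metadata."""
        seen: list[str] = []
        for v in self.variables:
            if v.source not in seen:
                seen.append(v.source)
        return seen

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def _validate(self) -> None:
        if self.n < 2:
            raise PanelError(f"need n >= 2 entities, got {self.n}")
        if self.N < 1:
            raise PanelError("need at least one time point")
        if len(set(self.times)) != self.N:
            raise PanelError("duplicate time labels")
        if sorted(self.times) != self.times:
            raise PanelError("times must be in sorted order")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise MetadataError("duplicate variable names in metadata")
        for t, frame in self._frames.items():
            if list(frame.index) != self.entities or list(frame.columns) != names:
                raise PanelError(f"frame at time {t!r} misaligned with panel labels")
        for v in self.variables:
            for t in self.times:
                col = self._frames[t][v.name]
                if col.isna().any():
                    ent = col.index[col.isna()][0]
                    raise MissingCellError(
                        f"missing value for entity {ent!r}, time {t!r}, variable {v.name!r}"
                    )
                if v.vtype == "binary" and not col.isin([0, 1]).all():
                    bad = col[~col.isin([0, 1])].iloc[0]
                    raise ValueTypeError(
                        f"binary variable {v.name!r} at time {t!r} has value {bad!r} not in {{0,1}}"
                    )

    # -- slicing -------------------------------------------------------
    def slice_time(self, t: str) -> pd.DataFrame:
        """Return the ``n x p`` snapshot at time ``t`` (copy)."""
        if t not in self._frames:
            raise KeyError(f"time {t!r} not in panel")
        return self._frames[t].copy()

    def values_by_type(self, t: str, names: list[str]) -> np.ndarray:
        """Numeric/object array of the named columns at time ``t``."""
        frame = self.slice_time(t)
        return frame[names].to_numpy()

    def to_long(self) -> pd.DataFrame:
        """Long-format DataFrame with columns entity, time, variable, value."""
        rows = []
        for t in self.times:
            f = self._frames[t]
            for v in self.variables:
                rows.append(
                    pd.DataFrame(
                        {
                            "entity": self.entities,
                            "time": t,
                            "variable": v.name,
                            "value": f[v.name].to_numpy(),
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    # -- constructors --------------------------------------------------
    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        variables: list[VariableSpec],
        missing: str = "error",
    ) -> "MixedPanel":
        """Build a panel from a long table (entity, time, variable, value).

        ``missing`` is the missing-cell policy: ``"error"`` (default) or
        ``"impute"`` (per-variable, per-time median for quantitative,
        mode for binary/categorical; mode ties broken by smallest value).
        """
        required = {"entity", "time", "variable", "value"}
        if not required.issubset(df.columns):
            raise PanelError(f"long table must have columns {sorted(required)}")
        if missing not in ("error", "impute"):
            raise PanelError(f"unknown missing policy {missing!r}")

        declared = {v.name: v for v in variables}
        present = df["variable"].unique()
        undeclared = [v for v in present if v not in declared]
        if undeclared:
            raise MetadataError(f"variables in data but not in metadata: {undeclared}")

        dup = df.duplicated(subset=["entity", "time", "variable"])
        if dup.any():
            r = df[dup].iloc[0]
            raise DuplicateCellError(
                f"duplicate cell entity={r['entity']!r} time={r['time']!r} "
                f"variable={r['variable']!r}"
            )

        entities = list(pd.unique(df["entity"].astype(str)))
        times = sorted(pd.unique(df["time"].astype(str)))

        frames: dict[str, pd.DataFrame] = {}
        df = df.assign(
            entity=df["entity"].astype(str),
            time=df["time"].astype(str),
            variable=df["variable"].astype(str),
        )
        for t, sub in df.groupby("time", sort=True):
            wide = sub.pivot(index="entity", columns="variable", values="value")
            wide = wide.reindex(index=entities, columns=[v.name for v in variables])
            frames[t] = _coerce_types(wide, variables, t, missing)
        return cls(entities, times, variables, frames)


def _coerce_types(
    wide: pd.DataFrame, variables: list[VariableSpec], t: str, missing: str
) -> pd.DataFrame:
    out = {}
    for v in variables:
        col = wide[v.name]
        if col.isna().any():
            if missing == "error":
                ent = col.index[col.isna()][0]
                raise MissingCellError(
                    f"missing value for entity {ent!r}, time {t!r}, variable {v.name!r}"
                )
            col = _impute(col, v)
        if v.vtype == "quantitative":
            try:
                col = col.astype(float)
            except (TypeError, ValueError) as exc:
                raise ValueTypeError(
                    f"quantitative variable {v.name!r} at time {t!r}: {exc}"
                ) from exc
        elif v.vtype == "binary":
            try:
                numeric = col.astype(float)
            except (TypeError, ValueError) as exc:
                raise ValueTypeError(
                    f"binary variable {v.name!r} at time {t!r}: non-numeric value"
                ) from exc
            if not numeric.isin([0.0, 1.0]).all():
                bad = numeric[~numeric.isin([0.0, 1.0])].iloc[0]
                raise ValueTypeError(
                    f"binary variable {v.name!r} at time {t!r} has value {bad!r} not in {{0,1}}"
                )
            col = numeric.astype(int)
        else:
            col = col.astype(str)
        out[v.name] = col
    return pd.DataFrame(out, index=wide.index)


def _impute(col: pd.Series, v: VariableSpec) -> pd.Series:
    observed = col.dropna()
    if observed.empty:
        raise MissingCellError(f"variable {v.name!r} entirely missing at one time")
    if v.vtype == "quantitative":
        fill = observed.astype(float).median()
    else:
        counts = observed.value_counts()
        top = counts[counts == counts.max()].index
        fill = sorted(map(str, top))[0] if v.vtype == "categorical" else min(
            float(x) for x in top
        )
    return col.fillna(fill)


# ---------------------------------------------------------------------
# metadata and panel files
# ---------------------------------------------------------------------

def read_metadata(path: str | Path) -> list[VariableSpec]:
    """Read variable metadata from YAML or JSON.

    Accepted layouts: a list of ``{name, vtype, source}`` mappings, or a
    mapping ``{"variables": [...]}`` with the same entries.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if isinstance(data, Mapping) and "variables" in data:
        data = data["variables"]
    if not isinstance(data, list):
        raise MetadataError("metadata must be a list of {name, vtype, source} entries")
    specs = []
    for entry in data:
        try:
            specs.append(
                VariableSpec(str(entry["name"]), str(entry["vtype"]), str(entry["source"]))
            )
        except KeyError as exc:
            raise MetadataError(f"metadata entry {entry!r} missing key {exc}") from exc
    return specs


def read_panel(
    data_path: str | Path, meta_path: str | Path, missing: str = "error"
) -> MixedPanel:
    """Read and validate a long-format panel CSV plus its metadata file."""
    variables = read_metadata(meta_path)
    df = pd.read_csv(
        data_path,
        dtype={"entity": str, "time": str, "variable": str},
        keep_default_na=False,
        na_values=[""],
        float_precision="round_trip",
    )
    missing_cols = {"entity", "time", "variable", "value"} - set(df.columns)
    if missing_cols:
        raise PanelError(f"data file missing columns {sorted(missing_cols)}")
    return MixedPanel.from_long(df, variables, missing=missing)


def write_panel(
    panel: MixedPanel, data_path: str | Path, meta_path: str | Path
) -> None:
    """Write a panel to the canonical long CSV + YAML metadata pair."""
    long = panel.to_long()
    # quantitative values serialized at full precision for lossless round-trip
    def _fmt(row_value: object) -> object:
        if isinstance(row_value, (float, np.floating)):
            return np.format_float_positional(float(row_value), trim="0", unique=True)
        return row_value

    long["value"] = long["value"].map(_fmt)
    long.to_csv(data_path, index=False)
    meta = [
        {"name": v.name, "vtype": v.vtype, "source": v.source} for v in panel.variables
    ]
    Path(meta_path).write_text(
        yaml.safe_dump({"variables": meta}, sort_keys=False, default_flow_style=False)
    )


# ---------------------------------------------------------------------
# labeled square matrices
# ---------------------------------------------------------------------

def write_matrix(values: np.ndarray, labels: list[str], path: str | Path) -> None:
    """Write a labeled square matrix as CSV (labels in first row/column)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ShapeError(f"matrix must be square, got shape {values.shape}")
    if len(labels) != values.shape[0]:
        raise ShapeError(
            f"{len(labels)} labels for a {values.shape[0]}x{values.shape[1]} matrix"
        )
    df = pd.DataFrame(values, index=list(labels), columns=list(labels))
    df.to_csv(path, float_format="%.12g", index_label="")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a labeled square matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ShapeError(f"file {path} does not hold a square matrix")
    return df.to_numpy(dtype=float), [str(x) for x in df.index]
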