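"""Two-arm randomised-trial data: marker schemas, loading, validation.

The data contract every downstream stage assumes: a binary treatment
assignment (1 = experimental arm, 0 = comparator), a binary outcome
(1 = adverse event), and one or more binary/categorical baseline markers
whose levels are declared up front in a :class:`MarkerSpec`.  Categorical
markers use reference-cell dummy coding; a K-level marker contributes
K - 1 dummy columns named ``name[level]``, a binary marker contributes a
single column named after the marker.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DataValueError,
    DegenerateDesignError,
    SchemaError,
)

__all__ = [
    "MarkerSpec",
    "TrialDataset",
    "ValidationReport",
    "read_trial_table",
    "validate_dataset",
    "marker_specs_from_json",
    "marker_specs_to_json",
    "design_matrix",
    "profile_to_markers",
]


def _level_str(value) -> str:
    """Canonical string form of a marker level or cell value.

    Integral floats collapse to their integer form so that ``0``, ``0.0``
    and ``"0"`` all denote the same level after a CSV round trip.
    """
    if isinstance(value, float):
        if math.isnan(value):
            raise ValueError("missing value has no level representation")
        if value.is_integer():
            return str(int(value))
    if isinstance(value, (bool, np.bool_)):
        return str(int(value))
    return str(value).strip()


@dataclass(frozen=True)
class MarkerSpec:
    """Declared coding of one baseline marker.

    Parameters
    ----------
    name : str
        Column name of the marker; unique within a dataset.
    kind : {"binary", "categorical"}
    levels : sequence
        Ordered level labels. Binary markers have exactly two, categorical
        markers at least two.
    reference_level : str, optional
        Level treated as baseline (absorbed into the intercept). Defaults
        to the first declared level.
    """

    name: str
    kind: str
    levels: tuple[str, ...]
    reference_level: str = None  # type: ignore[assignment]

    def __post_init__(self):
        levels = tuple(_level_str(v) for v in self.levels)
        object.__setattr__(self, "levels", levels)
        if self.kind not in ("binary", "categorical"):
            raise SchemaError(f"marker {self.name!r}: kind must be 'binary' or "
                              f"'categorical', got {self.kind!r}")
        if self.kind == "binary" and len(levels) != 2:
            raise SchemaError(f"binary marker {self.name!r} must have exactly 2 "
                              f"levels, got {len(levels)}")
        if len(levels) < 2:
            raise SchemaError(f"marker {self.name!r} needs at least 2 levels")
        if len(set(levels)) != len(levels):
            raise SchemaError(f"marker {self.name!r} has duplicate levels")
        ref = self.reference_level
        ref = levels[0] if ref is None else _level_str(ref)
        if ref not in levels:
            raise SchemaError(f"marker {self.name!r}: reference level {ref!r} "
                              f"not among declared levels {levels}")
        object.__setattr__(self, "reference_level", ref)

    @property
    def non_reference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference_level)

    @property
    def dummy_names(self) -> tuple[str, ...]:
        """Design-column names for this marker's dummy variables."""
        if self.kind == "binary":
            return (self.name,)
        return tuple(f"{self.name}[{l}]" for l in self.non_reference_levels)

    def dummy_level(self, dummy_name: str) -> str:
        """Level label encoded by a given dummy column."""
        if self.kind == "binary":
            if dummy_name != self.name:
                raise KeyError(dummy_name)
            return self.non_reference_levels[0]
        prefix = f"{self.name}["
        if not (dummy_name.startswith(prefix) and dummy_name.endswith("]")):
            raise KeyError(dummy_name)
        return dummy_name[len(prefix):-1]

    def to_dict(self) -> dict:
        return {"name": self.name, "kind": self.kind,
                "levels": list(self.levels),
                "reference_level": self.reference_level}

    @classmethod
    def from_dict(cls, d: Mapping) -> "MarkerSpec":
        return cls(name=d["name"], kind=d["kind"],
                   levels=tuple(d["levels"]),
                   reference_level=d.get("reference_level"))


def _check_unique_names(specs: Sequence[MarkerSpec]) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise SchemaError(f"duplicate marker names: {sorted(names)}")


def marker_specs_from_json(source) -> tuple[MarkerSpec, ...]:
    """Read a marker schema from a JSON file path, file object, or list."""
    if isinstance(source, (list, tuple)):
        raw = source
    else:
        if hasattr(source, "read"):
            raw = json.load(source)
        else:
            with open(source) as fh:
                raw = json.load(fh)
        if isinstance(raw, dict) and "markers" in raw:
            raw = raw["markers"]
    specs = tuple(MarkerSpec.from_dict(d) for d in raw)
    _check_unique_names(specs)
    return specs


def marker_specs_to_json(specs: Sequence[MarkerSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump({"markers": [s.to_dict() for s in specs]}, fh, indent=2)
        fh.write("\n")


@dataclass
class TrialDataset:
    """Per-patient extract of a two-arm randomised trial.

    treatment and outcome are 0/1 integer arrays; markers is a string-valued
    DataFrame with one column per declared marker (NaN marks a missing
    value, removed by :func:`validate_dataset`).
    """

    treatment: np.ndarray
    outcome: np.ndarray
    markers: pd.DataFrame
    marker_specs: tuple[MarkerSpec, ...]

    def __post_init__(self):
        self.marker_specs = tuple(self.marker_specs)
        _check_unique_names(self.marker_specs)
        self.treatment = np.asarray(self.treatment, dtype=np.int64)
        self.outcome = np.asarray(self.outcome, dtype=np.int64)
        for label, arr in (("treatment", self.treatment),
                           ("outcome", self.outcome)):
            bad = ~np.isin(arr, (0, 1))
            if bad.any():
                row = int(np.flatnonzero(bad)[0]) + 1
                raise DataValueError(
                    f"{label} must be 0/1; first offending data row {row}")
        n = len(self.treatment)
        if len(self.outcome) != n or len(self.markers) != n:
            raise SchemaError("treatment, outcome and markers must have "
                              "equal length")
        spec_names = [s.name for s in self.marker_specs]
        missing = [m for m in spec_names if m not in self.markers.columns]
        if missing:
            raise SchemaError(f"marker columns missing from data: {missing}")
        self.markers = self.markers[spec_names].reset_index(drop=True)
        for spec in self.marker_specs:
            col = self.markers[spec.name]
            values = col[col.notna()]
            bad = ~values.astype(str).isin(spec.levels)
            if bad.any():
                row = int(values.index[bad][0]) + 1
                raise DataValueError(
                    f"undeclared level {values[bad].iloc[0]!r} in column "
                    f"{spec.name!r}, data row {row}; declared levels: "
                    f"{spec.levels}")

    @property
    def n(self) -> int:
        return len(self.treatment)

    @property
    def arm_sizes(self) -> tuple[int, int]:
        """(n_control, n_treated)."""
        t = int(self.treatment.sum())
        return self.n - t, t

    def event_rate(self, arm: int | None = None) -> float:
        mask = np.ones(self.n, bool) if arm is None else self.treatment == arm
        return float(self.outcome[mask].mean())

    def subset(self, index) -> "TrialDataset":
        """Row subset by boolean mask or integer index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return TrialDataset(self.treatment[index], self.outcome[index],
                            self.markers.iloc[index].reset_index(drop=True),
                            self.marker_specs)

    def to_frame(self, treatment_col: str = "treatment",
                 outcome_col: str = "outcome") -> pd.DataFrame:
        df = pd.DataFrame({treatment_col: self.treatment,
                           outcome_col: self.outcome})
        return pd.concat([df, self.markers.reset_index(drop=True)], axis=1)

    def write_csv(self, path, treatment_col: str = "treatment",
                  outcome_col: str = "outcome") -> None:
        self.to_frame(treatment_col, outcome_col).to_csv(path, index=False)

    def equals(self, other: "TrialDataset") -> bool:
        return (np.array_equal(self.treatment, other.treatment)
                and np.array_equal(self.outcome, other.outcome)
                and self.marker_specs == other.marker_specs
                and self.markers.equals(other.markers))


@dataclass
class ValidationReport:
    """Summary of the checks applied by :func:`validate_dataset`."""

    n_dropped_incomplete: int
    arm_sizes: tuple[int, int]
    control_event_rate: float
    treated_event_rate: float
    events_per_parameter: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"n_dropped_incomplete": self.n_dropped_incomplete,
                "arm_sizes": list(self.arm_sizes),
                "control_event_rate": self.control_event_rate,
                "treated_event_rate": self.treated_event_rate,
                "events_per_parameter": self.events_per_parameter,
                "warnings": list(self.warnings)}


def read_trial_table(path, treatment_col: str, outcome_col: str,
                     marker_specs: Sequence[MarkerSpec]) -> TrialDataset:
    """Read a trial extract from a headed CSV file.

    Raises :class:`SchemaError` if a named column is absent and
    :class:`DataValueError` if a marker cell holds an undeclared level
    (1-based data rows, header excluded, in all messages).
    """
    marker_specs = tuple(marker_specs)
    _check_unique_names(marker_specs)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    needed = [treatment_col, outcome_col] + [s.name for s in marker_specs]
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"column {col!r} not found in {path}; "
                              f"available: {list(df.columns)}")

    def to_binary(col: str) -> np.ndarray:
        vals = df[col]
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0]) + 1
            raise DataValueError(f"missing value in column {col!r}, "
                                 f"data row {row}")
        cleaned = vals.map(_level_str)
        bad = ~cleaned.isin(("0", "1"))
        if bad.any():
            row = int(cleaned.index[bad][0]) + 1
            raise DataValueError(
                f"column {col!r} must be 0/1; got {vals[bad].iloc[0]!r} "
                f"at data row {row}")
        return cleaned.astype(np.int64).to_numpy()

    markers = pd.DataFrame(index=df.index)
    for spec in marker_specs:
        col = df[spec.name].map(lambda v: np.nan if pd.isna(v)
                                else _level_str(v))
        markers[spec.name] = col
    return TrialDataset(to_binary(treatment_col), to_binary(outcome_col),
                        markers, marker_specs)


def validate_dataset(ds: TrialDataset, n_model_params: int
                     ) -> tuple[TrialDataset, ValidationReport]:
    """Apply the complete-case policy and the events-per-variable check.

    Rows with any missing marker are dropped (with a logged count);
    ``n_model_params`` counts the non-intercept parameters of the intended
    model. Warnings are emitted at fewer than 10 events per parameter,
    a stronger one below 5, and when either arm has zero events.

    Raises :class:`DegenerateDesignError` if an arm is empty after
    filtering.
    """
    if n_model_params < 1:
        raise ValueError("n_model_params must be at least 1")
    complete = ~ds.markers.isna().any(axis=1).to_numpy()
    clean = ds.subset(complete)
    n_dropped = ds.n - clean.n
    n_control, n_treated = (clean.arm_sizes if clean.n else (0, 0))
    if n_control == 0 or n_treated == 0:
        raise DegenerateDesignError(
            f"degenerate design: arm sizes (control={n_control}, "
            f"treated={n_treated}) after complete-case filtering")
    events = int(clean.outcome.sum())
    epv = events / n_model_params
    warnings: list[str] = []
    if n_dropped:
        warnings.append(f"dropped {n_dropped} incomplete rows "
                        f"(complete-case policy)")
    if epv < 5:
        warnings.append(
            f"severe: only {epv:.2f} events per parameter "
            f"({events} events / {n_model_params} parameters); at least 5, "
            f"preferably 10, are recommended")
    elif epv < 10:
        warnings.append(
            f"{epv:.2f} events per parameter ({events} events / "
            f"{n_model_params} parameters); 10 or more are recommended")
    for arm, label in ((0, "control"), (1, "treated")):
        if clean.outcome[clean.treatment == arm].sum() == 0:
            warnings.append(f"no events in the {label} arm")
    report = ValidationReport(
        n_dropped_incomplete=n_dropped,
        arm_sizes=(n_control, n_treated),
        control_event_rate=clean.event_rate(arm=0),
        treated_event_rate=clean.event_rate(arm=1),
        events_per_parameter=epv,
        warnings=warnings)
    return clean, report


# ---------------------------------------------------------------------------
# Design-matrix construction (reference-cell dummy coding)
# ---------------------------------------------------------------------------

def coefficient_names(specs: Sequence[MarkerSpec]) -> list[str]:
    """Ordered coefficient names of the full interaction model."""
    dummies = [d for s in specs for d in s.dummy_names]
    return (["intercept", "treatment"] + dummies
            + [f"treatment:{d}" for d in dummies])


def design_matrix(markers: pd.DataFrame, treatment,
                  specs: Sequence[MarkerSpec]) -> pd.DataFrame:
    """Build the full marker-by-treatment interaction design.

    Columns: intercept, treatment, one dummy per non-reference marker
    level, then one treatment interaction per dummy, in declaration order.
    """
    n = len(markers)
    t = np.asarray(treatment, dtype=float)
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(n), "treatment": t}
    for spec in specs:
        values = markers[spec.name].astype(str)
        for dummy in spec.dummy_names:
            cols[dummy] = (values == spec.dummy_level(dummy)
                           ).to_numpy(dtype=float)
    for spec in specs:
        for dummy in spec.dummy_names:
            cols[f"treatment:{dummy}"] = cols[dummy] * t
    return pd.DataFrame(cols)


def profile_to_markers(profile: Mapping[str, object],
                       specs: Sequence[MarkerSpec]) -> pd.DataFrame:
    """One-row marker frame from a {marker: level} mapping.

    Every declared marker must be assigned a declared level.
    """
    row = {}
    known = {s.name for s in specs}
    unknown = set(profile) - known
    if unknown:
        raise DataValueError(f"unknown marker(s) in profile: "
                             f"{sorted(unknown)}")
    for spec in specs:
        if spec.name not in profile:
            raise DataValueError(f"profile missing marker {spec.name!r}")
        level = _level_str(profile[spec.name])
        if level not in spec.levels:
            raise DataValueError(
                f"unknown level {level!r} for marker {spec.name!r}; "
                f"declared levels: {spec.levels}")
        row[spec.name] = level
    return pd.DataFrame([row])
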