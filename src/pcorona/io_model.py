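"""Core tabular data types and delimited-text I/O.

A corona dataset is a flat table: one row per nanoparticle-incubation
experiment, a mix of categorical and numerical physicochemical /
protocol factors, and one non-negative relative protein abundance (RPA)
column per target protein.  Which column plays which role is declared
in a :class:`ColumnRoleConfig` rather than hard-coded, because the
source tables in this field do not share a fixed schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    CompletenessError,
    DimensionError,
    ParseError,
    SchemaError,
)

#: strings treated as a missing cell when reading a table
_MISSING_TOKENS = {"", "NA", "N/A", "NAN", "NaN", "nan", "na", "NULL", "null", "None"}


@dataclass(frozen=True)
class ColumnRoleConfig:
    """Declares the role of every column of an input table.

    The three lists must be disjoint and together cover every column of
    the table they describe.
    """

    categorical: tuple[str, ...]
    numerical: tuple[str, ...]
    targets: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "categorical", tuple(self.categorical))
        object.__setattr__(self, "numerical", tuple(self.numerical))
        object.__setattr__(self, "targets", tuple(self.targets))
        groups = [set(self.categorical), set(self.numerical), set(self.targets)]
        total = sum(len(g) for g in groups)
        union = set().union(*groups)
        if total != len(union):
            overlap = sorted(
                c
                for c in union
                if sum(c in g for g in groups) > 1
            )
            raise SchemaError(f"column roles overlap: {overlap}")

    @property
    def factors(self) -> tuple[str, ...]:
        return self.categorical + self.numerical


def load_roles(path: str | Path) -> ColumnRoleConfig:
    """Load a :class:`ColumnRoleConfig` from a YAML or JSON file.

    The file must carry the keys ``categorical``, ``numerical`` and
    ``targets``, each a list of column names.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, Mapping):
        raise SchemaError(f"role config {path} is not a mapping")
    missing = {"categorical", "numerical", "targets"} - set(data)
    if missing:
        raise SchemaError(f"role config missing keys: {sorted(missing)}")
    return ColumnRoleConfig(
        categorical=tuple(data["categorical"]),
        numerical=tuple(data["numerical"]),
        targets=tuple(data["targets"]),
    )


@dataclass
class CoronaDataset:
    """A validated factor table plus per-protein RPA targets.

    Parameters
    ----------
    factors
        Row-indexed table of the experimental factors; categorical
        columns hold strings, numerical columns floats.
    rpa
        Row-indexed table of relative protein abundances, one column
        per protein; finite and non-negative.
    factor_kinds
        Map from factor name to ``"categorical"`` or ``"numerical"``.

    Rows carry a stable integer index assigned at construction so that
    resampled replicas can cite their origin row.
    """

    factors: pd.DataFrame
    rpa: pd.DataFrame
    factor_kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.factors = self.factors.reset_index(drop=True)
        self.rpa = self.rpa.reset_index(drop=True)
        if not self.factor_kinds:
            self.factor_kinds = {
                c: ("numerical" if pd.api.types.is_numeric_dtype(self.factors[c]) else "categorical")
                for c in self.factors.columns
            }
        self.validate()

    # -- basic views ---------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.factors)

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors.columns)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.rpa.columns)

    @property
    def categorical_factors(self) -> list[str]:
        return [f for f in self.factor_names if self.factor_kinds[f] == "categorical"]

    @property
    def numerical_factors(self) -> list[str]:
        return [f for f in self.factor_names if self.factor_kinds[f] == "numerical"]

    def validate(self) -> None:
        """Check completeness and RPA sign/finiteness; report all violations."""
        problems: list[str] = []
        if len(self.factors) != len(self.rpa):
            raise DimensionError(
                f"factor table has {len(self.factors)} rows but RPA table has {len(self.rpa)}"
            )
        unknown = set(self.factors.columns) - set(self.factor_kinds)
        if unknown:
            raise SchemaError(f"factors without a declared kind: {sorted(unknown)}")
        for col in self.factors.columns:
            null = self.factors[col].isna()
            for i in np.flatnonzero(null.to_numpy()):
                problems.append(f"missing factor value at row {i}, column {col!r}")
        rpa_vals = self.rpa.to_numpy(dtype=float, na_value=np.nan)
        bad_nan = np.argwhere(np.isnan(rpa_vals))
        for i, j in bad_nan:
            problems.append(f"missing RPA value at row {i}, protein {self.rpa.columns[j]!r}")
        with np.errstate(invalid="ignore"):
            bad_val = np.argwhere(~np.isnan(rpa_vals) & (~np.isfinite(rpa_vals) | (rpa_vals < 0)))
        for i, j in bad_val:
            problems.append(
                f"non-finite or negative RPA at row {i}, protein {self.rpa.columns[j]!r}"
            )
        if problems:
            raise CompletenessError("; ".join(problems))

    def to_frame(self) -> pd.DataFrame:
        """The full table (factors then targets), suitable for writing."""
        return pd.concat([self.factors, self.rpa], axis=1)


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_corona_table(
    path: str | Path,
    roles: ColumnRoleConfig,
    delimiter: str | None = None,
) -> CoronaDataset:
    """Read a delimited text table into a validated :class:`CoronaDataset`.

    The delimiter is inferred from the extension (``.tsv``/``.tab`` →
    tab, otherwise comma) unless given explicitly.  Categorical values
    are kept as strings; numerical factors and targets are parsed to
    floats, with every unparseable or missing cell reported.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    missing_cols = [
        c
        for c in roles.categorical + roles.numerical + roles.targets
        if c not in raw.columns
    ]
    if missing_cols:
        raise SchemaError(f"columns declared in roles but absent from {path}: {missing_cols}")

    completeness: list[str] = []
    parse: list[str] = []

    def parse_numeric(col: str) -> np.ndarray:
        out = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell in _MISSING_TOKENS:
                completeness.append(f"missing value at row {i}, column {col!r}")
                out[i] = np.nan
                continue
            try:
                out[i] = float(cell)
            except ValueError:
                parse.append(f"unparseable numeric cell {cell!r} at row {i}, column {col!r}")
                out[i] = np.nan
        return out

    factors = pd.DataFrame(index=raw.index)
    for col in roles.categorical:
        vals = raw[col].str.strip()
        for i in np.flatnonzero(vals.isin(_MISSING_TOKENS).to_numpy()):
            completeness.append(f"missing value at row {i}, column {col!r}")
        factors[col] = vals
    for col in roles.numerical:
        factors[col] = parse_numeric(col)
    rpa = pd.DataFrame({col: parse_numeric(col) for col in roles.targets}, index=raw.index)

    if parse:
        raise ParseError("; ".join(parse))
    if completeness:
        raise CompletenessError("; ".join(completeness))

    kinds = {c: "categorical" for c in roles.categorical}
    kinds.update({c: "numerical" for c in roles.numerical})
    # order columns as declared: categoricals first, then numericals
    factors = factors[list(roles.categorical) + list(roles.numerical)]
    return CoronaDataset(factors=factors, rpa=rpa, factor_kinds=kinds)


def write_corona_table(
    path: str | Path,
    dataset: CoronaDataset,
    delimiter: str | None = None,
    float_format: str = "%.12g",
) -> None:
    """Write a dataset back to delimited text (inverse of read)."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    dataset.to_frame().to_csv(path, sep=sep, index=False, float_format=float_format)


def roles_of(dataset: CoronaDataset) -> ColumnRoleConfig:
    """The role configuration describing an existing dataset."""
    return ColumnRoleConfig(
        categorical=tuple(dataset.categorical_factors),
        numerical=tuple(dataset.numerical_factors),
        targets=tuple(dataset.protein_ids),
    )


def write_predictions(
    path: str | Path,
    protein_ids: Sequence[str],
    predictions: np.ndarray,
    true_values: np.ndarray | None = None,
    delimiter: str | None = None,
) -> None:
    """Write per-protein predictions (and optionally true values) to text.

    One row per input record with a leading ``record`` index column;
    when ``true_values`` is given, each protein contributes a
    ``<id>_pred`` and ``<id>_true`` column pair.
    """
    predictions = np.asarray(predictions, dtype=float)
    if predictions.ndim == 1:
        predictions = predictions[:, None]
    if predictions.shape[1] != len(protein_ids):
        raise DimensionError(
            f"predictions have {predictions.shape[1]} columns but {len(protein_ids)} protein ids given"
        )
    cols: dict[str, np.ndarray] = {"record": np.arange(predictions.shape[0])}
    if true_values is not None:
        true_values = np.asarray(true_values, dtype=float)
        if true_values.ndim == 1:
            true_values = true_values[:, None]
        if true_values.shape != predictions.shape:
            raise DimensionError(
                f"true_values shape {true_values.shape} != predictions shape {predictions.shape}"
            )
        for j, pid in enumerate(protein_ids):
            cols[f"{pid}_pred"] = predictions[:, j]
            cols[f"{pid}_true"] = true_values[:, j]
    else:
        for j, pid in enumerate(protein_ids):
            cols[f"{pid}_pred"] = predictions[:, j]
    path = Path(path)
    pd.DataFrame(cols).to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


def save_roles(path: str | Path, roles: ColumnRoleConfig) -> None:
    """Write a role configuration as JSON (readable by :func:`load_roles`)."""
    Path(path).write_text(
        json.dumps(
            {
                "categorical": list(roles.categorical),
                "numerical": list(roles.numerical),
                "targets": list(roles.targets),
            },
            indent=2,
        )
    )
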