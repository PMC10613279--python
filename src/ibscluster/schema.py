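"""Variable schemas and the mixed-type data matrix.

Questionnaire-based cohorts mix ordinal Likert items, nominal categories and
continuous psychometric scores.  A :class:`VariableSchema` declares, per
variable, which of the three kinds it is, the ordered level labels (ordinal /
nominal) or the admissible numeric range (continuous).  A
:class:`MixedDataMatrix` binds an n x p table to a list of schemas, validates
every cell against its schema, and stores ordinal/nominal values internally as
integer codes (0..L-1 in declared level order) so that downstream numerics
never touch the free-text labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

KINDS = ("ordinal", "nominal", "continuous")


class SchemaError(ValueError):
    """A value or schema declaration violates the variable schema."""


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of a single variable.

    Parameters
    ----------
    code : str
        Short unique identifier, e.g. ``"AP"`` for abdominal pain.
    name : str
        Free-text description.
    kind : {"ordinal", "nominal", "continuous"}
    levels : tuple of str, optional
        Ordered category labels (ordinal) or unordered labels (nominal).
    range : tuple of float, optional
        ``(min, max)`` bounds for continuous variables.
    """

    code: str
    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"{self.code}: unknown kind {self.kind!r}")
        if self.kind in ("ordinal", "nominal"):
            if not self.levels or len(self.levels) < 2:
                raise SchemaError(f"{self.code}: {self.kind} variables need >=2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"{self.code}: duplicate levels")
            object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
            object.__setattr__(self, "range", None)
        else:
            if self.range is None:
                raise SchemaError(f"{self.code}: continuous variables need a range")
            lo, hi = float(self.range[0]), float(self.range[1])
            if not lo < hi:
                raise SchemaError(f"{self.code}: range must satisfy min < max")
            object.__setattr__(self, "range", (lo, hi))
            object.__setattr__(self, "levels", None)

    @property
    def n_levels(self) -> int:
        if self.levels is None:
            raise SchemaError(f"{self.code}: continuous variable has no levels")
        return len(self.levels)

    def encode(self, value, row=None):
        """Map a raw cell to its internal representation (rank code or float)."""
        if self.kind == "continuous":
            try:
                x = float(value)
            except (TypeError, ValueError):
                raise SchemaError(f"{self.code}: non-numeric value {value!r} (row {row})")
            lo, hi = self.range
            if not (lo <= x <= hi):
                raise SchemaError(
                    f"{self.code}: value {x} outside declared range [{lo}, {hi}] (row {row})"
                )
            return x
        label = str(value)
        try:
            return self.levels.index(label)
        except ValueError:
            raise SchemaError(
                f"{self.code}: {label!r} is not a declared level of "
                f"{list(self.levels)} (row {row})"
            )

    def decode(self, internal):
        """Inverse of :meth:`encode`."""
        if self.kind == "continuous":
            return float(internal)
        return self.levels[int(internal)]

    def to_dict(self) -> dict:
        d: dict = {"code": self.code, "name": self.name, "kind": self.kind}
        if self.levels is not None:
            d["levels"] = list(self.levels)
        if self.range is not None:
            d["range"] = [self.range[0], self.range[1]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSchema":
        return cls(
            code=str(d["code"]),
            name=str(d.get("name", d["code"])),
            kind=str(d["kind"]),
            levels=tuple(d["levels"]) if d.get("levels") else None,
            range=tuple(d["range"]) if d.get("range") else None,
        )


def validate_schema(variables: Sequence[VariableSchema]) -> list[VariableSchema]:
    variables = list(variables)
    codes = [v.code for v in variables]
    dupes = {c for c in codes if codes.count(c) > 1}
    if dupes:
        raise SchemaError(f"duplicate variable codes: {sorted(dupes)}")
    return variables


@dataclass
class MixedDataMatrix:
    """An n x p mixed-type table bound to a variable schema.

    ``frame`` holds the internal representation: integer rank codes for
    ordinal/nominal columns (0..L-1 in declared level order) and floats for
    continuous columns.  The index carries the sample ids.
    """

    schema: list[VariableSchema]
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.schema = validate_schema(self.schema)
        codes = [v.code for v in self.schema]
        if list(self.frame.columns) != codes:
            raise SchemaError("frame columns do not match schema codes/order")
        self.validate()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_labeled(cls, df: pd.DataFrame, schema: Sequence[VariableSchema],
                     on_missing: str = "error") -> "MixedDataMatrix":
        """Build from a table of raw labels/values, validating every cell.

        ``on_missing`` is ``"error"`` (default) or ``"drop"`` (listwise
        deletion of incomplete rows, with the dropped count logged).
        """
        schema = validate_schema(schema)
        df = df[[v.code for v in schema]].copy() if set(df.columns) >= {v.code for v in schema} \
            else df.copy()
        missing_cols = [v.code for v in schema if v.code not in df.columns]
        if missing_cols:
            raise SchemaError(f"table lacks columns {missing_cols}")
        df = df[[v.code for v in schema]]
        mask = df.isna().any(axis=1)
        if mask.any():
            if on_missing == "drop":
                logger.info("listwise deletion dropped %d incomplete rows", int(mask.sum()))
                df = df.loc[~mask]
            else:
                bad = df.index[mask][0]
                raise SchemaError(
                    f"missing cell(s), first in row {bad!r}; pass on_missing='drop' "
                    "for listwise deletion"
                )
        data = {}
        for v in schema:
            col = df[v.code]
            if v.kind == "continuous":
                vals = pd.to_numeric(col, errors="coerce")
                if vals.isna().any():
                    bad = col.index[vals.isna()][0]
                    raise SchemaError(f"{v.code}: non-numeric value (row {bad!r})")
                lo, hi = v.range
                out = (vals < lo) | (vals > hi)
                if out.any():
                    bad = col.index[out][0]
                    raise SchemaError(
                        f"{v.code}: value {vals.loc[bad]} outside declared range "
                        f"[{lo}, {hi}] (row {bad!r})"
                    )
                data[v.code] = vals.astype(float)
            else:
                lut = {lvl: i for i, lvl in enumerate(v.levels)}
                codes = col.astype(str).map(lut)
                if codes.isna().any():
                    bad = col.index[codes.isna()][0]
                    raise SchemaError(
                        f"{v.code}: {col.loc[bad]!r} is not a declared level of "
                        f"{list(v.levels)} (row {bad!r})"
                    )
                data[v.code] = codes.astype(int)
        return cls(schema=list(schema), frame=pd.DataFrame(data, index=df.index))

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for v in self.schema:
            col = self.frame[v.code]
            if v.kind == "continuous":
                lo, hi = v.range
                if ((col < lo) | (col > hi)).any():
                    raise SchemaError(f"{v.code}: values outside [{lo}, {hi}]")
            else:
                if ((col < 0) | (col >= v.n_levels)).any():
                    raise SchemaError(f"{v.code}: rank codes outside 0..{v.n_levels - 1}")

    # -- views -------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def n_variables(self) -> int:
        return len(self.schema)

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def codes(self) -> list[str]:
        return [v.code for v in self.schema]

    def kinds(self) -> list[str]:
        return [v.kind for v in self.schema]

    def variable(self, code: str) -> VariableSchema:
        for v in self.schema:
            if v.code == code:
                return v
        raise KeyError(code)

    def numeric(self) -> pd.DataFrame:
        """All columns as floats (ordinal/nominal as their integer codes)."""
        return self.frame.astype(float)

    def to_labeled_frame(self) -> pd.DataFrame:
        """Human-readable table: ordinal/nominal codes mapped back to labels."""
        out = {}
        for v in self.schema:
            col = self.frame[v.code]
            if v.kind == "continuous":
                out[v.code] = col.astype(float)
            else:
                out[v.code] = col.map(dict(enumerate(v.levels)))
        return pd.DataFrame(out, index=self.frame.index)

    def subset(self, idx: Iterable[int]) -> "MixedDataMatrix":
        idx = np.asarray(list(idx))
        return MixedDataMatrix(schema=self.schema, frame=self.frame.iloc[idx].copy())

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return (
            isinstance(other, MixedDataMatrix)
            and self.schema == other.schema
            and self.frame.equals(other.frame)
        )


# -- schema file I/O -------------------------------------------------------

def read_schema(path: str | Path) -> list[VariableSchema]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict) and "variables" in raw:
        raw = raw["variables"]
    return validate_schema([VariableSchema.from_dict(d) for d in raw])


def write_schema(variables: Sequence[VariableSchema], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"variables": [v.to_dict() for v in variables]}, fh,
                       sort_keys=False)


def load_dataset(table_path: str | Path, schema_path: str | Path,
                 on_missing: str = "error") -> MixedDataMatrix:
    """Load a CSV table (first column sample id, header of variable codes)
    together with its schema document, validating every cell."""
    schema = read_schema(schema_path)
    df = pd.read_csv(table_path, index_col=0, dtype=str, keep_default_na=True)
    return MixedDataMatrix.from_labeled(df, schema, on_missing=on_missing)


def save_dataset(data: MixedDataMatrix, table_path: str | Path,
                 schema_path: str | Path | None = None) -> None:
    data.to_labeled_frame().to_csv(table_path, index_label="sample_id")
    if schema_path is not None:
        write_schema(data.schema, schema_path)
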