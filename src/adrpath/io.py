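"""Tabular input/output for the ADR–pathway association pipeline.

All tables are tab-separated UTF-8 with a single header row; lines starting
with ``#`` are comments.  Missing optional numerics are written as the
literal ``NA`` so that read→write→read round-trips are identity.

The docking table never declares its own score orientation: whether lower
or higher raw scores mean stronger predicted binding is engine-specific and
must be supplied explicitly (see :class:`DockingScoreMatrix`).
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


class SchemaError(ValueError):
    """A table does not match its declared schema."""


class ConfigError(ValueError):
    """A required configuration value is missing or out of range."""


class Direction(enum.Enum):
    """Orientation of a docking engine's raw score."""

    LOWER = "lower"   # lower raw score = stronger predicted binding (eHiTS-like)
    HIGHER = "higher"

    @classmethod
    def coerce(cls, value: "Direction | str | None") -> "Direction":
        if value is None:
            raise ConfigError(
                "better_direction must be declared (lower|higher); "
                "it is never inferred from score signs"
            )
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError as exc:
            raise ConfigError(f"invalid better_direction {value!r}") from exc


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str            # "str" | "float" | "int" | "bool"
    required: bool = True
    optional_values: bool = False  # cell-level NA allowed


@dataclass(frozen=True)
class Schema:
    name: str
    columns: tuple[ColumnSpec, ...]
    key: tuple[str, ...] = ()      # uniqueness constraint

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)


SCHEMAS: dict[str, Schema] = {
    s.name: s
    for s in (
        Schema(
            "drugs",
            (
                ColumnSpec("drug_id", "str"),
                ColumnSpec("name", "str"),
                ColumnSpec("molecular_weight", "float", optional_values=True),
                ColumnSpec("rotatable_bonds", "int", optional_values=True),
                ColumnSpec("smiles", "str", required=False, optional_values=True),
            ),
            key=("drug_id",),
        ),
        Schema(
            "adr",
            (
                ColumnSpec("drug_id", "str"),
                ColumnSpec("adr_phrase", "str"),
                ColumnSpec("frequency", "float", optional_values=True),
                ColumnSpec("placebo_frequency", "float", optional_values=True),
                ColumnSpec("post_marketing", "bool"),
            ),
            key=("drug_id", "adr_phrase"),
        ),
        Schema(
            "proteins",
            (
                ColumnSpec("protein_id", "str"),
                ColumnSpec("method", "str"),
                ColumnSpec("resolution", "float", optional_values=True),
                ColumnSpec("length", "int"),
                ColumnSpec("organism", "str"),
                ColumnSpec("has_ec", "bool"),
                ColumnSpec("pathway_annotated", "bool"),
            ),
            key=("protein_id",),
        ),
        Schema(
            "similarity",
            (
                ColumnSpec("protein_a", "str"),
                ColumnSpec("protein_b", "str"),
                ColumnSpec("identity", "float"),
                ColumnSpec("coverage", "float"),
            ),
        ),
        Schema(
            "docking",
            (
                ColumnSpec("drug_id", "str"),
                ColumnSpec("protein_id", "str"),
                ColumnSpec("pocket_id", "int"),
                ColumnSpec("raw_score", "float"),
            ),
            key=("drug_id", "protein_id", "pocket_id"),
        ),
        Schema(
            "pathway_map",
            (
                ColumnSpec("protein_id", "str"),
                ColumnSpec("pathway_id", "str"),
                ColumnSpec("pathway_name", "str", required=False, optional_values=True),
            ),
            key=("protein_id", "pathway_id"),
        ),
        Schema(
            "hits",
            (
                ColumnSpec("pathway_term", "str"),
                ColumnSpec("adr_term", "str"),
                ColumnSpec("hit_count", "int"),
            ),
            key=("pathway_term", "adr_term"),
        ),
        Schema(
            "associations",
            (
                ColumnSpec("adr_group", "str"),
                ColumnSpec("pathway_id", "str"),
                ColumnSpec("phase1_weight", "float"),
                ColumnSpec("phase2_coefficient", "float", optional_values=True),
                ColumnSpec("p_value", "float", optional_values=True),
                ColumnSpec("q_value", "float", optional_values=True),
                ColumnSpec("significant", "bool"),
            ),
            key=("adr_group", "pathway_id"),
        ),
        Schema(
            "matrix",  # generic drugs-by-columns numeric matrix, first column = drug_id
            (ColumnSpec("drug_id", "str"),),
        ),
    )
}

NA = "NA"

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _convert(raw: pd.Series, col: ColumnSpec, path: str) -> pd.Series:
    def bad(i: int, value: str) -> SchemaError:
        # +2: header line plus 1-based indexing (comment lines not counted)
        return SchemaError(
            f"{path}: column {col.name!r}, data row {i + 1}: "
            f"cannot parse {value!r} as {col.kind}"
        )

    out = []
    for i, v in enumerate(raw):
        s = "" if v is None else str(v).strip()
        if s == NA or s == "":
            if col.optional_values:
                out.append(None)
                continue
            raise bad(i, s)
        if col.kind == "str":
            out.append(s)
        elif col.kind == "bool":
            low = s.lower()
            if low in _TRUE:
                out.append(True)
            elif low in _FALSE:
                out.append(False)
            else:
                raise bad(i, s)
        else:
            try:
                out.append(float(s) if col.kind == "float" else int(s))
            except ValueError:
                raise bad(i, s) from None
    if col.kind == "float":
        return pd.Series(out, dtype="float64" if not col.optional_values else "Float64")
    if col.kind == "int":
        return pd.Series(out, dtype="int64" if not col.optional_values else "Int64")
    if col.kind == "bool":
        return pd.Series(out, dtype="bool")
    return pd.Series(out, dtype="object")


def read_table(path: str | Path, schema: str | Schema) -> pd.DataFrame:
    """Read and validate a TSV table against a named schema.

    Row order is preserved.  Raises :class:`SchemaError` naming the first
    missing column, unparseable cell (with its data-row number), or
    duplicated key.
    """
    sch = SCHEMAS[schema] if isinstance(schema, str) else schema
    path = Path(path)
    raw = pd.read_csv(
        path, sep="\t", comment="#", dtype=str,
        keep_default_na=False, na_values=[],
    )
    for col in sch.columns:
        if col.required and col.name not in raw.columns:
            raise SchemaError(f"{path}: missing required column {col.name!r}")
    cols = {}
    for col in sch.columns:
        if col.name in raw.columns:
            cols[col.name] = _convert(raw[col.name], col, str(path))
    out = pd.DataFrame(cols)
    if sch.key:
        dup = out.duplicated(subset=list(sch.key))
        if dup.any():
            first = out.loc[dup, list(sch.key)].iloc[0].tolist()
            raise SchemaError(
                f"{path}: duplicate key {tuple(first)} for {sch.key} "
                f"(schema {sch.name!r})"
            )
    if sch.name == "similarity":
        out = _symmetrize_similarity(out, str(path))
    _check_ranges(out, sch, str(path))
    return out


def _symmetrize_similarity(df: pd.DataFrame, path: str) -> pd.DataFrame:
    """(a,b) and (b,a) denote the same pair; conflicting duplicates error."""
    canon = df.copy()
    flip = canon.protein_a > canon.protein_b
    canon.loc[flip, ["protein_a", "protein_b"]] = canon.loc[
        flip, ["protein_b", "protein_a"]
    ].to_numpy()
    grouped = canon.groupby(["protein_a", "protein_b"], sort=False)
    for (a, b), g in grouped:
        if len(g) > 1 and (g[["identity", "coverage"]].nunique() > 1).any():
            raise SchemaError(f"{path}: conflicting similarity entries for ({a}, {b})")
    return grouped.first().reset_index()


def _check_ranges(df: pd.DataFrame, sch: Schema, path: str) -> None:
    def require(mask: pd.Series, msg: str) -> None:
        bad = mask.fillna(False) if hasattr(mask, "fillna") else mask
        if bad.any():
            raise SchemaError(f"{path}: {msg} (first offending row {int(bad.idxmax()) + 1})")

    if sch.name == "drugs" and "molecular_weight" in df:
        require(df.molecular_weight <= 0, "molecular_weight must be > 0")
        require(df.rotatable_bonds < 0, "rotatable_bonds must be >= 0")
    elif sch.name == "adr":
        for c in ("frequency", "placebo_frequency"):
            require((df[c] < 0) | (df[c] > 100), f"{c} must be in [0, 100]")
    elif sch.name == "proteins":
        require(df.resolution <= 0, "resolution must be > 0")
        require(df.length < 1, "length must be >= 1")
    elif sch.name == "similarity":
        for c in ("identity", "coverage"):
            require((df[c] < 0) | (df[c] > 100), f"{c} must be in [0, 100]")
    elif sch.name == "docking":
        require(~df.pocket_id.isin([1, 2]), "pocket_id must be 1 or 2")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with ``NA`` for missing cells (round-trip safe)."""
    out = df.copy()
    for c in out.columns:
        if str(out[c].dtype) in ("Float64", "float64"):
            out[c] = out[c].map(lambda v: NA if pd.isna(v) else repr(float(v)))
        elif str(out[c].dtype) == "Int64":
            out[c] = out[c].map(lambda v: NA if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False, na_rep=NA)


@dataclass
class DockingScoreMatrix:
    """Raw drug×protein(×pocket) docking scores plus their declared orientation."""

    entries: pd.DataFrame          # schema "docking"
    better_direction: Direction

    def __post_init__(self) -> None:
        self.better_direction = Direction.coerce(self.better_direction)


def read_docking(path: str | Path, better_direction: Direction | str | None) -> DockingScoreMatrix:
    """Read a docking table; ``better_direction`` is mandatory, never guessed."""
    direction = Direction.coerce(better_direction)
    return DockingScoreMatrix(read_table(path, "docking"), direction)


# ---------------------------------------------------------------------------
# Network export

EDGE_TYPES = ("binds", "member_of", "causes", "associated_with")


def export_network(
    associations: pd.DataFrame,
    retained_interactions: pd.DataFrame,
    pathway_map: pd.DataFrame,
    adr_matrix: pd.DataFrame,
    path: str | Path,
) -> None:
    """Write the full relation network as a SIF edge list.

    Four typed edge classes: drug→protein ``binds`` (predicted by docking),
    protein→pathway ``member_of`` (annotation), drug→ADR ``causes``
    (observed), pathway→ADR ``associated_with`` (inferred).  Any association
    referencing a pathway or ADR group absent from the annotation/observation
    layers is a dangling-id error.
    """
    known_pathways = set(pathway_map.pathway_id)
    known_adrs = set(adr_matrix.columns)
    dangling = sorted(
        set(associations.pathway_id) - known_pathways
    ) + sorted(set(associations.adr_group) - known_adrs)
    if dangling:
        raise ValueError(f"dangling ids in associations: {dangling}")

    lines: list[tuple[str, str, str]] = []
    ri = retained_interactions
    if "retained" in ri.columns:
        ri = ri[ri.retained]
    for row in ri.itertuples(index=False):
        lines.append((row.drug_id, "binds", row.protein_id))
    for row in pathway_map.itertuples(index=False):
        lines.append((row.protein_id, "member_of", row.pathway_id))
    for drug in adr_matrix.index:
        for adr in adr_matrix.columns[adr_matrix.loc[drug].to_numpy(dtype=bool)]:
            lines.append((str(drug), "causes", str(adr)))
    for row in associations.itertuples(index=False):
        lines.append((row.pathway_id, "associated_with", row.adr_group))
    with open(path, "w", encoding="utf-8") as fh:
        for src, rel, dst in lines:
            fh.write(f"{src}\t{rel}\t{dst}\n")


def read_network(path: str | Path) -> pd.DataFrame:
    """Read a SIF edge list back as (source, relation, target) rows."""
    df = pd.read_csv(
        path, sep="\t", names=["source", "relation", "target"],
        dtype=str, keep_default_na=False,
    )
    unknown = set(df.relation) - set(EDGE_TYPES)
    if unknown:
        raise SchemaError(f"{path}: unknown edge types {sorted(unknown)}")
    return df


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
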