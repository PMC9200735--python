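"""Readers and writers for the delimited-text file schemas.

Everything is comma-delimited UTF-8 with a decimal point.  Two fraction
encodings exist side by side in the historical file set and both are
registered explicitly: the catch-export dialect (2 = landings, 1 = discards)
and the Spanish-fleet dialect (0 = discards, 1 = landings).  Months are
0-based indices from January of the start year, with a companion year-month
column for human readers.

All parsing goes through pandas; this module only adds schema validation
(field names, arity, sign constraints) and the mapping between files and the
in-memory objects.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import FRACTIONS, OutputStore

__all__ = ["TableSchema", "SCHEMAS", "read_table", "write_table", "write_outputs"]

FRACTION_EXPORT = {"landings": 2, "discards": 1}  # catch-export dialect
FRACTION_SPANISH = {"landings": 1, "discards": 0}  # Spanish-fleet dialect

FLOAT_FORMAT = "%.6g"  # fixed numeric formatting => byte-stable reruns


@dataclass(frozen=True)
class TableSchema:
    """A registered file schema: ordered fields or a matrix orientation."""

    name: str
    fields: tuple[str, ...]  # empty for matrix-oriented files
    orientation: str = "long"  # "long" | "matrix"
    non_negative: tuple[str, ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        if len(set(self.fields)) != len(self.fields):
            raise ValueError(f"schema {self.name}: duplicate field names")


SCHEMAS: dict[str, TableSchema] = {}


def _register(schema: TableSchema) -> TableSchema:
    SCHEMAS[schema.name] = schema
    return schema


# -- output schemas (trace and catch files) ---------------------------------
_register(TableSchema(
    "StrMetBeforeChecks",
    ("month", "metier_of_origin", "strategy", "share_before",
     "destination_metiers", "destination_proportions"),
    description="Effort re-allocation trace (before)",
))
_register(TableSchema(
    "StrMetAfterChecks", ("month", "metier", "strategy", "share_after"),
    description="Effort re-allocation trace (after)",
))
_register(TableSchema(
    "TACvalues", ("year", "population", "quota_tons"),
    non_negative=("quota_tons",),
    description="Simulated catch/landings quota values trace",
))
_register(TableSchema(
    "TraceTarfs",
    ("month", "target_factor", "original", "new",
     "ratio_hake", "ratio_sole", "ratio_nephrops"),
    description="Changes done on target factors due to management rules",
))
_register(TableSchema(
    "flagChecks", ("month", "metier", "flagged"),
    description="Métier flags trace",
))
_register(TableSchema(
    "catch",
    ("month", "year_month", "metier", "zone", "stock", "class", "fraction",
     "numbers", "tons"),
    non_negative=("numbers", "tons"),
    description="Catch per month, métier, zone, stock and class "
                "(fraction: 2 = landings, 1 = discards)",
))
_register(TableSchema(
    "catchSpanishLG",
    ("month", "unused", "fraction", "length_group", "tons"),
    non_negative=("tons",),
    description="Spanish longliners and gillnetters hake catch in tons "
                "(fraction: 0 = discards, 1 = landings)",
))
_register(TableSchema(
    "catchSpanishLGNum",
    ("month", "unused", "fraction", "length_group", "numbers"),
    non_negative=("numbers",),
    description="Spanish longliners and gillnetters hake catch in numbers",
))

# -- input schemas -----------------------------------------------------------
_register(TableSchema(
    "hake_init", (), orientation="matrix",
    description="Hake initial abundance: 1 column per area, 1 row per length bin",
))
_register(TableSchema(
    "sole_init", ("age_class", "abundance"), non_negative=("abundance",),
    description="Sole initial abundance: 1 value per age bin",
))
_register(TableSchema(
    "nephrops_init", (), orientation="matrix",
    description="Norway lobster initial abundance: 1 column per statistical "
                "rectangle, 1 row per length*sex bin",
))
_register(TableSchema(
    "catch_ratios", (), orientation="matrix",
    description="Spanish over French catch ratios: 1 row per month, "
                "1 column per size bin",
))
_register(TableSchema(
    "weightings", ("quarter", "metier_group", "fraction", "weight"),
    non_negative=("weight",),
    description="Objective-function weightings",
))
_register(TableSchema(
    "weight_at_length", ("class", "weight_tons"), non_negative=("weight_tons",),
    description="Mean weight per size bin",
))
_register(TableSchema(
    "observed_catch", ("stock", "metier_group", "season", "year", "tons"),
    non_negative=("tons",),
    description="Observed catch for inter-annual factors",
))


def read_table(schema: TableSchema | str, source) -> pd.DataFrame:
    """Read and validate a file against a registered schema.

    Long-oriented schemas must carry exactly the registered columns (an
    unknown or missing column is an error naming it); matrix-oriented
    schemas are read with a label index/header and checked for
    non-negativity.  Violations are reported with row numbers.
    """
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    if schema.orientation == "matrix":
        df = pd.read_csv(source, index_col=0)
        num = df.select_dtypes("number")
        bad = num.lt(0).any(axis=1)
        if bad.any():
            rows = [int(i) for i in np.flatnonzero(bad.to_numpy())]
            raise ValueError(f"{schema.name}: negative values in rows {rows}")
        return df
    df = pd.read_csv(source)
    extra = set(df.columns) - set(schema.fields)
    if extra:
        raise ValueError(f"{schema.name}: unknown column(s) {sorted(extra)}")
    missing = set(schema.fields) - set(df.columns)
    if missing:
        raise ValueError(f"{schema.name}: missing column(s) {sorted(missing)}")
    df = df[list(schema.fields)]
    for col in schema.non_negative:
        bad = df[col].lt(0)
        if bad.any():
            rows = [int(i) for i in np.flatnonzero(bad.to_numpy())]
            raise ValueError(f"{schema.name}: negative {col!r} in rows {rows}")
    return df


def write_table(schema: TableSchema | str, df: pd.DataFrame, path) -> None:
    """Write a frame under a registered schema with fixed field order and
    numeric formatting (reruns on identical data are byte-identical)."""
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    if schema.orientation == "matrix":
        df.to_csv(path, float_format=FLOAT_FORMAT)
        return
    out = df.reindex(columns=list(schema.fields))
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _year_month(store: OutputStore, t: int) -> str:
    return f"{store.year_of(t)}-{t % 12 + 1:02d}"


def catch_frame(store: OutputStore, stock: str, structure_labels: tuple[str, ...]) -> pd.DataFrame:
    """Long-format catch records for one stock (non-zero cells only)."""
    rows = []
    cn, cw = store.catch_n[stock], store.catch_w[stock]
    for t in range(store.n_months):
        for ri, rm in enumerate(store.rows[stock]):
            for fi, frac in enumerate(FRACTIONS):
                nz = np.flatnonzero(cn[t, ri, :, fi])
                for c in nz:
                    rows.append((
                        t, _year_month(store, t), rm.name, rm.zone, stock,
                        structure_labels[c], FRACTION_EXPORT[frac],
                        cn[t, ri, c, fi], cw[t, ri, c, fi],
                    ))
    return pd.DataFrame(rows, columns=list(SCHEMAS["catch"].fields))


def write_outputs(store: OutputStore, config, out_dir) -> list[str]:
    """Write every registered output file for a finished run.

    Emits the five management trace files, the catch table and (when the
    run has Spanish-fleet rows) the two Spanish hake catch files.  Returns
    the list of files written.  An empty store yields headers-only files.
    """
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def emit(name: str, df: pd.DataFrame, schema: str | None = None) -> None:
        path = os.path.join(out_dir, f"{name}.csv")
        write_table(schema or name, df, path)
        written.append(path)

    emit("StrMetBeforeChecks", pd.DataFrame(
        [(tr.month, tr.origin, tr.strategy, tr.share_before,
          ";".join(tr.destinations), ";".join(f"{p:.6g}" for p in tr.proportions))
         for tr in store.realloc_traces],
        columns=list(SCHEMAS["StrMetBeforeChecks"].fields)))
    emit("StrMetAfterChecks", pd.DataFrame(
        [(tr.month, tr.origin, tr.strategy, tr.share_after)
         for tr in store.realloc_traces],
        columns=list(SCHEMAS["StrMetAfterChecks"].fields)))
    emit("TACvalues", pd.DataFrame(
        [(y, s, amount) for (y, s, qtype, amount) in store.quota_values if qtype != "none"],
        columns=list(SCHEMAS["TACvalues"].fields)))
    emit("TraceTarfs", pd.DataFrame(
        [(tr.month, tr.name, tr.original, tr.new,
          tr.quota_ratio.get("hake", np.inf), tr.quota_ratio.get("sole", np.inf),
          tr.quota_ratio.get("nephrops", np.inf))
         for tr in store.tf_traces],
        columns=list(SCHEMAS["TraceTarfs"].fields)))
    emit("flagChecks", pd.DataFrame(
        [(f.month, f.metier, int(f.value)) for f in store.flags],
        columns=list(SCHEMAS["flagChecks"].fields)))

    frames = [catch_frame(store, s, config.stocks[s].structure.labels) for s in store.stocks]
    emit("catch", pd.concat(frames, ignore_index=True) if frames else
         pd.DataFrame(columns=list(SCHEMAS["catch"].fields)))

    if "hake" in store.stocks:
        es = [i for i, rm in enumerate(store.rows["hake"]) if rm.nationality == "ES"]
        if es:
            rows_w, rows_n = [], []
            cn, cw = store.catch_n["hake"], store.catch_w["hake"]
            labels = config.stocks["hake"].structure.labels
            for t in range(store.n_months):
                for ri in es:
                    for frac, fi in (("discards", 1), ("landings", 0)):
                        for c in np.flatnonzero(cn[t, ri, :, fi]):
                            code = FRACTION_SPANISH[frac]
                            rows_w.append((t, 0, code, labels[c], cw[t, ri, c, fi]))
                            rows_n.append((t, 0, code, labels[c], cn[t, ri, c, fi]))
            emit("catchSpanishLGWithRule", pd.DataFrame(
                rows_w, columns=list(SCHEMAS["catchSpanishLG"].fields)), "catchSpanishLG")
            emit("catchSpanishLGNumWithRule", pd.DataFrame(
                rows_n, columns=list(SCHEMAS["catchSpanishLGNum"].fields)), "catchSpanishLGNum")
    return written
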