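"""Tabular input and report rendering.

The one tabular dialect is TSV: tab-separated, UTF-8, header row required,
'.' decimal point.  Validation outcome tables carry a ``feature_id`` column
and a binary ``delta`` column (1 = the feature failed validation); p-value
tables carry a ``pvalue`` column with an optional id column.  Reports render
as JSON (full precision), TSV, or human-readable text rounded to the 2-3
decimals customary in write-ups.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .design import SignificanceProfile

__all__ = [
    "ValidationTable",
    "read_validation_table",
    "read_pvalues",
    "render_report",
]


class TableFormatError(ValueError):
    """A tabular input file violates the expected layout."""


@dataclasses.dataclass(frozen=True)
class ValidationTable:
    feature_ids: tuple[str, ...]
    deltas: np.ndarray

    @property
    def n(self) -> int:
        return len(self.feature_ids)

    @property
    def n_fp(self) -> float:
        return float(self.deltas.sum())


def read_validation_table(path) -> ValidationTable:
    """Parse a per-feature validation outcome TSV.

    Requires ``feature_id`` and ``delta`` columns; ids must be unique and
    deltas binary.  Errors name the offending lines (1-based, counting the
    header as line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: file is empty") from None
    missing = {"feature_id", "delta"} - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {sorted(missing)}")
    if df.empty:
        raise TableFormatError(f"{path}: table has a header but no rows")
    deltas = pd.to_numeric(df["delta"], errors="coerce")
    bad = ~deltas.isin([0, 1])
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +1 header, +1 one-based
        raise TableFormatError(
            f"{path}: delta must be 0 or 1; offending line(s) {lines[:10]}"
        )
    dup = df["feature_id"][df["feature_id"].duplicated()].unique()
    if dup.size:
        raise TableFormatError(f"{path}: duplicate feature_id(s) {dup[:10].tolist()}")
    return ValidationTable(tuple(df["feature_id"]), deltas.to_numpy(dtype=np.int64))


def read_pvalues(path) -> SignificanceProfile:
    """Parse a p-value TSV (``pvalue`` column, optional id column)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: file is empty") from None
    if "pvalue" not in df.columns:
        raise TableFormatError(f"{path}: missing required column 'pvalue'")
    p = pd.to_numeric(df["pvalue"], errors="coerce")
    bad = p.isna() | (p < 0) | (p > 1)
    if bad.any():
        offenders = df["pvalue"][bad].head(5).tolist()
        raise TableFormatError(f"{path}: p-values outside [0, 1]: {offenders}")
    return SignificanceProfile(p.to_numpy())


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _render_text(results: dict[str, Any]) -> str:
    out = []
    flat = _jsonable(results)

    def emit(prefix: str, value: Any) -> None:
        if isinstance(value, dict):
            for k, v in value.items():
                emit(f"{prefix}{k}." if prefix else f"{k}.", v) if isinstance(v, dict) \
                    else emit(f"{prefix}{k}", v)
            return
        if isinstance(value, float):
            shown = f"{value:.2f}" if abs(value) >= 0.01 or value == 0 else f"{value:.3g}"
            out.append(f"{prefix.rstrip('.').replace('_', ' ')}: {shown}")
        elif isinstance(value, list):
            shown = ", ".join(f"{v:.3f}" if isinstance(v, float) else str(v) for v in value)
            out.append(f"{prefix.rstrip('.').replace('_', ' ')}: ({shown})")
        else:
            out.append(f"{prefix.rstrip('.').replace('_', ' ')}: {value}")

    emit("", flat)
    return "\n".join(out) + "\n"


def render_report(results: dict[str, Any], format: str = "json") -> str:
    """Serialize a result mapping.

    ``json`` keeps full precision and round-trips; ``tsv`` flattens to
    key/value rows; ``text`` rounds floats to 2 decimals (3 significant
    digits for small magnitudes) for human reading.
    """
    if format == "json":
        return json.dumps(_jsonable(results), indent=2, sort_keys=False) + "\n"
    if format == "tsv":
        flat = pd.json_normalize(_jsonable(results), sep=".")
        buf = _io.StringIO()
        flat.T.reset_index().to_csv(
            buf, sep="\t", header=["key", "value"], index=False
        )
        return buf.getvalue()
    if format == "text":
        return _render_text(results)
    raise ValueError(f"unknown report format {format!r}; expected json, tsv or text")
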