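"""Validated readers and writers for the package's table dialects.

Three schemas are shared by every stage:

* ``intensity`` — raw assay table: individual_id, group, tissue, locus,
  allele_a_label, allele_b_label, intensity_a, intensity_b
* ``ratio``     — scalar scores: individual_id, group, tissue, locus,
  score_kind, value
* ``ct``        — qPCR table: individual_id, group, tissue, gene, ct

CSV is the canonical dialect (comma, UTF-8, header required, "." decimal
separator); TSV is accepted on read by delimiter sniffing.  Validation
errors name the offending column or row so problems in hand-edited tables
are quick to locate.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import pandas as pd

from .vocab import Gene, Group, Locus, ScoreKind, Tissue, coerce

__all__ = ["TableFormatError", "SCHEMAS", "read_table", "write_table"]

logger = logging.getLogger(__name__)


class TableFormatError(ValueError):
    """A table failed schema validation."""


#: schema -> (column -> validator); numeric columns map to float bounds,
#: enum columns to their vocabulary class, plain strings to None.
SCHEMAS: dict[str, dict[str, object]] = {
    "intensity": {
        "individual_id": None,
        "group": Group,
        "tissue": Tissue,
        "locus": Locus,
        "allele_a_label": None,
        "allele_b_label": None,
        "intensity_a": ("numeric", 0.0, None),
        "intensity_b": ("numeric", 0.0, None),
    },
    "ratio": {
        "individual_id": None,
        "group": Group,
        "tissue": Tissue,
        "locus": Locus,
        "score_kind": ScoreKind,
        "value": ("numeric", 0.0, None),
    },
    "ct": {
        "individual_id": None,
        "group": Group,
        "tissue": Tissue,
        "gene": Gene,
        "ct": ("numeric", None, None),
    },
}


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        sample = fh.read(4096)
    if not sample.strip():
        return ","
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV/TSV table against one of the shared schemas.

    Returns a DataFrame with enum columns normalized to their string values
    and numeric columns as float64.  Raises :class:`TableFormatError`
    naming the unknown column, the unparseable row, or the invalid enum
    value.  An empty table (header only) is returned as-is with a warning.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    spec = SCHEMAS[schema]
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)

    unknown = [c for c in df.columns if c not in spec]
    if unknown:
        raise TableFormatError(f"{path}: unknown column(s) {unknown}")
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    if df.empty:
        logger.warning("%s: table has a header but no rows", path)
        return df

    out = {}
    for col, rule in spec.items():
        series = df[col]
        if rule is None:
            out[col] = series.astype(str)
        elif isinstance(rule, tuple) and rule[0] == "numeric":
            _, lo, hi = rule
            parsed = pd.to_numeric(series, errors="coerce")
            bad = parsed.isna()
            if bad.any():
                row = int(bad.idxmax()) + 2  # 1-based, plus header line
                raise TableFormatError(
                    f"{path}: column {col!r}, line {row}: "
                    f"unparseable numeric value {series[bad.idxmax()]!r}"
                )
            if lo is not None and (parsed < lo).any():
                row = int((parsed < lo).idxmax()) + 2
                raise TableFormatError(
                    f"{path}: column {col!r}, line {row}: value below {lo}"
                )
            if hi is not None and (parsed > hi).any():
                row = int((parsed > hi).idxmax()) + 2
                raise TableFormatError(
                    f"{path}: column {col!r}, line {row}: value above {hi}"
                )
            out[col] = parsed.astype(float)
        else:  # enum vocabulary
            values = []
            for i, raw in enumerate(series):
                try:
                    values.append(coerce(rule, raw).value)
                except ValueError as exc:
                    raise TableFormatError(
                        f"{path}: column {col!r}, line {i + 2}: {exc}"
                    ) from None
            out[col] = values
    return pd.DataFrame(out, columns=list(spec))


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as canonical CSV (comma, UTF-8, header, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
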