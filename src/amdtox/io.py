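"""Readers and writers for the package's TSV dialects, newick trees and the
run configuration.

All tables are tab-delimited UTF-8 with '.' decimals.  Readers validate the
header against the declared dialect and report malformed cells with the
file, line and column that caused them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import skbio
import yaml

from .exceptions import TableFormatError

__all__ = ["DIALECTS", "read_table", "write_table", "read_tree", "RunConfig", "load_config"]

# dialect -> (required columns, numeric columns, key columns for uniqueness);
# None key means no uniqueness constraint.
DIALECTS: dict[str, tuple[list[str], list[str], list[str] | None]] = {
    "metals": (
        ["sample_id", "replicate_id", "analyte", "concentration_mg_per_L"],
        ["concentration_mg_per_L"],
        ["sample_id", "replicate_id", "analyte"],
    ),
    "background": (["analyte", "background_mg_per_L"], ["background_mg_per_L"], ["analyte"]),
    "tr": (["analyte", "toxic_response_factor"], ["toxic_response_factor"], ["analyte"]),
    "pnec": (["analyte", "pnec_mg_per_L"], ["pnec_mg_per_L"], ["analyte"]),
    "standards": (["nh4cl_uM", "absorbance"], ["nh4cl_uM", "absorbance"], None),
    "urease_samples": (
        ["absorbance", "incubation_min", "dilution"],
        ["absorbance", "incubation_min", "dilution"],
        None,
    ),
    "timecourse": (["time_h", "od600", "ph"], ["time_h", "od600", "ph"], ["time_h"]),
    "sequestration": (
        ["analyte", "mqm_mg_per_L", "sq_mg_per_L"],
        ["mqm_mg_per_L", "sq_mg_per_L"],
        ["analyte"],
    ),
}


def read_table(path, dialect: str) -> pd.DataFrame:
    """Read and validate one TSV table.

    Extra columns beyond the dialect's required set are allowed (e.g. the
    per-metal supernatant columns of a time course) and numeric-coerced when
    their values parse.  Missing required columns, non-numeric cells and
    duplicate keys raise :class:`TableFormatError` naming file, line and
    column.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    required, numeric, key = DIALECTS[dialect]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing} for dialect {dialect!r}")
    if df.empty:
        warnings.warn(f"{path}: header-only table (no data rows)", stacklevel=2)
    extra_numeric = [
        c for c in df.columns
        if c not in required and not df.empty and _all_numeric(df[c])
    ]
    for col in numeric + extra_numeric:
        converted = pd.to_numeric(df[col].replace("", None), errors="coerce")
        bad = converted.isna() & df[col].ne("")
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise TableFormatError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {line}"
            )
        df[col] = converted
    if key is not None:
        dup = df.duplicated(subset=key)
        if dup.any():
            line = int(dup.idxmax()) + 2
            raise TableFormatError(f"{path}: duplicate key {key} at line {line}")
    return df


def _all_numeric(series: pd.Series) -> bool:
    nonempty = series[series.ne("")]
    if nonempty.empty:
        return False
    return pd.to_numeric(nonempty, errors="coerce").notna().all()


def write_table(df: pd.DataFrame, path, *, index: bool = False) -> None:
    """Write a TSV deterministically (fixed float formatting, LF endings)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g", lineterminator="\n")


def read_tree(path) -> skbio.TreeNode:
    """Parse a newick tree with branch lengths."""
    return skbio.TreeNode.read(str(path), format="newick")


@dataclass
class RunConfig:
    """Structured run configuration; unknown keys are rejected on load."""

    ef_reference_element: str | None = None
    mcd_variant: str = "mean_cf"
    mpi_basis: str = "ef"
    mer_basis: str = "ef"
    tr_overrides: dict[str, float] = field(default_factory=dict)
    rare_threshold: int = 10
    n_boot: int = 1000
    seed: int = 0
    out_dir: str = "."
    verbose: bool = False


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise TableFormatError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise TableFormatError(f"{path}: unknown config key(s) {unknown}; known keys: {sorted(known)}")
    return RunConfig(**raw)
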