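"""Cleaning of tabular repertoire data and success-rate evaluation.

These functions back the command-line interface.  A rearrangement-style
table (AIRR TSV with ``v_call``/``j_call``/``junction_aa`` columns is the
primary dialect, CSV is auto-detected by extension) has selected columns
replaced by standardized values — an empty cell marks a failure so
downstream tools can filter — and per-column success statistics are
computed over *unique* raw values, mirroring how curation of a database
export is usually reported.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from tcrnorm import aa, junction, mh, tr
from tcrnorm._core import normalize_species_label

logger = logging.getLogger("tcrnorm")

VALUE_KINDS = ("tr_gene", "mh_gene", "junction", "epitope")

__all__ = [
    "VALUE_KINDS",
    "ColumnSpec",
    "KindReport",
    "EvaluationReport",
    "standardize_value",
    "standardize_table",
    "evaluate_export",
]


@dataclass(frozen=True)
class ColumnSpec:
    """Which standardizer to apply to a named table column."""

    column_name: str
    value_kind: str  # one of VALUE_KINDS
    species_column: Optional[str] = None

    def __post_init__(self):
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(
                f"Unknown value kind {self.value_kind!r}: expected one of {VALUE_KINDS}."
            )


@dataclass
class KindReport:
    """Success statistics for one value kind."""

    unique_values: int = 0
    standardized: int = 0
    failure_examples: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def failed(self) -> int:
        return self.unique_values - self.standardized

    @property
    def success_fraction(self) -> float:
        if self.unique_values == 0:
            return 0.0
        return self.standardized / self.unique_values

    def to_dict(self) -> dict:
        return {
            "unique_values": self.unique_values,
            "standardized": self.standardized,
            "failed": self.failed,
            "success_fraction": self.success_fraction,
            "failure_examples": [list(pair) for pair in self.failure_examples],
        }


@dataclass
class EvaluationReport:
    """Per-kind success statistics for one table or export."""

    per_kind: Dict[str, KindReport] = field(default_factory=dict)

    def kind(self, value_kind: str) -> KindReport:
        return self.per_kind.setdefault(value_kind, KindReport())

    def to_dict(self) -> dict:
        return {k: v.to_dict() for k, v in sorted(self.per_kind.items())}

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def standardize_value(
    value_kind: str,
    raw: str,
    species: str = "homosapiens",
    precision: str = "allele",
    enforce_functional: bool = False,
    strict_junction: bool = False,
) -> Tuple[Optional[str], Optional[str]]:
    """Standardize one value, returning (standardized, diagnostic).

    The diagnostic is the warning text the standardizer emitted (None when
    the value standardized silently).
    """
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if value_kind == "tr_gene":
            result = tr.standardize(
                raw,
                species=species,
                precision="gene" if precision == "gene" else "allele",
                enforce_functional=enforce_functional,
            )
        elif value_kind == "mh_gene":
            result = mh.standardize(raw, species=species, precision=precision)
        elif value_kind == "junction":
            result = junction.standardize(raw, strict=strict_junction)
        elif value_kind == "epitope":
            result = aa.standardize(raw)
        else:
            raise ValueError(
                f"Unknown value kind {value_kind!r}: expected one of {VALUE_KINDS}."
            )
    diagnostic = str(caught[-1].message) if caught else None
    return result, diagnostic


_MAX_FAILURE_EXAMPLES = 20


def _read_table(path) -> Tuple[pd.DataFrame, str]:
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return frame, sep


def _row_species(row, species_column: Optional[str], default_species: str):
    """Per-row species identifier, or None when the row's label is
    unsupported (which counts as a standardization failure)."""
    if species_column is None:
        return default_species
    label = row[species_column]
    if not str(label).strip():
        return default_species
    return normalize_species_label(str(label))


def standardize_table(
    input_path,
    output_path,
    column_specs: Sequence[ColumnSpec],
    default_species: str = "homosapiens",
    precision: str = "allele",
    enforce_functional: bool = False,
    strict_junction: bool = False,
    report_path=None,
) -> EvaluationReport:
    """Standardize the specified columns of a tabular file.

    Writes a copy of the table with each specified column replaced by
    standardized values (empty cell on failure; unspecified columns pass
    through untouched) and returns an :class:`EvaluationReport` computed
    over unique raw values per kind — for gene kinds uniqueness is per
    (value, species) when a per-row species column is in use, for
    junction/epitope kinds per raw string.

    Raises KeyError if a named column is missing from the table.
    """
    frame, sep = _read_table(input_path)
    for spec in column_specs:
        for name in filter(None, (spec.column_name, spec.species_column)):
            if name not in frame.columns:
                raise KeyError(f"Column {name!r} not found in {input_path}.")

    report = EvaluationReport()
    seen: Dict[str, Dict[tuple, Optional[str]]] = {k: {} for k in VALUE_KINDS}
    for spec in column_specs:
        stats = report.kind(spec.value_kind)
        cache = seen[spec.value_kind]
        new_column = []
        for _, row in frame.iterrows():
            raw = row[spec.column_name]
            species = _row_species(row, spec.species_column, default_species)
            key = (raw, species) if spec.value_kind in ("tr_gene", "mh_gene") else (raw,)
            if key not in cache:
                if species is None:
                    result, diagnostic = None, (
                        f"Unsupported species label for value {raw!r}."
                    )
                else:
                    result, diagnostic = standardize_value(
                        spec.value_kind,
                        raw,
                        species=species,
                        precision=precision,
                        enforce_functional=enforce_functional,
                        strict_junction=strict_junction,
                    )
                cache[key] = result
                stats.unique_values += 1
                if result is not None:
                    stats.standardized += 1
                else:
                    logger.info("failed to standardize %r: %s", raw, diagnostic)
                    if len(stats.failure_examples) < _MAX_FAILURE_EXAMPLES:
                        stats.failure_examples.append((raw, diagnostic or ""))
            new_column.append(cache[key] if cache[key] is not None else "")
        frame[spec.column_name] = new_column

    frame.to_csv(output_path, sep=sep, index=False)
    if report_path is not None:
        with open(report_path, "w") as fh:
            fh.write(report.to_json() + "\n")
    return report


def evaluate_export(
    values_path,
    value_kind: str,
    default_species: str = "homosapiens",
    value_column: Optional[str] = None,
    species_column: Optional[str] = None,
    precision: str = "allele",
    enforce_functional: bool = False,
    strict_junction: bool = False,
) -> EvaluationReport:
    """Measure the standardization success rate over an export of raw
    values (e.g. the unique symbol values of a database column).

    The file's first column is used unless ``value_column`` names another;
    an optional species column supplies per-row labels, with unsupported
    labels counting as failures and missing ones falling back to the
    default species.  Values are deduplicated before standardization.  An
    empty export yields a zero-count report, not an error.
    """
    if value_kind not in VALUE_KINDS:
        raise ValueError(
            f"Unknown value kind {value_kind!r}: expected one of {VALUE_KINDS}."
        )
    frame, _ = _read_table(values_path)
    report = EvaluationReport()
    stats = report.kind(value_kind)
    if frame.empty:
        return report
    column = value_column or frame.columns[0]
    if column not in frame.columns:
        raise KeyError(f"Column {column!r} not found in {values_path}.")
    seen = set()
    for _, row in frame.iterrows():
        raw = row[column]
        species = _row_species(row, species_column, default_species)
        key = (raw, species) if value_kind in ("tr_gene", "mh_gene") else (raw,)
        if key in seen:
            continue
        seen.add(key)
        if species is None:
            result, diagnostic = None, f"Unsupported species label for value {raw!r}."
        else:
            result, diagnostic = standardize_value(
                value_kind,
                raw,
                species=species,
                precision=precision,
                enforce_functional=enforce_functional,
                strict_junction=strict_junction,
            )
        stats.unique_values += 1
        if result is not None:
            stats.standardized += 1
        else:
            logger.info("failed to standardize %r: %s", raw, diagnostic)
            if len(stats.failure_examples) < _MAX_FAILURE_EXAMPLES:
                stats.failure_examples.append((raw, diagnostic or ""))
    return report
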