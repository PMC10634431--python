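"""Standardization and classification of MH (MHC) gene symbols.

Human genes use IMGT/HLA nomenclature (``HLA-DQB1*06:02``); mouse genes use
the IMGT ``MH1-``/``MH2-`` nomenclature, with legacy ``H2-``/``H-2``
symbols (``H2-Q9``, ``H2-Kb``) accepted as input.  Allele designations are
colon-separated two-digit fields after ``*``; the registry catalogues genes
only, so a valid root keeps its (zero-padded) fields as given, capped at
four fields.

Precision levels: ``allele`` keeps all fields, ``protein`` keeps at most
the first two (the protein-level identity used by most analyses), ``gene``
drops them all.
"""

from __future__ import annotations

import re
from typing import Optional, Set

from tcrnorm import reference
from tcrnorm._core import GeneRecord, NoMetadataError, validate_species, warn

PRECISIONS = ("allele", "protein", "gene")

_H2_RE = re.compile(r"^H-?2-?(.+)$")
_MAX_FIELDS = 4

__all__ = ["standardize", "query", "get_chain", "get_class", "PRECISIONS"]


def _resolve_root(registry, root: str) -> Optional[GeneRecord]:
    rec = registry.lookup(root)
    if rec is not None and rec.locus == "MH":
        return rec
    if registry.species == "homosapiens" and not root.startswith("HLA-"):
        rec = registry.lookup("HLA-" + root)
        if rec is not None and rec.locus == "MH":
            return rec
    if registry.species == "musmusculus":
        m = _H2_RE.match(root)
        if m:
            remainder = m.group(1).lstrip("-")
            for attempt in (f"MH1-{remainder}", f"MH2-{remainder}", f"H2-{remainder}"):
                rec = registry.lookup(attempt)
                if rec is not None and rec.locus == "MH":
                    return rec
    return None


def standardize(
    raw,
    species: str = "homosapiens",
    precision: str = "allele",
    suppress_warnings: bool = False,
) -> Optional[str]:
    """Standardize an MH gene symbol to its IMGT-compliant form.

    Whitespace-separated qualifier text is discarded: the first token that
    resolves to a known MH gene of the species is used, and a string none
    of whose tokens resolve fails.  Returns None (with a diagnostic
    warning) on failure; raises ValueError only for unknown species or
    precision keywords.
    """
    validate_species(species)
    if precision not in PRECISIONS:
        raise ValueError(f"Unknown precision {precision!r}: expected one of {PRECISIONS}.")
    registry = reference.load_reference(species)

    def fail(reason: str, attempted: str) -> None:
        warn(
            f'Failed to standardize "{raw}" for species {species}: {reason}. '
            f'Attempted fix "{attempted}".',
            suppress_warnings,
        )

    if not isinstance(raw, str) or not raw.strip():
        fail("input is not a non-empty string", str(raw))
        return None

    tokens = raw.strip().upper().split()
    record: Optional[GeneRecord] = None
    fields: list = []
    for token in tokens:
        root, star, allele_part = token.partition("*")
        rec = _resolve_root(registry, root)
        if rec is None:
            continue
        record = rec
        if star:
            fields = [
                f.zfill(2) if f.isdigit() else f
                for f in allele_part.split(":")
                if f
            ]
        break

    if record is None:
        fail("unrecognized gene symbol", tokens[0])
        return None

    if len(fields) > _MAX_FIELDS:
        warn(
            f'Discarding allele fields beyond the fourth in "{raw}" '
            f"({record.symbol}).",
            suppress_warnings,
        )
        fields = fields[:_MAX_FIELDS]

    if precision == "gene":
        fields = []
    elif precision == "protein":
        fields = fields[:2]

    if not fields:
        return record.symbol
    return f"{record.symbol}*{':'.join(fields)}"


def _resolve_record(symbol: str, species: str) -> GeneRecord:
    standardized = standardize(symbol, species=species, precision="gene", suppress_warnings=True)
    if standardized is None:
        raise ValueError(
            f"{symbol!r} could not be standardized to a known MH gene for "
            f"species {species}."
        )
    return reference.load_reference(species).records[standardized]


def get_chain(symbol: str, species: str = "homosapiens") -> str:
    """Classify an MH gene as an "alpha" or "beta" chain gene."""
    record = _resolve_record(symbol, species)
    if record.chain is None:
        raise NoMetadataError(f"No chain annotation for {record.symbol} ({species}).")
    return record.chain


def get_class(symbol: str, species: str = "homosapiens") -> int:
    """Classify an MH gene as MH class 1 or 2."""
    record = _resolve_record(symbol, species)
    if record.mh_class is None:
        raise NoMetadataError(f"No MH class annotation for {record.symbol} ({species}).")
    return record.mh_class


def query(
    species: str = "homosapiens",
    precision: str = "gene",
    contains: Optional[str] = None,
) -> Set[str]:
    """Query the catalogue of known MH genes for a species.

    The registry catalogues MH genes (not alleles), so every precision
    renders the same gene-level symbols; ``contains`` filters on a
    substring.
    """
    validate_species(species)
    if precision not in PRECISIONS:
        raise ValueError(f"Unknown precision {precision!r}: expected one of {PRECISIONS}.")
    registry = reference.load_reference(species)
    return {
        sym
        for sym, rec in registry.records.items()
        if rec.locus == "MH" and (contains is None or contains in sym)
    }
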