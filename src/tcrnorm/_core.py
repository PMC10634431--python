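"""Shared domain types and the warning plumbing used by every standardizer.

The package supports exactly two species, identified by the lower-case,
space-free strings ``"homosapiens"`` and ``"musmusculus"``.  Gene records
carry IMGT functionality classes per allele: ``F`` (functional), ``ORF``
(open reading frame) and ``P`` (pseudogene).  A gene counts as functional
iff at least one of its alleles is class F.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional

SUPPORTED_SPECIES = ("homosapiens", "musmusculus")
FUNCTIONALITY_CLASSES = ("F", "ORF", "P")

#: module-level switch; when True no standardizer emits warnings.
_suppress_all = False


def suppress_warnings(value: bool = True) -> None:
    """Globally silence (or re-enable) standardization warnings.

    Batch runs over many thousands of values use this so the console is not
    flooded; the CLI routes diagnostics through ``logging`` instead.
    """
    global _suppress_all
    _suppress_all = bool(value)


def warn(message: str, suppress: bool = False) -> None:
    """Emit a standardization diagnostic unless suppressed."""
    if suppress or _suppress_all:
        return
    warnings.warn(message, UserWarning, stacklevel=3)


def validate_species(species: str) -> str:
    if species not in SUPPORTED_SPECIES:
        raise ValueError(
            f"Unsupported species {species!r}: supported identifiers are "
            f"{SUPPORTED_SPECIES[0]!r} and {SUPPORTED_SPECIES[1]!r}."
        )
    return species


def normalize_species_label(label: str) -> Optional[str]:
    """Map a free-text species label ("Homo sapiens", "musmusculus", ...)
    onto a supported identifier, or None if the species is unsupported."""
    if not isinstance(label, str):
        return None
    compact = "".join(label.split()).lower()
    return compact if compact in SUPPORTED_SPECIES else None


class NoMetadataError(LookupError):
    """A resolved gene record lacks the metadata a query asked for
    (chain / MH class annotation, or packaged amino-acid sequence data)."""


class RegistrySchemaError(ValueError):
    """A packaged registry file violates the registry schema; the message
    lists every offending entry."""


@dataclass(frozen=True)
class GeneRecord:
    """One canonical gene with its alleles, synonyms and metadata.

    ``alleles`` maps two-digit allele designations ("01") to functionality
    classes.  ``synonyms`` are deprecated/alternative symbols, stored
    upper-cased.  ``chain`` and ``mh_class`` are MH-only; ``sequences``
    (feature label -> amino-acid string) is TR-only.
    """

    symbol: str
    locus: str  # "TR" or "MH"
    alleles: Mapping[str, str] = field(default_factory=dict)
    synonyms: tuple = ()
    chain: Optional[str] = None  # "alpha" | "beta"
    mh_class: Optional[int] = None  # 1 | 2
    sequences: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "alleles", MappingProxyType(dict(self.alleles)))
        object.__setattr__(self, "sequences", MappingProxyType(dict(self.sequences)))
        object.__setattr__(self, "synonyms", tuple(self.synonyms))

    @property
    def is_functional(self) -> bool:
        return any(cls == "F" for cls in self.alleles.values())

    @property
    def functionality_classes(self) -> frozenset:
        return frozenset(self.alleles.values())


@dataclass(frozen=True)
class ReferenceRegistry:
    """Immutable per-species catalogue of canonical genes.

    ``records`` maps canonical symbol -> GeneRecord; ``synonym_index`` is
    exactly the inversion of all records' synonym lists (upper-cased
    synonym -> canonical symbol).
    """

    species: str
    records: Mapping[str, GeneRecord]
    synonym_index: Mapping[str, str]

    def __post_init__(self):
        object.__setattr__(self, "records", MappingProxyType(dict(self.records)))
        object.__setattr__(
            self, "synonym_index", MappingProxyType(dict(self.synonym_index))
        )

    def lookup(self, token: str) -> Optional[GeneRecord]:
        """Resolve a token case-insensitively: canonical symbols take
        priority over synonyms; None signals a miss."""
        if not token:
            return None
        upper = token.upper()
        rec = self.records.get(upper)
        if rec is not None:
            return rec
        canonical = self.synonym_index.get(upper)
        if canonical is not None:
            return self.records[canonical]
        return None

    def symbols(self, locus: Optional[str] = None):
        if locus is None:
            return sorted(self.records)
        return sorted(s for s, r in self.records.items() if r.locus == locus)
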