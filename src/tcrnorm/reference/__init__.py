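"""Packaged per-species registries of valid TR and MH gene symbols.

Each species has one human-readable TSV per locus under ``data/`` with the
schema ``symbol, locus, chain, mh_class, alleles, synonyms`` ('-' marks an
empty field; alleles are ``designation=functionality`` pairs joined by '|',
synonyms are joined by '|').  A separate, explicitly synthetic file provides
per-gene amino-acid feature sequences for the TR sequence-lookup utility.

Registries are validated against the schema on load and are immutable
afterwards.  Contributors adding records can run :func:`validate_records`
(or simply reload) to check new rows.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources
from typing import Dict, Iterable, List, Optional

from tcrnorm._core import (
    FUNCTIONALITY_CLASSES,
    GeneRecord,
    ReferenceRegistry,
    RegistrySchemaError,
    validate_species,
)

_ALLELE_RE = re.compile(r"^\d{2}$")

__all__ = [
    "load_reference",
    "lookup",
    "validate_records",
    "RegistrySchemaError",
]


def _data_text(filename: str) -> str:
    return (
        resources.files("tcrnorm.reference").joinpath("data", filename).read_text()
    )


def _parse_rows(text: str, filename: str, n_fields: int = 6) -> Iterable[List[str]]:
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if not header_seen:  # first non-comment line is the header
            header_seen = True
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != n_fields:
            raise RegistrySchemaError(
                f"{filename}:{lineno}: expected {n_fields} tab-separated fields, "
                f"got {len(fields)}"
            )
        yield fields


def _parse_registry_file(filename: str) -> List[GeneRecord]:
    records = []
    for symbol, locus, chain, mh_class, alleles_s, synonyms_s in _parse_rows(
        _data_text(filename), filename
    ):
        alleles: Dict[str, str] = {}
        if alleles_s != "-":
            for part in alleles_s.split("|"):
                designation, _, cls = part.partition("=")
                alleles[designation] = cls
        synonyms = tuple(s.upper() for s in synonyms_s.split("|")) if synonyms_s != "-" else ()
        records.append(
            GeneRecord(
                symbol=symbol,
                locus=locus,
                alleles=alleles,
                synonyms=synonyms,
                chain=None if chain == "-" else chain,
                mh_class=None if mh_class == "-" else int(mh_class),
            )
        )
    return records


def _load_sequences(species: str) -> Dict[str, Dict[str, str]]:
    seqs: Dict[str, Dict[str, str]] = {}
    for sp, symbol, feature, sequence in _parse_rows(
        _data_text("tr_sequences_synthetic.tsv"),
        "tr_sequences_synthetic.tsv",
        n_fields=4,
    ):
        if sp == species:
            seqs.setdefault(symbol, {})[feature] = sequence
    return seqs


def validate_records(records: List[GeneRecord], species: str) -> None:
    """Check a record list against the registry schema invariants; raises
    :class:`RegistrySchemaError` listing every offending entry."""
    problems = []
    symbols = set()
    claimed_synonyms: Dict[str, str] = {}
    for rec in records:
        if rec.symbol in symbols:
            problems.append(f"duplicate symbol {rec.symbol!r}")
        symbols.add(rec.symbol)
        if rec.locus not in ("TR", "MH"):
            problems.append(f"{rec.symbol}: bad locus {rec.locus!r}")
        for designation, cls in rec.alleles.items():
            if not _ALLELE_RE.match(designation):
                problems.append(
                    f"{rec.symbol}: allele designation {designation!r} is not a "
                    "two-digit zero-padded decimal string"
                )
            if cls not in FUNCTIONALITY_CLASSES:
                problems.append(f"{rec.symbol}: bad functionality {cls!r}")
        if rec.chain not in (None, "alpha", "beta"):
            problems.append(f"{rec.symbol}: bad chain {rec.chain!r}")
        if rec.mh_class not in (None, 1, 2):
            problems.append(f"{rec.symbol}: bad MH class {rec.mh_class!r}")
        for syn in rec.synonyms:
            prior = claimed_synonyms.get(syn)
            if prior is not None and prior != rec.symbol:
                problems.append(
                    f"synonym {syn!r} claimed by both {prior} and {rec.symbol}"
                )
            claimed_synonyms[syn] = rec.symbol
    for syn, owner in claimed_synonyms.items():
        if syn in symbols:
            problems.append(
                f"synonym {syn!r} of {owner} equals a canonical symbol"
            )
    if problems:
        raise RegistrySchemaError(
            f"registry for {species} violates the schema: " + "; ".join(problems)
        )


@lru_cache(maxsize=None)
def load_reference(species: str = "homosapiens") -> ReferenceRegistry:
    """Load the packaged registry for a species.

    Raises ValueError for unsupported species and RegistrySchemaError if a
    packaged file is malformed.  Repeated calls return the same immutable
    registry object.
    """
    validate_species(species)
    records = _parse_registry_file(f"{species}_tr.tsv") + _parse_registry_file(
        f"{species}_mh.tsv"
    )
    sequences = _load_sequences(species)
    records = [
        GeneRecord(
            symbol=r.symbol,
            locus=r.locus,
            alleles=r.alleles,
            synonyms=r.synonyms,
            chain=r.chain,
            mh_class=r.mh_class,
            sequences=sequences.get(r.symbol, {}),
        )
        for r in records
    ]
    validate_records(records, species)
    return ReferenceRegistry(
        species=species,
        records={r.symbol: r for r in records},
        synonym_index={syn: r.symbol for r in records for syn in r.synonyms},
    )


def lookup(registry: ReferenceRegistry, token: str) -> Optional[GeneRecord]:
    """Case-insensitive resolution of a token against a registry: canonical
    symbols take priority over synonyms; returns None on a miss."""
    return registry.lookup(token)
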