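"""Standardization of T cell receptor (TR) gene symbols.

The central entry point is :func:`standardize`, which maps a potentially
non-standard TR gene symbol (legacy prefixes like ``TCR``, Wei/Arden
S-notation subfamilies, missing locus prefixes, stray qualifier text,
unpadded allele designations) onto its IMGT-compliant form, or returns
``None`` with a diagnostic warning when the input cannot be resolved to a
known gene of the requested species.

Resolution is purely rule-based and deterministic.  Rewrite attempts are
applied in a fixed order, re-consulting the registry after each:

1. replace a leading ``TCR`` with ``TR``;
2. prepend ``TR`` when the token starts with a locus letter pair
   (``AV``/``AJ``/``BV``/``BD``/``BJ``/``GV``/``GJ``/``DV``/``DD``/``DJ``);
3. prepend ``TRAV`` to bare alpha/delta dual-gene fragments (``29/DV5``);
4. strip legacy annotation suffixes after an S-notation subfamily
   (``TRBV22S1A2N1T`` -> ``TRBV22S1``);
5. convert S-notation ``rootNSm`` to ``rootN-m``, and for single-member
   subfamilies ``rootS1`` to ``root``;
6. consult the deprecated-synonym index (part of every lookup);
7. as a last resort, resolve a bare subgroup root to its only matching
   member (``TRAV15`` -> ``TRAV15-1/DV6-1`` when unique).
"""

from __future__ import annotations

import re
from typing import Dict, Optional, Set

from tcrnorm import reference
from tcrnorm._core import GeneRecord, ReferenceRegistry, NoMetadataError, validate_species, warn

PRECISIONS = ("allele", "gene")

_LOCUS_PAIRS = ("AV", "AJ", "BV", "BD", "BJ", "GV", "GJ", "DV", "DD", "DJ")
_DUAL_FRAGMENT_RE = re.compile(r"^\d+[A-Z0-9-]*/DV\d")
_S_SUFFIX_RE = re.compile(r"^(TR[ABGD]V\d+S\d+)[A-Z0-9]+$")
_S_NOTATION_RE = re.compile(r"^(TR[ABGD]V\d+)S(\d+)$")

__all__ = ["standardize", "query", "get_aa_sequence", "PRECISIONS"]


def _root_candidates(root: str) -> list:
    """Ordered, de-duplicated rewrite candidates for a normalized root."""
    cands = [root]

    def add(tok: Optional[str]) -> None:
        if tok and tok not in cands:
            cands.append(tok)

    if root.startswith("TCR"):
        add("TR" + root[3:])
    elif not root.startswith("TR") and root[:2] in _LOCUS_PAIRS:
        add("TR" + root)
    if _DUAL_FRAGMENT_RE.match(root):
        add("TRAV" + root)
    for cand in list(cands):
        m = _S_SUFFIX_RE.match(cand)
        if m:
            add(m.group(1))
    for cand in list(cands):
        m = _S_NOTATION_RE.match(cand)
        if m:
            base, member = m.group(1), int(m.group(2))
            add(f"{base}-{member}")
            if member == 1:
                add(base)
    return cands


def _resolve_root(registry: ReferenceRegistry, root: str):
    """Resolve a root token to a TR GeneRecord, or (None, attempts)."""
    cands = _root_candidates(root)
    for cand in cands:
        rec = registry.lookup(cand)
        if rec is not None and rec.locus == "TR":
            return rec, cands
    # subgroup-member fallback: a bare subgroup resolves iff exactly one
    # canonical symbol extends it as member 1 or as a dual-gene name.
    for cand in cands:
        hits: Set[str] = set()
        for sym, rec in registry.records.items():
            if rec.locus != "TR":
                continue
            if sym == cand + "-1" or sym.startswith((cand + "/", cand + "-1/")):
                hits.add(sym)
        if len(hits) == 1:
            return registry.records[hits.pop()], cands
    return None, cands


def standardize(
    raw,
    species: str = "homosapiens",
    precision: str = "allele",
    enforce_functional: bool = False,
    suppress_warnings: bool = False,
) -> Optional[str]:
    """Standardize a TR gene symbol to its IMGT-compliant form.

    Parameters
    ----------
    raw
        The symbol to standardize.  Anything that is not a non-empty string
        fails (returns None) rather than raising.
    species
        ``"homosapiens"`` (default) or ``"musmusculus"``.
    precision
        ``"allele"`` (default) keeps a catalogued allele designation;
        ``"gene"`` truncates it.
    enforce_functional
        When True, fail unless the resolved gene has at least one allele of
        functionality class F; when an allele is named, that allele itself
        must be class F.
    suppress_warnings
        Silence the diagnostic emitted on failure or attempted fixes.

    Returns the standardized symbol, or None if the input could not be
    resolved to a known TR gene.
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
    allele: Optional[str] = None
    last_attempt = tokens[0]
    for token in tokens:
        root, star, allele_part = token.partition("*")
        rec, cands = _resolve_root(registry, root)
        if rec is None:
            last_attempt = cands[-1]
            continue
        record = rec
        allele = allele_part if star else None
        break

    if record is None:
        fail("unrecognized gene symbol", last_attempt)
        return None

    if allele is not None:
        allele = allele.zfill(2) if allele.isdigit() else allele
        if allele not in record.alleles:
            # valid gene, unknown allele: degrade to gene-level output
            warn(
                f'Allele designation "*{allele}" of "{raw}" is not catalogued '
                f"for {record.symbol} ({species}); returning gene-level symbol.",
                suppress_warnings,
            )
            allele = None

    if enforce_functional:
        if allele is not None:
            if record.alleles[allele] != "F":
                fail(
                    f"allele {record.symbol}*{allele} is not functional",
                    f"{record.symbol}*{allele}",
                )
                return None
        elif not record.is_functional:
            fail("gene has no functional alleles", record.symbol)
            return None

    if precision == "gene" or allele is None:
        return record.symbol
    return f"{record.symbol}*{allele}"


def query(
    species: str = "homosapiens",
    precision: str = "gene",
    functionality: Optional[Set[str]] = None,
    contains: Optional[str] = None,
) -> Set[str]:
    """Query the catalogue of known TR genes (or alleles).

    ``precision="gene"`` returns gene symbols; ``"allele"`` returns one
    entry per catalogued allele (``TRBV6-4*01``).  ``functionality`` filters
    on IMGT functionality classes ({"F"}, {"F", "ORF"}, ...); at gene
    precision a gene passes when any of its alleles' classes intersects the
    filter.  ``contains`` keeps symbols containing the substring.
    """
    validate_species(species)
    if precision not in PRECISIONS:
        raise ValueError(f"Unknown precision {precision!r}: expected one of {PRECISIONS}.")
    if isinstance(functionality, str):
        functionality = {functionality}
    registry = reference.load_reference(species)
    out: Set[str] = set()
    for sym, rec in registry.records.items():
        if rec.locus != "TR":
            continue
        if precision == "gene":
            if functionality is not None and not (
                rec.functionality_classes & set(functionality)
            ):
                continue
            if contains is None or contains in sym:
                out.add(sym)
        else:
            for designation, cls in rec.alleles.items():
                if functionality is not None and cls not in functionality:
                    continue
                rendered = f"{sym}*{designation}"
                if contains is None or contains in rendered:
                    out.add(rendered)
    return out


def get_aa_sequence(symbol: str, species: str = "homosapiens") -> Dict[str, str]:
    """Return the packaged per-feature amino-acid sequences of a TR gene.

    The symbol is first standardized; an unresolvable symbol raises
    ValueError, and a gene without packaged sequence data raises
    :class:`~tcrnorm._core.NoMetadataError`.  Packaged sequences are
    synthetic placeholders exercising the lookup machinery (see the data
    file header), not IMGT germline sequences.
    """
    standardized = standardize(symbol, species=species, precision="gene", suppress_warnings=True)
    if standardized is None:
        raise ValueError(
            f"Cannot fetch sequence data: {symbol!r} could not be standardized "
            f"to a known TR gene for species {species}."
        )
    record = reference.load_reference(species).records[standardized]
    if not record.sequences:
        raise NoMetadataError(
            f"No sequence data packaged for {standardized} ({species})."
        )
    return dict(record.sequences)
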