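"""Messy-symbol fixture generation for round-trip testing.

Canonical registry symbols are corrupted by deterministic, documented rules
that model the corruption classes seen in real repertoire exports: case
folding, legacy ``TCR`` prefixes, missing ``TR``/``HLA-`` prefixes,
appended qualifier text, S-notation subfamilies, unpadded allele
designations and ``A or B`` duplications.  Every generated
(messy, expected) pair is recoverable by the standardizers by construction,
which makes the generator the core regression suite: recovery must be 100%.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from tcrnorm import reference
from tcrnorm._core import validate_species

RULE_IDS = (
    "lowercase",
    "tcr_prefix",
    "drop_prefix",
    "add_qualifier",
    "s_notation",
    "allele_unpad",
    "or_duplicate",
)

_S_NOTATION_OK = re.compile(r"^TR[ABGD]V\d+(-\d+)?$")

__all__ = ["RULE_IDS", "MessyPair", "corrupt_symbol", "generate_pairs", "write_pairs_tsv"]


@dataclass(frozen=True)
class MessyPair:
    """A corrupted input with the standardized output it must map back to."""

    messy: str
    expected: str
    locus: str  # "TR" or "MH"
    rule_trace: Tuple[str, ...]


def _applicable(state: str, rule: str, locus: str) -> bool:
    has_space = " " in state
    if rule == "lowercase":
        return state.upper() != state.lower() and state != state.lower()
    if rule == "tcr_prefix":
        return locus == "TR" and state.startswith("TR") and not state.startswith("TCR")
    if rule == "drop_prefix":
        if has_space:
            return False
        if locus == "TR":
            return state.startswith("TR") and state[2:4] in (
                "AV", "AJ", "BV", "BD", "BJ", "GV", "GJ", "DV", "DD", "DJ",
            )
        return state.startswith("HLA-")
    if rule == "add_qualifier":
        return not has_space
    if rule == "s_notation":
        return locus == "TR" and _S_NOTATION_OK.match(state) is not None
    if rule == "allele_unpad":
        return locus == "TR" and not has_space and "*" not in state
    if rule == "or_duplicate":
        return not has_space
    return False


def corrupt_symbol(symbol: str, rule: str, locus: str = "TR") -> str:
    """Apply one deterministic corruption rule to a symbol.

    Raises ValueError if the rule is unknown or not applicable to the
    symbol/locus combination.  The output always differs from the input.
    """
    if rule not in RULE_IDS:
        raise ValueError(f"Unknown corruption rule {rule!r}: expected one of {RULE_IDS}.")
    if not _applicable(symbol, rule, locus):
        raise ValueError(f"Rule {rule!r} is not applicable to {symbol!r} (locus {locus}).")
    if rule == "lowercase":
        return symbol.lower()
    if rule == "tcr_prefix":
        return "TCR" + symbol[2:]
    if rule == "drop_prefix":
        return symbol[2:] if locus == "TR" else symbol[len("HLA-"):]
    if rule == "add_qualifier":
        return symbol + " MUTANT"
    if rule == "s_notation":
        m = re.match(r"^(TR[ABGD]V\d+)(?:-(\d+))?$", symbol)
        base, member = m.group(1), m.group(2) or "1"
        return f"{base}S{member}"
    if rule == "allele_unpad":
        return symbol + "*1"
    if rule == "or_duplicate":
        return f"{symbol} or {symbol}"
    raise AssertionError(rule)


def _corrupt_with_trace(
    symbol: str, locus: str, rng: random.Random, max_rules: int
) -> Optional[Tuple[str, Tuple[str, ...]]]:
    n_rules = rng.randint(1, max_rules)
    state = symbol
    trace: List[str] = []
    for _ in range(n_rules):
        options = [
            r for r in RULE_IDS if r not in trace and _applicable(state, r, locus)
        ]
        if not options:
            break
        rule = rng.choice(options)
        state = corrupt_symbol(state, rule, locus)
        trace.append(rule)
    if not trace:
        return None
    return state, tuple(trace)


def generate_pairs(
    species: str = "homosapiens",
    n: int = 100,
    seed: int = 0,
    loci: Sequence[str] = ("TR", "MH"),
) -> List[MessyPair]:
    """Generate ``n`` reproducible (messy, expected) pairs for a species.

    Symbols are sampled uniformly from the registry's canonical symbols of
    the requested loci; rule traces have length 1-3 and never combine
    mutually destructive rules (applicability is re-checked at every step).
    The same seed always yields the identical list.
    """
    validate_species(species)
    if n < 1:
        raise ValueError("n must be >= 1")
    registry = reference.load_reference(species)
    pool = [
        (sym, registry.records[sym].locus)
        for sym in registry.symbols()
        if registry.records[sym].locus in loci
    ]
    if not pool:
        raise ValueError(f"No registry symbols for loci {loci!r} ({species}).")
    rng = random.Random(seed)
    pairs: List[MessyPair] = []
    while len(pairs) < n:
        symbol, locus = pool[rng.randrange(len(pool))]
        result = _corrupt_with_trace(symbol, locus, rng, max_rules=3)
        if result is None:
            continue
        messy, trace = result
        expected = symbol
        if "allele_unpad" in trace:
            # default (allele) precision restores the catalogued designation
            expected = f"{symbol}*01"
        pairs.append(MessyPair(messy=messy, expected=expected, locus=locus, rule_trace=trace))
    return pairs


def write_pairs_tsv(pairs: Sequence[MessyPair], path) -> None:
    """Write pairs as a TSV usable as CLI test input (columns: value,
    expected, locus)."""
    with open(path, "w") as fh:
        fh.write("value\texpected\tlocus\n")
        for pair in pairs:
            fh.write(f"{pair.messy}\t{pair.expected}\t{pair.locus}\n")
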