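"""Validation/standardization of generic amino-acid sequences (epitopes).

A sequence is accepted iff, after trimming and upper-casing, every character
is one of the 20 standard amino-acid letters.  Ambiguity letters (B, J, O,
U, X, Z), gaps, digits and peptide-modification punctuation all fail.
"""

from __future__ import annotations

from typing import Optional

from tcrnorm._core import warn

STANDARD_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

__all__ = ["standardize", "STANDARD_AMINO_ACIDS"]


def standardize(raw, suppress_warnings: bool = False) -> Optional[str]:
    """Return the upper-cased sequence if it is a valid amino-acid string,
    else None with a diagnostic warning."""
    if not isinstance(raw, str):
        warn(
            f"Input {raw!r} was rejected as it is not a valid amino acid sequence.",
            suppress_warnings,
        )
        return None
    seq = raw.strip().upper()
    if not seq or not set(seq) <= STANDARD_AMINO_ACIDS:
        warn(
            f"Input {raw} was rejected as it is not a valid amino acid sequence.",
            suppress_warnings,
        )
        return None
    return seq
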