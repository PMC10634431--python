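"""Standardization of TR junction (CDR3) amino-acid sequences.

A full junction starts with the conserved cysteine (C) and ends with a
phenylalanine (F) or tryptophan (W).  Many sources instead store the CDR3
without these framing residues; by default a valid amino-acid sequence that
is not already framed is treated as a bare CDR3 and repaired by prepending
"C" and appending "F" (the terminal residue is assumed to be F — predicting
W from the J gene is out of scope).  In strict mode an unframed sequence
fails instead.
"""

from __future__ import annotations

from typing import Optional

from tcrnorm._core import warn
from tcrnorm.aa import STANDARD_AMINO_ACIDS

__all__ = ["standardize"]


def standardize(raw, strict: bool = False, suppress_warnings: bool = False) -> Optional[str]:
    """Standardize a junction sequence.

    Alphabet-invalid or empty input returns None with a warning.  A valid
    sequence already framed as C...F/W is returned unchanged.  Otherwise the
    missing framing residues are added (default) or, with ``strict=True``,
    the sequence is rejected.
    """
    if not isinstance(raw, str):
        warn(
            f"Input {raw!r} was rejected as it is not a valid junction sequence.",
            suppress_warnings,
        )
        return None
    seq = raw.strip().upper()
    if not seq or not set(seq) <= STANDARD_AMINO_ACIDS:
        warn(
            f"Input {raw} was rejected as it is not a valid junction sequence.",
            suppress_warnings,
        )
        return None
    framed = seq[0] == "C" and seq[-1] in "FW"
    if framed:
        return seq
    if strict:
        warn(
            f"Input {raw} was rejected as it is not a valid junction sequence.",
            suppress_warnings,
        )
        return None
    # repair is all-or-nothing: an unframed sequence is assumed to be a bare
    # CDR3, so both framing residues are (re)attached around it
    return "C" + seq + "F"
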