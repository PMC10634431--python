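"""Validate and repair junction (CDR3) and epitope amino-acid sequences.

A full junction is framed by the conserved cysteine and a terminal F/W.
Sources that store the bare CDR3 lack the framing residues; by default
they are re-attached (the terminal residue is assumed to be F).  Strict
mode rejects unframed sequences instead, and anything outside the
20-letter amino-acid alphabet always fails.
"""

import tcrnorm as tn

for raw in ("CSVNRDTGAGGYTF", "sadaf", "AASANSGTYQR", "IVRVSHN*G#RDNYGQNFV"):
    default = tn.junction.standardize(raw, suppress_warnings=True)
    strict = tn.junction.standardize(raw, strict=True, suppress_warnings=True)
    print(f"  junction {raw!r}: default -> {default!r}, strict -> {strict!r}")

for raw in ("VMAPRTLIL", "nlvpmvatv", "LLFGFPVYV + SCM(F5)"):
    print(f"  epitope {raw!r} -> {tn.aa.standardize(raw, suppress_warnings=True)!r}")
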