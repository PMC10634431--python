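"""Standardize messy TR and MH gene symbols to IMGT-compliant form.

Each input below is a real-world style corruption: missing locus prefixes,
legacy TCR/S-notation names, qualifier text, deprecated synonyms.  The
printed arrow shows the resolved IMGT symbol, or None when the value cannot
be resolved (such rows should be filtered from downstream analyses).
"""

import tcrnorm as tn

tr_cases = [
    ("aj1", "homosapiens"),
    ("TCRBV17S1", "homosapiens"),
    ("TCRBV5-1*01 or TCRBV5-1*02", "homosapiens"),
    ("TCRBV22S1A2N1T", "musmusculus"),
    ("TCRAJ1-3", "homosapiens"),  # nonexistent gene -> None
]
mh_cases = [
    ("DQB1*06:02", "homosapiens"),
    ("HLA-A*02:01 W167A mutant", "homosapiens"),
    ("CRW2", "musmusculus"),
    ("H2-Db", "musmusculus"),
    ("human MR1 K43A mutant", "homosapiens"),  # non-classical -> None
]

print("TR gene symbols:")
for raw, species in tr_cases:
    out = tn.tr.standardize(raw, species=species, suppress_warnings=True)
    print(f"  {raw!r} ({species}) -> {out!r}")

print("MH gene symbols:")
for raw, species in mh_cases:
    out = tn.mh.standardize(raw, species=species, suppress_warnings=True)
    print(f"  {raw!r} ({species}) -> {out!r}")

print("MH precision levels for 'HLA-A*01:01:01':")
for precision in ("allele", "protein", "gene"):
    out = tn.mh.standardize("HLA-A*01:01:01", precision=precision)
    print(f"  {precision}: {out}")

print("Classification: HLA-DQB1*06:02 is a class",
      tn.mh.get_class("HLA-DQB1*06:02"), tn.mh.get_chain("HLA-DQB1*06:02"), "chain gene")
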