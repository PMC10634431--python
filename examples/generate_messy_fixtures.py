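"""Generate seeded messy-symbol/expected pairs and verify total recovery.

The generator corrupts canonical registry symbols with documented rules
(case folding, legacy prefixes, S-notation, qualifier text, ...).  By
construction every pair is recoverable, so the recovery rate printed at
the end must be 100% — this is the package's core regression check.
"""

from tcrnorm import fixtures, mh, tr

for species in ("homosapiens", "musmusculus"):
    pairs = fixtures.generate_pairs(species, 1000, seed=42)
    recovered = 0
    for pair in pairs:
        standardize = tr.standardize if pair.locus == "TR" else mh.standardize
        if standardize(pair.messy, species=species, suppress_warnings=True) == pair.expected:
            recovered += 1
    print(f"{species}: {recovered}/{len(pairs)} recovered "
          f"({100.0 * recovered / len(pairs):.1f}%)")
    for pair in pairs[:5]:
        print(f"  {pair.messy!r} -> {pair.expected!r}   rules: {', '.join(pair.rule_trace)}")
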