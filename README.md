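# tcrnorm

Standardization of T cell receptor (TR) and Major Histocompatibility (MH)
gene nomenclature, and of junction/epitope amino-acid sequences.

## The problem

TR repertoire datasets describe each receptor chain by its V and J gene
(e.g. `TRBV6-4`, `TRAJ1`), the amino-acid sequence of the junction (CDR3)
region between them, and often the cognate peptide/MH.  In practice the
same gene appears under many names — deprecated symbols (`TCRBV17S1`),
missing locus prefixes (`aj1`, `DQB1*06:02`), serology-era qualifiers
(`HLA-A*02:01 W167A mutant`), mixed allele resolution (`TRAV1-1` vs
`TRAV1-1*01`) — which breaks any analysis that treats gene symbols as keys.
`tcrnorm` resolves such values to their IMGT-compliant form, or returns
`None` with a diagnostic when a value cannot be resolved, so invalid
records can be filtered out.

Supported species are *Homo sapiens* (`"homosapiens"`, the default) and
*Mus musculus* (`"musmusculus"`).  Resolution is driven by packaged
per-species registries of canonical genes, per-allele IMGT functionality
classes (F / ORF / P), and deprecated synonyms.

## Core operations

```python
>>> import tcrnorm as tn

# TR gene symbols: deterministic rewrites + registry lookup
>>> tn.tr.standardize("aj1")
'TRAJ1'
>>> tn.tr.standardize("TRBV6-4*01", precision="gene")
'TRBV6-4'
>>> tn.tr.standardize("TCRBV22S1A2N1T", species="musmusculus")
'TRBV2'
>>> tn.tr.standardize("TRBV1", enforce_functional=True)  # pseudogene
None

# MH symbols: HLA / mouse MH1-/MH2- nomenclature, H2 legacy names
>>> tn.mh.standardize("HLA-A*01:01:01", precision="protein")
'HLA-A*01:01'
>>> tn.mh.standardize("CRW2", species="musmusculus")
'MH1-M5'
>>> tn.mh.get_class("HLA-DQB1*06:02"), tn.mh.get_chain("HLA-DQB1*06:02")
(2, 'beta')

# junction (CDR3) framing: conserved C ... F/W
>>> tn.junction.standardize("sadaf")      # bare CDR3 -> framed junction
'CSADAFF'
>>> tn.junction.standardize("sadaf", strict=True)
None
>>> tn.aa.standardize("VMAPRTLIL")        # generic epitope validation
'VMAPRTLIL'
```

Gene-symbol standardization always returns either a symbol whose root is a
canonical registry entry (catalogued allele designations are kept,
`precision="gene"` drops them, MH `precision="protein"` keeps two
colon-fields) or `None` plus a `UserWarning` diagnostic.  Failures never
raise; only unknown species/precision keywords do.

Other utilities: `tn.tr.query` / `tn.mh.query` (catalogue queries with
functionality/substring filters), `tn.tr.get_aa_sequence` (per-feature
amino-acid sequences; the packaged sequence data is synthetic placeholder
data for the lookup machinery), `tn.fixtures.generate_pairs` (seeded
messy-symbol/expected pairs for regression testing), and
`tn.tabular.standardize_table` / `evaluate_export` for table cleaning.

## Command line

```bash
tcrnorm standardize-table --input rearr.tsv --output clean.tsv \
    --tr-col v_call --junction-col junction_aa --report report.json
tcrnorm evaluate --input values.tsv --kind tr --species homosapiens
```

`standardize-table` replaces the named columns with standardized values
(empty cell on failure) and reports per-kind success statistics over
unique raw values; `evaluate` measures the success rate over an export of
raw values.  A `--species-col` supplies per-row species labels
("Homo sapiens" / "Mus musculus" style); rows with missing labels default
to `--species`, unsupported labels count as failures.

## Worked example

Running `python examples/generate_messy_fixtures.py` corrupts 1,000
canonical symbols per species with documented rules and feeds them back
through the standardizers:

```
homosapiens: 1000/1000 recovered (100.0%)
  'trbv12-2' -> 'TRBV12-2'   rules: lowercase
  'TCRBV4-2 MUTANT' -> 'TRBV4-2'   rules: tcr_prefix, add_qualifier
  'traj2 or traj2' -> 'TRAJ2'   rules: lowercase, or_duplicate
musmusculus: 1000/1000 recovered (100.0%)
```

Every generated pair is recoverable by construction, so anything below
100% is a regression.  The other scripts in `examples/` walk through
symbol standardization, junction repair and table cleaning.

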