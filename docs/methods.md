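# Methods

## Scope and model

`tcrnorm` treats nomenclature standardization as deterministic resolution
against a curated registry: a value is valid exactly when its root resolves
to a canonical gene of the requested species, and every correction is a
fixed, ordered rewrite — there is no fuzzy matching, scoring or inference.
This makes outputs reproducible and auditable: the same input always maps
to the same symbol, and a failed input fails for a stated reason.

## Reference registries

One human-readable TSV per species per locus under
`src/tcrnorm/reference/data/` holds the canonical symbols, per-allele IMGT
functionality classes (F / ORF / P), optional chain (alpha/beta) and MH
class (1/2) metadata, and deprecated synonyms.  The registries were curated
by hand from the IMGT gene lists for the human and mouse TR loci (TRA, TRB,
TRG, TRD: 223 human, 190 mouse genes) and for the classical MH genes
(24 human HLA class I/II genes plus B2M; 37 mouse MH1-/MH2- genes plus
B2M).  Design choices in the curation:

* **B2M** is included in both species as a valid class I *beta*-chain
  record: it is the invariant light chain of every class I complex and
  appears as an MH value in real exports.
* **Non-classical MH** (MR1, CD1, MIC) are deliberately absent, so inputs
  naming them fail standardization rather than being silently accepted.
* **Mouse H2 legacy names**: the IMGT mouse nomenclature uses `MH1-`/`MH2-`
  prefixes; `H2-`/`H-2` inputs are rewritten by trying both prefixes on the
  remainder, and haplotype-qualified forms (`H2-Kb`, `H2-Db`, upper-cased to
  `H2-KB`, `H2-DB`) are synonyms of the haplotype-free gene.  The H2-D
  locus gene is curated class-consistently as **MH1-D1** (class I, alpha),
  with `H2-D`/`H2-Db`/`H2-Dd`/`H2-Dk` as synonyms.
* **Arden-style mouse V-beta names** (`TCRBV22S1A2N1T`): legacy subfamily
  numbers do not coincide with IMGT gene numbers, so these are synonyms
  (`TRBV22S1` → `TRBV2`, `TRBV8S1..3` → `TRBV13-3/-2/-1`).  Only legacy
  numbers without an IMGT gene of the same number are mapped this way, so a
  synonym can never shadow the S-notation rendering of a canonical gene.
* **Serology-style HLA abbreviations** ("A1", "DR4") are *not* mapped: they
  name allele groups rather than genes, and a faithful serology table is a
  separate curation effort.  Such inputs fail with a diagnostic.
* **Allele catalogues**: TR genes carry explicit allele lists (·01, often
  ·02) with per-allele functionality.  HLA allele catalogues are four
  orders of magnitude larger than the gene list and are not packaged; MH
  standardization therefore validates the root only and keeps the
  zero-padded fields as given.
* **TR amino-acid sequences** (`tr.get_aa_sequence`): the packaged
  per-gene CDR/FR sequences are explicitly synthetic placeholders (see the
  data file header) exercising the retrieval machinery; germline sequence
  curation is out of scope, and the file name and docstrings say so.

Registry files are schema-validated on load (unique symbols, two-digit
allele designations, no synonym equal to or shared between canonical
symbols); `reference.validate_records` is the entry point for contributors
adding records.

## TR resolution pipeline

For `tr.standardize(raw, species, precision, enforce_functional)`:

1. trim, upper-case; split on whitespace and use the **first token that
   resolves** (qualifier text like " mutant" or " or B" is discarded —
   greatest-common-factor handling of "A or B" is deliberately not
   attempted, so `TCRBV5-1*01 or TCRBV5-1*02` resolves to `TRBV5-1*01`);
2. split an allele designation at `*`, zero-padding digits to two;
3. resolve the root through an ordered, de-duplicated candidate list,
   looking each candidate up (canonical first, then synonyms):
   the raw root; `TCR`→`TR` prefix fix; `TR` prepended when the token
   starts with a locus letter pair (AV/AJ/BV/BD/BJ/GV/GJ/DV/DD/DJ);
   `TRAV` prepended to bare dual-gene fragments (`29/DV5`); legacy
   annotation suffixes stripped after an S-notation subfamily
   (`TRBV22S1A2N1T` → `TRBV22S1`); S-notation conversion
   `rootNSm` → `rootN-m`, with `rootS1` → `root` for single-member
   subfamilies;
4. if still unresolved, a **subgroup-member fallback**: a candidate
   resolves to the unique canonical symbol matching `root-1`, `root/...`
   or `root-1/...` (e.g. mouse `TRAV15` → `TRAV15-1/DV6-1`, human
   `TRAV14` → `TRAV14/DV4`); ambiguity or no match fails.  Bare digits or
   subfamily fragments without a locus letter (`1`, `12D-2`) can never
   reach a candidate and fail as carrying insufficient information;
5. an uncatalogued allele of a valid gene **degrades to gene-level output**
   with a diagnostic — failure is reserved for unresolvable roots;
6. `enforce_functional` rejects genes with no class-F allele, and rejects a
   named allele that is itself not class F;
7. `precision="gene"` drops the allele designation.

The candidate order is fixed and documented so outputs are reproducible;
the first hit wins.  On failure the function returns `None` and emits a
`UserWarning` naming the input, species and best attempted fix.  Warnings
can be silenced per call (`suppress_warnings=True`) or globally
(`tcrnorm.suppress_warnings(True)`); the CLI captures them and routes
failures through `logging`.

## MH resolution

Same token logic; allele fields are split at `*` and `:` and zero-padded.
Root resolution tries: direct lookup; for human, `HLA-` prepended; for
mouse, `MH1-`/`MH2-` substituted for an `H2-`/`H-2` prefix, then the
legacy-synonym table.  Roots naming a class or gene group (`HLA class II`,
`HLA-DQ`) are simply absent from the registry and fail.  Fields beyond the
fourth are discarded with a diagnostic; `precision="protein"` keeps two
fields (the protein-level identity most analyses use), `"gene"` none.
`get_chain`/`get_class` standardize first, then return registry metadata,
raising `ValueError` for unresolvable symbols and a distinct
`NoMetadataError` when a record lacks the annotation.

## Junction and epitope sequences

`aa.standardize` accepts a sequence iff, after trimming and upper-casing,
every character is one of the 20 standard amino-acid letters — ambiguity
codes (B/J/O/U/X/Z), `*`/`#`, digits and modification syntax all fail.
`junction.standardize` additionally requires the conserved framing
(first residue C, last F or W).  An unframed valid sequence is treated as
a bare CDR3 and repaired **all-or-nothing**: `C` is prepended *and* `F`
appended around the whole sequence (`sadaf` → `CSADAFF`) — the repair
never edits per-end, always assumes a terminal F rather than W, adds
exactly two residues and removes none.  `strict=True` rejects unframed
sequences instead.  The empty string always fails, so no output is ever
fabricated from nothing.  No length bound is imposed on epitopes.

## Fixture generator

`fixtures.generate_pairs` emulates the corruption classes seen in public
database exports: case folding, legacy `TCR` prefixes, dropped
`TR`/`HLA-` prefixes, appended qualifier tokens, S-notation subfamilies,
unpadded allele designations, and `A or A`-style duplications.  Rules are
deterministic string rewrites applied in seeded traces of length 1–3;
applicability is re-checked at every step so mutually destructive
combinations never occur, which makes every pair recoverable by
construction — the recovery suites therefore demand exactly 100%.

What the generator deliberately does **not** model: corruption classes the
standardizer is documented not to handle (ambiguity codes, peptide
modifications, non-classical MH, serology abbreviations), misspelled gene
numbers, and cross-species mislabels.  Passing the recovery suites
therefore demonstrates the resolution pipeline is self-consistent and
invertible over its documented scope; it does not bound the success rate
on an arbitrary real-world export, where unsupported value classes occur
at whatever rate the source database exhibits.  Those appear only as fixed
negative-case fixtures in the tests.

## Problem sizes and numerical choices

The test and acceptance runs use 1,000 generated pairs per species (the
point where every rule/locus combination is exercised many times over),
and the junction brute-force equivalence check enumerates all 406,900
strings of length ≤ 4 over a 25-character alphabet (20 valid residues plus
`B`, `X`, `Z`, `*`, `#`), comparing both strict and non-strict decisions
against an independently written character-level predicate.  There is no
floating-point numerics anywhere; determinism comes from fixed rule order,
sorted registry iteration and seeded `random.Random` instances only.

## Known limitations

* Gene-level registry completeness reflects the curated IMGT lists above;
  allele catalogues are exercised at the depth the tests need (TR ·01/·02)
  and HLA alleles are not validated at all.
* "A or B" inputs resolve to the first resolvable token, not the greatest
  common factor of A and B.
* Junction repair cannot know when the true terminal residue is W.
* Only human and mouse are supported; species is never inferred from the
  symbol shape.
* The subgroup-member fallback resolves a bare subgroup (`TRBV6`) to its
  member 1 when unique — convenient for legacy data, but a data source
  that intends the whole subgroup loses that distinction.
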