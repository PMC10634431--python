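"""Clean an AIRR rearrangement-style table and report success rates.

Builds a small TSV with v_call / junction_aa columns (plus a per-row
species column for the MH column), standardizes the columns in place, and
prints the per-kind report: unique raw values seen, how many standardized,
and examples of the failures.  Failed cells are written empty so they can
be filtered downstream.
"""

import tempfile
from pathlib import Path

import pandas as pd

from tcrnorm import tabular

workdir = Path(tempfile.mkdtemp())
table = workdir / "rearrangements.tsv"
pd.DataFrame(
    {
        "v_call": ["aj1", "TCRBV17S1", "TCRAJ1-3", "aj1"],
        "junction_aa": ["CASSLGQAYEQYF", "sadaf", "CASSF", "IVR*VSHN"],
        "mhc": ["DQB1*06:02", "CRW2", "B2M", "HLA-DQ"],
        "organism": ["Homo sapiens", "Mus musculus", "", "Homo sapiens"],
    }
).to_csv(table, sep="\t", index=False)

report = tabular.standardize_table(
    table,
    workdir / "clean.tsv",
    [
        tabular.ColumnSpec("v_call", "tr_gene"),
        tabular.ColumnSpec("junction_aa", "junction"),
        tabular.ColumnSpec("mhc", "mh_gene", species_column="organism"),
    ],
)
print("cleaned table:")
print((workdir / "clean.tsv").read_text())
print("report (per value kind, computed over unique raw values):")
print(report.to_json())
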