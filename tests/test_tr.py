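"""TR gene symbol standardization, query and sequence utilities."""

import pytest
from hypothesis import given, strategies as st

from tcrnorm import NoMetadataError, tr


@pytest.mark.parametrize(
    "raw,species,expected",
    [
        ("aj1", "homosapiens", "TRAJ1"),
        ("TRAJ1", "homosapiens", "TRAJ1"),
        ("TCRBV22S1A2N1T", "musmusculus", "TRBV2"),
        ("TCRBV17S1", "homosapiens", "TRBV17"),
        ("29/DV5*01", "homosapiens", "TRAV29/DV5*01"),
        ("TCRBV5-1*01 or TCRBV5-1*02", "homosapiens", "TRBV5-1*01"),
        ("TCRAV14D-3/DV8*02", "musmusculus", "TRAV14D-3/DV8*02"),
        ("TRAV15", "musmusculus", "TRAV15-1/DV6-1"),
        ("TRAV15", "homosapiens", "TRAV15"),
        ("trbv6-4*1", "homosapiens", "TRBV6-4*01"),
        ("TCRGV9", "homosapiens", "TRGV9"),
        ("DV3", "homosapiens", "TRDV3"),
    ],
)
def test_messy_symbols_resolve_to_imgt_form(raw, species, expected):
    assert tr.standardize(raw, species=species, suppress_warnings=True) == expected


@pytest.mark.parametrize(
    "raw,species",
    [
        ("TCRAJ1-3", "homosapiens"),
        ("TRBV14DV4", "homosapiens"),
        ("1", "musmusculus"),
        ("12D-2", "musmusculus"),
        ("TRVB13-1*02", "musmusculus"),
        ("", "homosapiens"),
        (None, "homosapiens"),
        (42, "homosapiens"),
    ],
)
def test_unresolvable_inputs_fail_with_a_warning(raw, species):
    with pytest.warns(UserWarning, match="Failed to standardize"):
        assert tr.standardize(raw, species=species) is None


def test_gene_precision_truncates_the_allele():
    assert tr.standardize("TRBV6-4*01", precision="gene", suppress_warnings=True) == "TRBV6-4"


def test_uncatalogued_allele_degrades_to_gene_level_with_diagnostic():
    with pytest.warns(UserWarning, match="not catalogued"):
        assert tr.standardize("TRBV6-4*99") == "TRBV6-4"


def test_enforce_functional_rejects_pseudogene():
    with pytest.warns(UserWarning, match="gene has no functional alleles"):
        assert tr.standardize("TRBV1", enforce_functional=True) is None


def test_enforce_functional_rejects_non_functional_allele():
    # TRBV17 is ORF-only: allele-level granularity must also fail
    with pytest.warns(UserWarning, match="not functional"):
        assert tr.standardize("TRBV17*01", enforce_functional=True) is None


def test_enforce_functional_keeps_functional_gene():
    assert tr.standardize("TRBV6-4", enforce_functional=True, suppress_warnings=True) == "TRBV6-4"


@pytest.mark.parametrize(
    "kwargs", [dict(species="homo"), dict(precision="proteins")]
)
def test_bad_keywords_raise(kwargs):
    with pytest.raises(ValueError):
        tr.standardize("TRAJ1", **kwargs)


def test_suppress_warnings_silences_diagnostics(recwarn):
    assert tr.standardize("TCRAJ1-3", suppress_warnings=True) is None
    assert len(recwarn) == 0


def test_global_warning_switch(recwarn):
    import tcrnorm

    tcrnorm.suppress_warnings(True)
    try:
        assert tr.standardize("TCRAJ1-3") is None
        assert len(recwarn) == 0
    finally:
        tcrnorm.suppress_warnings(False)
    with pytest.warns(UserWarning):
        tr.standardize("TCRAJ1-3")


class TestQuery:
    def test_contains_filter(self):
        result = tr.query("homosapiens", contains="TRAJ1")
        assert "TRAJ1" in result
        assert all("TRAJ1" in symbol for symbol in result)

    def test_functionality_filter_excludes_pseudogene(self):
        functional = tr.query("homosapiens", functionality={"F"})
        assert "TRBV1" not in functional
        assert "TRBV6-4" in functional

    def test_no_match_returns_empty_set(self, species):
        assert tr.query(species, contains="ZZZZ") == set()

    def test_allele_precision_renders_catalogued_alleles(self):
        alleles = tr.query("homosapiens", precision="allele", contains="TRBV6-4")
        assert alleles == {"TRBV6-4*01", "TRBV6-4*02"}

    def test_every_queried_symbol_is_a_standardization_fixed_point(self, species):
        for symbol in tr.query(species):
            assert tr.standardize(symbol, species=species, suppress_warnings=True) == symbol


class TestAaSequence:
    def test_round_trip_against_registry(self, human):
        stored = human.records["TRBV6-4"].sequences
        assert tr.get_aa_sequence("TRBV6-4") == dict(stored)
        assert stored  # the fixture gene actually carries data

    def test_messy_symbol_is_standardized_first(self):
        assert tr.get_aa_sequence("tcrbv6-4*01") == tr.get_aa_sequence("TRBV6-4")

    def test_unresolvable_symbol_raises_naming_the_input(self):
        with pytest.raises(ValueError, match="TCRAJ1-3"):
            tr.get_aa_sequence("TCRAJ1-3")

    def test_gene_without_sequence_data_raises_distinct_error(self):
        with pytest.raises(NoMetadataError, match="No sequence data"):
            tr.get_aa_sequence("TRAJ2")


@given(st.text(max_size=30))
def test_standardize_never_raises_on_arbitrary_text(text):
    result = tr.standardize(text, suppress_warnings=True)
    assert result is None or isinstance(result, str)
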