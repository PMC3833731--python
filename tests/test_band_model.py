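import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyo.band_model import (
    ArmSequence,
    Band,
    Karyotype,
    format_band_sequence,
    format_combination,
    karyotypes_to_tsv,
    make_reference,
    parse_band_label,
    parse_band_sequence,
    parse_combination,
    read_karyotype,
    read_registry,
    write_karyotype,
    write_registry,
)
from karyo.errors import BandParseError, ValidationError
from karyo.synthetic_data import evolve, generate_ancestor

from conftest import random_pair


class TestBand:
    def test_label_round_trip(self):
        for label in ("1", "17", "17b", "3ab"):
            assert parse_band_label(label).label == label

    def test_order_lexicographic(self):
        assert Band(17) < Band(17, "a") < Band(17, "b") < Band(18)

    @pytest.mark.parametrize("bad", ["", "b17", "17B", "-3", "17 b"])
    def test_malformed_label(self, bad):
        with pytest.raises(BandParseError):
            parse_band_label(bad)

    def test_major_must_be_positive(self):
        with pytest.raises(ValidationError):
            Band(0)


class TestParse:
    def test_four_interval_example(self, ref19):
        s = parse_band_sequence("1-7 15-12 8-11 16-19", "A", ref19, code="tstA1")
        assert len(s.intervals) == 4
        assert [iv.orientation for iv in s.intervals] == [
            "forward", "inverted", "forward", "forward",
        ]

    def test_identity(self, ref19):
        s = parse_band_sequence("1-19", "A", ref19, code="tstA1")
        assert len(s.intervals) == 1
        assert s.intervals[0].orientation == "forward"

    def test_subband_coverage_brute_force(self):
        ref = ["1a", "1b", "2a", "2b", "2c", "3", "4", "5a"]
        s = parse_band_sequence("1a-2c 4-3 5a", "G", ref, code="tstG1")
        assert len(s.intervals) == 3
        assert s.intervals[1].orientation == "inverted"
        # brute-force expansion of every interval to its band list
        expanded = []
        labels = [b.label for b in s.reference]
        for iv in s.intervals:
            i, j = labels.index(iv.start.label), labels.index(iv.end.label)
            run = labels[min(i, j) : max(i, j) + 1]
            expanded.extend(reversed(run) if iv.inverted else run)
        assert sorted(expanded) == sorted(labels)
        assert len(expanded) == 8

    def test_gap_reported_by_band(self, ref19):
        with pytest.raises(ValidationError, match="band 5 missing"):
            parse_band_sequence("1-4 6-19", "A", ref19)

    def test_overlap_reported_by_band(self, ref19):
        with pytest.raises(ValidationError, match="band 3 covered more than once"):
            parse_band_sequence("1-5 3 6-19", "A", ref19)

    def test_unknown_band(self, ref19):
        with pytest.raises(ValidationError, match="unknown band '77'"):
            parse_band_sequence("1-19 77", "A", ref19)

    @pytest.mark.parametrize("text", ["1--5", "1-2-3", "-5", "5-"])
    def test_malformed_token_has_position(self, text, ref19):
        with pytest.raises(BandParseError) as err:
            parse_band_sequence(text, "A", ref19)
        assert err.value.position == 0

    def test_code_arm_mismatch(self, ref19):
        with pytest.raises(ValidationError, match="names arm B"):
            parse_band_sequence("1-19", "A", ref19, code="xxxB1")


class TestFormat:
    def test_identity_formats_as_single_interval(self, ref19):
        s = parse_band_sequence("1-19", "A", ref19, code="tstA1")
        assert format_band_sequence(s) == "1-19"

    def test_single_inverted_block(self, ref19):
        s = parse_band_sequence("1-5 12-6 13-19", "A", ref19, code="tstA1")
        out = format_band_sequence(s)
        assert sum("-" in t and t.split("-") != sorted(t.split("-"), key=int) for t in out.split()) >= 1
        assert out == "1-5 12-6 13-19"

    def test_merges_adjacent_tokens(self, ref19):
        s = parse_band_sequence("1-7 8-19", "A", ref19, code="tstA1")
        assert format_band_sequence(s) == "1-19"

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10**6), k=st.integers(0, 6))
    def test_round_trip_property(self, seed, k):
        anc, der, _ = random_pair(seed, n_bands=14, k=k, subband_rate=0.2)
        for s in (anc, der):
            again = parse_band_sequence(s.formula, s.arm, s.reference, code=s.code)
            assert again.order == s.order

    def test_unmapped_has_no_formula(self, ref19):
        s = ArmSequence("tstA1", "A", ref19, ())
        assert s.formula is None
        with pytest.raises(ValidationError):
            format_band_sequence(s)


class TestCanonical:
    def test_flip_chooses_smaller_first_band(self, ref19):
        s = parse_band_sequence("19-1", "A", ref19, code="tstA1")
        assert s.canonical().order[0] == 1

    def test_canonical_idempotent(self):
        anc, der, _ = random_pair(7, k=4)
        assert der.canonical().canonical() == der.canonical()


class TestCombination:
    def test_parse_and_format(self):
        groups = parse_combination("AE CD BF G")
        assert groups == (("A", "E"), ("C", "D"), ("B", "F"), ("G",))
        assert format_combination(groups) == "AE CD BF G"

    def test_duplicate_arm_rejected(self):
        with pytest.raises(ValidationError, match="arm E appears in more than one group"):
            parse_combination("AE CD BE FG")

    def test_missing_arm_rejected(self):
        with pytest.raises(ValidationError, match="arm G missing"):
            parse_combination("AE CD BF")


class TestKaryotypeIO:
    def test_fixture_loads(self, by_species):
        k = by_species["Chironomus alluaudi"]
        assert k.haploid_n == 4
        assert format_combination(k.arm_combination) == "AE CD BF G"
        codes = {s.code for s in k.sequences()}
        assert codes == {"allA1", "allE1", "allC1", "allC2", "allD1", "allF1", "allG1", "allG2"}
        assert not k.pool["B"]  # unmapped monomorphic

    def test_round_trip_lossless(self, study, tmp_path):
        for k in study:
            p = tmp_path / "k.json"
            write_karyotype(k, p)
            k2 = read_karyotype(p)
            assert k2.species == k.species
            assert k2.arm_combination == k.arm_combination
            assert [s.order for s in k2.sequences()] == [s.order for s in k.sequences()]
            assert [s.annotations for s in k2.sequences()] == [
                s.annotations for s in k.sequences()
            ]

    def test_second_write_byte_identical(self, study, tmp_path):
        k = study[1]
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_karyotype(k, p1)
        write_karyotype(read_karyotype(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_arm_in_two_groups_fails(self, tmp_path):
        obj = {
            "species": "broken",
            "haploid_n": 4,
            "arm_combination": "AE CD BE FG",
            "arms": {},
        }
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(obj))
        with pytest.raises(ValidationError, match="arm E appears in more than one group"):
            read_karyotype(p)

    def test_all_violations_listed(self, tmp_path):
        obj = {
            "species": "broken",
            "haploid_n": 3,
            "arm_combination": "AE CD BF",  # missing G and wrong n
            "arms": {"A": [{"code": "xxxB1", "formula": None}]},
        }
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(obj))
        with pytest.raises(ValidationError) as err:
            read_karyotype(p)
        text = str(err.value)
        assert "arm G missing" in text
        assert "xxxB1" in text

    def test_wrong_haploid_n(self):
        with pytest.raises(ValidationError, match="haploid_n=3 but combination has 4"):
            Karyotype("x", 3, parse_combination("AE CD BF G"))

    def test_tsv_export(self, study):
        tsv = karyotypes_to_tsv(study)
        lines = tsv.strip().split("\n")
        assert lines[0].startswith("species\t")
        # one row per sequence plus one per empty arm
        n_rows = sum(
            max(1, len(k.pool.get(a, []))) for k in study for a in "ABCDEFG"
        )
        assert len(lines) == 1 + n_rows


class TestRegistryIO:
    def test_round_trip(self, registry, tmp_path):
        p = tmp_path / "basic.json"
        write_registry(registry, p)
        reg2 = read_registry(p)
        assert [e.name for e in reg2.entries] == [e.name for e in registry.entries]
        assert reg2.get("lonC1").sequence.order == registry.get("lonC1").sequence.order

    def test_duplicate_names_rejected(self, registry):
        from karyo.band_model import BasicRegistry

        with pytest.raises(ValidationError, match="duplicate registry name"):
            BasicRegistry(registry.entries + [registry.entries[0]])

    def test_scope_validated(self, registry):
        from karyo.band_model import RegistryEntry

        e = registry.entries[0]
        with pytest.raises(ValidationError, match="unknown registry scope"):
            RegistryEntry(e.name, e.arm, e.sequence, "weird")


def test_reference_order_must_be_sorted():
    with pytest.raises(ValidationError, match="violates"):
        make_reference(["2", "1", "3"])
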