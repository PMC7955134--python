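"""Genotype nomenclature, dataset reading/writing and validation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epideconv import (
    DatasetError,
    DeconvolutionDataset,
    EpistasisResult,
    GenotypeFormatError,
    Genotype,
    Measurement,
    analyze_all,
    format_genotype,
    parse_genotype,
    read_dataset,
    validate_dataset,
    write_dataset,
    write_results,
)
from epideconv.epistasis import CombinationSplit
from epideconv.io import epistasis_markdown

from conftest import SITES3, make_dataset


class TestGenotypeNomenclature:
    @pytest.mark.parametrize(
        "label, expected",
        [
            ("---", (False, False, False)),
            ("III", (True, True, True)),
            ("-I-", (False, True, False)),
            ("I-I", (True, False, True)),
        ],
    )
    def test_parse_presence(self, label, expected):
        assert parse_genotype(label, SITES3).present == expected

    def test_wrong_length_rejected(self):
        with pytest.raises(GenotypeFormatError):
            parse_genotype("II", SITES3)

    def test_strict_rejects_foreign_mark(self):
        # lenient mode accepts any non-dash mark; strict wants the residue letter
        assert parse_genotype("A--", SITES3).present == (True, False, False)
        with pytest.raises(GenotypeFormatError):
            parse_genotype("A--", SITES3, strict=True)

    @settings(derandomize=True, max_examples=200)
    @given(n=st.integers(1, 6), mask=st.integers(0, 63))
    def test_parse_format_roundtrip(self, n, mask):
        sites = tuple(f"X{i}I" for i in range(n))
        genotype = Genotype.from_indices(sites, {i for i in range(n) if mask >> i & 1})
        assert parse_genotype(format_genotype(genotype), sites) == genotype


class TestMeasurement:
    def test_sem_from_two_replicates(self):
        m = Measurement.from_replicates(
            Genotype.from_indices(SITES3, {0, 1, 2}), "ttf", [157.0, 159.0]
        )
        assert m.mean == 158.0 and m.n == 2
        # sd = sqrt(2), sem = sd/sqrt(2) = |r1-r2|/2
        assert m.sem == pytest.approx(1.0)

    def test_negative_sem_rejected(self):
        with pytest.raises(ValueError):
            Measurement(Genotype.from_indices(SITES3, set()), "f", 1.0, -0.1, 2)


class TestReadDataset:
    def _write(self, tmp_path, text, name="data.csv"):
        path = tmp_path / name
        path.write_text(text, encoding="utf-8")
        return path

    def test_replicate_rows_aggregate(self, tmp_path):
        path = self._write(
            tmp_path,
            "genotype,trait,value\n---,ttf,10\n---,ttf,12\nIII,ttf,157\nIII,ttf,159\n",
        )
        ds = read_dataset(path, sites=SITES3)
        m = ds.get("III", "ttf")
        assert m.mean == 158.0 and m.n == 2 and m.sem == pytest.approx(1.0)

    def test_complete_flag_by_enumeration(self, bm3):
        # 8 genotypes x 7 traits, n=2 everywhere: complete for n=3 sites
        assert bm3.is_complete()
        assert len(bm3.all_genotypes()) == 2**3

    def test_missing_genotype_listed(self, tmp_path):
        rows = ["genotype,trait,mean,sem,n"]
        for label in ["---", "I--", "-I-", "--I", "II-", "-II", "III"]:  # no I-I
            rows.append(f"{label},ttf,1.0,0.1,2")
        ds = read_dataset(self._write(tmp_path, "\n".join(rows) + "\n"), sites=SITES3)
        assert not ds.is_complete("ttf")
        assert ds.missing("ttf") == ["I-I"]

    def test_non_numeric_value_names_line(self, tmp_path):
        path = self._write(
            tmp_path, "genotype,trait,value\n---,ttf,10\nIII,ttf,oops\n"
        )
        with pytest.raises(DatasetError, match=r":3:.*oops"):
            read_dataset(path, sites=SITES3)

    def test_missing_parent_rejected(self, tmp_path):
        path = self._write(tmp_path, "genotype,trait,value\nIII,ttf,158\n")
        with pytest.raises(DatasetError, match="parent"):
            read_dataset(path, sites=SITES3)

    def test_tsv_dialect(self, tmp_path):
        path = self._write(
            tmp_path, "genotype\ttrait\tvalue\n---\tttf\t10\nIII\tttf\t158\n", "d.tsv"
        )
        assert read_dataset(path, sites=SITES3).value("III", "ttf") == 158.0

    def test_write_read_roundtrip_bit_for_bit(self, tmp_path, bm3):
        path = tmp_path / "out.csv"
        write_dataset(bm3, path)
        back = read_dataset(path, sites=bm3.sites)
        for m in bm3.measurements():
            m2 = back.get(m.genotype.label, m.trait)
            assert m2.mean == m.mean and m2.sem == m.sem and m2.n == m.n


class TestValidation:
    def test_complete_fixture_summary(self, bm3):
        report = validate_dataset(bm3)
        assert report.ok and report.complete
        assert report.summary().startswith("complete, 8 genotypes, 7 traits")
        assert report.warnings == []  # pfr == ncr*ce by construction

    def test_pfr_inconsistency_names_genotype(self, bm3):
        ds = make_dataset({"---": 100.0, "III": 100.0}, trait="ncr")
        for label, value in {"---": 20.0, "III": 50.0}.items():
            g = ds.genotype_from_indices({i for i, c in enumerate(label) if c != "-"})
            ds.add(Measurement(g, "ce", value, 0.0, 2))
            ds.add(Measurement(g, "pfr", 20.0 if label == "---" else 10.0, 0.0, 2))
        report = validate_dataset(ds)
        assert any("III" in w and "PFR" in w for w in report.warnings)

    def test_empty_dataset_is_an_error(self):
        report = validate_dataset(DeconvolutionDataset(sites=SITES3))
        assert not report.ok and "no measurements" in report.errors


class TestWriteResults:
    def test_markdown_cells_mirror_table_style(self, tmp_path, bm3):
        table = analyze_all(bm3, traits=["ddg"])
        path = tmp_path / "t.md"
        write_results(table, path, "markdown", trait_definitions=bm3.traits)
        text = path.read_text()
        assert "+SE 9.1" in text  # tertiary selectivity cell (epsilon = 9.05)
        assert "| I-- + -I- + --I |" in text

    def test_additive_cell_formatting(self):
        split = CombinationSplit((frozenset({0}), frozenset({2})))
        result = EpistasisResult(
            split=split, trait="pfr", combination="I-- + --I -> I-I",
            resulting_genotype="I-I", w_parts=(0.1, 0.2), sem_w_parts=(0.1, 0.1),
            w_combined=0.1, sem_w_combined=0.1, expected=10.2, sem_expected=0.2,
            observed=10.0, sem_observed=0.1, epsilon=-0.2, sem_epsilon=0.3,
            label="ADD",
        )
        assert result.cell(1) == "ADD -0.2"

    def test_empty_results_header_only(self, tmp_path, bm3):
        table = analyze_all(bm3, traits=["ddg"])
        table.results = []
        path = tmp_path / "empty.csv"
        write_results(table, path, "csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("type,combination")

    def test_json_carries_full_precision(self, tmp_path, bm3):
        import json

        table = analyze_all(bm3, traits=["ddg"])
        path = tmp_path / "t.json"
        write_results(table, path, "json")
        payload = json.loads(path.read_text())
        tertiary = [r for r in payload["results"] if r["type"] == "T"][0]
        assert math.isclose(tertiary["epsilon"], 9.05)
        assert len(tertiary["w_parts"]) == 3
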