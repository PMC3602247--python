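"""Exports: genotype lists, merged CSV/XLSX, highlighting, PED/MAP."""

import csv

import openpyxl
import pandas as pd
import pytest

from snpqc.errors import EmptySelectionError
from snpqc.pop_compare import Harmonization, PopulationComparison
from snpqc.qc_stats import GenotypeCounts, QCReport
from snpqc.report_export import (
    HighlightRule,
    apply_highlight_rules,
    export_genotype_list,
    export_merged,
    export_ped_map,
    export_population_comparisons,
    read_genotype_matrix_csv,
)
from snpqc.sex_check import load_sex_phenotypes
from snpqc.study import create_study


@pytest.fixture()
def matrix():
    frame = pd.DataFrame(
        {"rs1": ["A/G", "A/A", "0/0"], "rs2": ["C/C", "C/T", "T/T"]},
        index=["S1", "S2", "S3"], dtype=object,
    )
    frame.index.name = "sample_id"
    return frame


def _report(snp, **overrides):
    base = dict(snp_id=snp, creation_date="2024-01-01T00:00:00", operator="op",
                comment="", call_rate=0.99, expected_replicates=2,
                real_replicates=2, discordant_replicates=0, discordance_rate=0.0,
                maf=0.25, minor_allele="G", hwe_chi2=0.5, hwe_p=0.48)
    base.update(overrides)
    return QCReport(**base)


class TestHighlighting:
    def test_paper_style_hwe_rule(self):
        assert apply_highlight_rules(_report("rs1", hwe_p=0.01)) == {"hwe_p"}

    def test_undefined_never_flagged(self):
        assert apply_highlight_rules(_report("rs1", hwe_p=None)) == set()

    def test_all_passing(self):
        assert apply_highlight_rules(_report("rs1")) == set()

    def test_custom_rule(self):
        rules = [HighlightRule("maf", "<", 0.3)]
        assert apply_highlight_rules(_report("rs1"), rules) == {"maf"}


class TestGenotypeList:
    def test_csv_contains_all_samples(self, matrix, tmp_path):
        path = export_genotype_list("rs1", matrix, tmp_path / "rs1.csv")
        rows = list(csv.reader(path.open()))
        assert rows[0] == ["sample_id", "rs1"]
        assert rows[1:] == [["S1", "A/G"], ["S2", "A/A"], ["S3", "0/0"]]

    def test_xlsx_cells_are_text_typed(self, matrix, tmp_path):
        path = export_genotype_list("rs1", matrix, tmp_path / "rs1.xlsx", fmt="xlsx")
        ws = openpyxl.load_workbook(path).active
        assert ws.cell(row=2, column=2).number_format == "@"
        assert ws.cell(row=2, column=2).value == "A/G"


class TestMergedExport:
    def test_csv_pair_and_roundtrip(self, matrix, tmp_path):
        study = create_study("s", list(matrix.index))
        reports = {s: _report(s) for s in matrix.columns}
        paths = export_merged(study, list(matrix.columns), matrix, reports,
                              tmp_path / "merged")
        reimported = read_genotype_matrix_csv(paths["genotypes"])
        pd.testing.assert_frame_equal(reimported, matrix)

    def test_undefined_serialized_as_na(self, matrix, tmp_path):
        study = create_study("s", list(matrix.index))
        reports = {s: _report(s, hwe_p=None, discordance_rate=None)
                   for s in matrix.columns}
        paths = export_merged(study, ["rs1"], matrix, reports, tmp_path / "m")
        header, row = list(csv.reader(paths["qc"].open()))[:2]
        record = dict(zip(header, row))
        assert record["hwe_p"] == "NA" and record["discordance_rate"] == "NA"

    def test_csv_and_xlsx_agree_cell_for_cell(self, matrix, tmp_path):
        study = create_study("s", list(matrix.index))
        reports = {s: _report(s, hwe_p=0.01) for s in matrix.columns}
        selection = list(matrix.columns)
        csv_paths = export_merged(study, selection, matrix, reports, tmp_path / "m")
        xlsx_paths = export_merged(study, selection, matrix, reports,
                                   tmp_path / "m.xlsx", fmt="xlsx")
        wb = openpyxl.load_workbook(xlsx_paths["workbook"])
        csv_rows = list(csv.reader(csv_paths["genotypes"].open()))
        xlsx_rows = [["" if c.value is None else str(c.value) for c in row] for row in wb["Genotypes"].iter_rows()]
        assert csv_rows == xlsx_rows
        qc_csv = [r[:-1] for r in csv.reader(csv_paths["qc"].open())]  # drop flags col
        qc_xlsx = [["" if c.value is None else str(c.value) for c in row] for row in wb["QC"].iter_rows()]
        assert qc_csv == qc_xlsx

    def test_empty_selection_rejected(self, matrix, tmp_path):
        study = create_study("s", list(matrix.index))
        with pytest.raises(EmptySelectionError):
            export_merged(study, [], matrix, {}, tmp_path / "m")


class TestPopulationExport:
    def _comparisons(self):
        user = GenotypeCounts(40, 40, 10, "A", "G")
        ref = GenotypeCounts(35, 45, 10, "A", "G")
        ok = PopulationComparison("CEU", "HAPMAP", Harmonization.DIRECT, user, ref,
                                  chi2=0.6, df=2, p=0.74)
        bad = PopulationComparison("YRI", "HAPMAP", Harmonization.INCOMPATIBLE,
                                   user, ref)
        return [ok, bad]

    def test_selection_filters_rows(self, tmp_path):
        path = export_population_comparisons(self._comparisons(), ["CEU"],
                                             tmp_path / "pop.csv")
        rows = list(csv.reader(path.open()))
        assert len(rows) == 2 and rows[1][0] == "CEU"

    def test_empty_selection_exports_all(self, tmp_path):
        path = export_population_comparisons(self._comparisons(), None,
                                             tmp_path / "pop.csv")
        assert len(list(csv.reader(path.open()))) == 3

    def test_incompatible_row_has_na_test_fields(self, tmp_path):
        path = export_population_comparisons(self._comparisons(), ["YRI"],
                                             tmp_path / "pop.csv")
        header, row = list(csv.reader(path.open()))
        record = dict(zip(header, row))
        assert record["harmonization"] == "incompatible"
        assert record["chi2"] == "NA" and record["p"] == "NA"


class TestPedMap:
    def test_field_arithmetic(self, matrix, tmp_path):
        ped, map_ = export_ped_map(matrix, {"rs1": (8, 19905), "rs2": (1, 100)},
                                   tmp_path / "out")
        ped_rows = [line.split() for line in ped.read_text().splitlines()]
        assert all(len(row) == 6 + 2 * 2 for row in ped_rows)
        map_rows = [line.split() for line in map_.read_text().splitlines()]
        assert len(map_rows) == 2
        assert map_rows[0] == ["8", "rs1", "0", "19905"]

    def test_missing_genotype_encoded_0_0(self, matrix, tmp_path):
        ped, _ = export_ped_map(matrix, None, tmp_path / "out")
        s3 = [line for line in ped.read_text().splitlines()
              if line.startswith("S3")][0].split()
        assert s3[6:8] == ["0", "0"]

    def test_sex_column_from_phenotypes(self, matrix, tmp_path):
        import io

        phen = load_sex_phenotypes(io.StringIO("S1\tm\nS2\tf\n"),
                                   {"m": "male", "f": "female"})
        ped, _ = export_ped_map(matrix, None, tmp_path / "out", sex_phenotypes=phen)
        rows = {line.split()[0]: line.split() for line in ped.read_text().splitlines()}
        assert rows["S1"][4] == "1" and rows["S2"][4] == "2" and rows["S3"][4] == "0"
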