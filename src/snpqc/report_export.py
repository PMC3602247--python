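"""Export of genotype lists, QC reports, population comparisons and PED/MAP.

Exports come as CSV (RFC-4180) or XLSX. Spreadsheet cells are written as
text-typed to prevent the classic auto-conversion accidents (genotypes or
identifiers reinterpreted as dates or numbers). Undefined statistics are
exported as the literal "NA", never blank and never 0.

QC values crossing configurable thresholds are highlighted: a fill style
in XLSX, an adjacent flag column in CSV. The default rules flag HWE
p < 0.05, call rate < 0.95 and any non-zero discordance rate.
"""

from __future__ import annotations

import csv
import operator as _op
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import EmptySelectionError, FormatError
from .genotype_core import Genotype
from .pop_compare import PopulationComparison
from .qc_stats import QCReport
from .sex_check import Sex, SexPhenotypes
from .study import StudyDefinition

__all__ = [
    "NA",
    "HighlightRule",
    "DEFAULT_HIGHLIGHT_RULES",
    "apply_highlight_rules",
    "export_genotype_list",
    "export_merged",
    "export_population_comparisons",
    "export_ped_map",
    "read_genotype_matrix_csv",
]

NA = "NA"

_COMPARATORS = {
    "<": _op.lt, "<=": _op.le, ">": _op.gt, ">=": _op.ge, "==": _op.eq, "!=": _op.ne,
}


@dataclass(frozen=True)
class HighlightRule:
    field: str
    comparator: str
    threshold: float

    def applies(self, value) -> bool:
        if value is None:
            return False  # undefined values are never highlighted
        return _COMPARATORS[self.comparator](value, self.threshold)


DEFAULT_HIGHLIGHT_RULES = (
    HighlightRule("hwe_p", "<", 0.05),
    HighlightRule("call_rate", "<", 0.95),
    HighlightRule("discordance_rate", ">", 0),
)


def apply_highlight_rules(
    report: QCReport, rules: Sequence[HighlightRule] = DEFAULT_HIGHLIGHT_RULES
) -> set[str]:
    """Names of the QC fields whose defined values trip a rule."""
    flagged: set[str] = set()
    for rule in rules:
        if rule.applies(getattr(report, rule.field, None)):
            flagged.add(rule.field)
    return flagged


def _fmt(value) -> str:
    if value is None:
        return NA
    if isinstance(value, float):
        return format(value, ".10g")
    return str(value)


# ---------------------------------------------------------------------------
# low-level writers


def _write_csv(path: Path, header: Sequence[str], rows: Sequence[Sequence[str]]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


_HIGHLIGHT_FILL = None  # built lazily; openpyxl import cost


def _xlsx_workbook():
    import openpyxl
    from openpyxl.styles import PatternFill

    global _HIGHLIGHT_FILL
    if _HIGHLIGHT_FILL is None:
        _HIGHLIGHT_FILL = PatternFill("solid", fgColor="FFC7CE")
    wb = openpyxl.Workbook()
    wb.remove(wb.active)
    return wb


def _xlsx_sheet(workbook, title: str, header: Sequence[str],
                rows: Sequence[Sequence[str]],
                highlights: Optional[Sequence[set[int]]] = None) -> None:
    ws = workbook.create_sheet(title=title)
    ws.append(list(header))
    for r, row in enumerate(rows):
        for c, value in enumerate(row, start=1):
            cell = ws.cell(row=r + 2, column=c, value=str(value))
            cell.number_format = "@"  # text-typed: no date/number auto-conversion
            if highlights and c - 1 in highlights[r]:
                cell.fill = _HIGHLIGHT_FILL


# ---------------------------------------------------------------------------
# genotype lists


def export_genotype_list(
    snp_id: str,
    matrix: pd.DataFrame,
    path: Union[str, Path],
    fmt: str = "csv",
) -> Path:
    """Write one SNP's genotype list (sample_id, genotype) for all samples."""
    path = Path(path)
    header = ["sample_id", snp_id]
    rows = [[sample, matrix.at[sample, snp_id]] for sample in matrix.index]
    if fmt == "csv":
        _write_csv(path, header, rows)
    elif fmt == "xlsx":
        wb = _xlsx_workbook()
        _xlsx_sheet(wb, snp_id[:31] or "genotypes", header, rows)
        wb.save(path)
    else:
        raise FormatError(f"unsupported export format {fmt!r}")
    return path


_QC_COLUMNS = ["snp_id", "creation_date", "operator", "comment", *QCReport.STAT_FIELDS]


def _qc_rows(reports: Sequence[QCReport], rules: Sequence[HighlightRule]):
    rows, flag_cols, highlight_idx = [], [], []
    for report in reports:
        flagged = apply_highlight_rules(report, rules)
        row = [_fmt(getattr(report, col)) for col in _QC_COLUMNS]
        rows.append(row)
        flag_cols.append(";".join(sorted(flagged)))
        highlight_idx.append({_QC_COLUMNS.index(f) for f in flagged})
    return rows, flag_cols, highlight_idx


def export_merged(
    study: StudyDefinition,
    snp_selection: Sequence[str],
    matrix: pd.DataFrame,
    reports: Mapping[str, QCReport],
    path: Union[str, Path],
    fmt: str = "csv",
    rules: Sequence[HighlightRule] = DEFAULT_HIGHLIGHT_RULES,
) -> dict[str, Path]:
    """Write the merged genotype list and merged QC report for selected SNPs.

    CSV output is a file pair (``<path>_genotypes.csv``/``<path>_qc.csv``);
    XLSX output is one workbook with "Genotypes" and "QC" sheets. The QC
    table carries one row per SNP and a flags column naming highlighted
    fields.
    """
    if not snp_selection:
        raise EmptySelectionError("no SNPs selected for merged export")
    unknown = [s for s in snp_selection if s not in matrix.columns]
    if unknown:
        raise EmptySelectionError(f"selected SNPs not in matrix: {unknown}")
    path = Path(path)

    geno_header = ["sample_id", *snp_selection]
    geno_rows = [[sample, *[matrix.at[sample, snp] for snp in snp_selection]]
                 for sample in matrix.index]
    selected_reports = [reports[snp] for snp in snp_selection]
    qc_rows, flag_cols, highlight_idx = _qc_rows(selected_reports, rules)

    if fmt == "csv":
        geno_path = path.with_name(path.name + "_genotypes.csv")
        qc_path = path.with_name(path.name + "_qc.csv")
        _write_csv(geno_path, geno_header, geno_rows)
        _write_csv(qc_path, _QC_COLUMNS + ["flags"],
                   [row + [flags] for row, flags in zip(qc_rows, flag_cols)])
        return {"genotypes": geno_path, "qc": qc_path}
    if fmt == "xlsx":
        out = path if path.suffix == ".xlsx" else path.with_suffix(".xlsx")
        wb = _xlsx_workbook()
        _xlsx_sheet(wb, "Genotypes", geno_header, geno_rows)
        _xlsx_sheet(wb, "QC", _QC_COLUMNS, qc_rows, highlights=highlight_idx)
        wb.save(out)
        return {"workbook": out}
    raise FormatError(f"unsupported export format {fmt!r}")


def read_genotype_matrix_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Re-import a merged genotype CSV into a sample × SNP matrix."""
    frame = pd.read_csv(path, dtype=str).set_index("sample_id")
    frame.index.name = "sample_id"
    return frame.astype(object)


# ---------------------------------------------------------------------------
# population comparisons


def export_population_comparisons(
    comparisons: Sequence[PopulationComparison],
    selected_populations: Optional[Sequence[str]],
    path: Union[str, Path],
) -> Path:
    """Write one row per selected population (empty selection = all).

    Each row reports genotype frequencies and absolute numbers for both
    sources, the chi-square test, and the allele-harmonisation outcome;
    incompatible populations carry "NA" test fields.
    """
    path = Path(path)
    wanted = set(selected_populations) if selected_populations else None
    header = [
        "population", "source", "harmonization",
        "user_n_AA", "user_n_AB", "user_n_BB",
        "user_f_AA", "user_f_AB", "user_f_BB",
        "ref_n_AA", "ref_n_AB", "ref_n_BB",
        "ref_f_AA", "ref_f_AB", "ref_f_BB",
        "chi2", "df", "p", "small_count_warning",
    ]
    rows = []
    for comp in comparisons:
        if wanted is not None and comp.population not in wanted:
            continue
        def freqs(counts):
            n = counts.n_called
            if n == 0:
                return [NA, NA, NA]
            return [_fmt(c / n) for c in counts.as_triple()]
        rows.append([
            comp.population, comp.source, comp.harmonization.value,
            *[_fmt(c) for c in comp.user_counts.as_triple()],
            *freqs(comp.user_counts),
            *[_fmt(c) for c in comp.ref_counts.as_triple()],
            *freqs(comp.ref_counts),
            _fmt(comp.chi2), _fmt(comp.df if comp.chi2 is not None else None),
            _fmt(comp.p), str(comp.small_count_warning).lower(),
        ])
    _write_csv(path, header, rows)
    return path


# ---------------------------------------------------------------------------
# PED/MAP


_PED_SEX = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}


def export_ped_map(
    matrix: pd.DataFrame,
    snp_meta: Optional[Mapping[str, tuple]] = None,
    path_prefix: Union[str, Path] = "export",
    sex_phenotypes: Optional[SexPhenotypes] = None,
) -> tuple[Path, Path]:
    """Write PLINK text PED/MAP files for the genotype matrix.

    PED rows: family and individual ID both set to the sample ID, founders
    (father = mother = 0), sex from the phenotype file when supplied (1 =
    male, 2 = female, else 0), phenotype -9, then one space-separated
    allele pair per SNP with "0 0" for missing. MAP rows: chromosome,
    snp_id, genetic distance 0, position — chromosome/position default to
    0 when no metadata is given.
    """
    prefix = Path(path_prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    snps = list(matrix.columns)

    with open(map_path, "w", encoding="utf-8") as fh:
        for snp in snps:
            chrom, pos = (snp_meta or {}).get(snp, (0, 0))
            fh.write(f"{chrom}\t{snp}\t0\t{pos}\n")

    with open(ped_path, "w", encoding="utf-8") as fh:
        for sample in matrix.index:
            sex_code = "0"
            if sex_phenotypes is not None:
                sex = sex_phenotypes.sex_of(sample)
                if sex is not None:
                    sex_code = _PED_SEX[sex]
            fields = [str(sample), str(sample), "0", "0", sex_code, "-9"]
            for snp in snps:
                g = Genotype.from_string(matrix.at[sample, snp])
                fields.extend(["0", "0"] if g.is_missing else list(g.alleles))
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path
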