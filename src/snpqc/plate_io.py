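"""Reading and merging plate-level genotyping exports.

Two delimiter-separated dialects are supported, modelled on the exports of
endpoint allelic-discrimination software (``SDS``: one file per plate, one
row per well and marker, calls encoded as per-allele detector names, "Both"
or "Undetermined") and of multiplexed mass-spectrometry typing software
(``TYPER``: one file spanning plates and assays, genotypes written as plain
base strings such as "AG"). Files may arrive singly or many-per-zip; a whole
study spans several 384-well microplates.

Raw call tokens are stored verbatim at this layer — normalisation to
genotypes happens later, behind an explicit user-approved conversion map.
"""

from __future__ import annotations

import csv
import io
import re
import zipfile
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

from .errors import (
    DuplicateWellError,
    EmptyInputError,
    FormatError,
    MixedFormatError,
    ParseError,
)

__all__ = [
    "Dialect",
    "WellAddress",
    "RawCall",
    "PlateResult",
    "DetectorDesignation",
    "sniff_format",
    "read_sds_export",
    "read_typer_export",
    "read_archive",
    "read_plate_file",
    "read_input",
    "parse_detector_designation",
]


class Dialect(str, Enum):
    SDS = "SDS"
    TYPER = "TYPER"


_PLATE_ROWS = "ABCDEFGHIJKLMNOP"  # 16 rows x 24 columns = 384 wells
_PLATE_COLUMNS = 24
_WELL_RE = re.compile(r"([A-Pa-p])0*(\d{1,2})")

# Header columns that identify each dialect.
_SDS_COLUMNS = ("Well", "Sample Name", "Marker", "Call")
_TYPER_COLUMNS = ("Plate", "Well", "Sample Id", "Assay Id", "Genotype")


@dataclass(frozen=True, order=True)
class WellAddress:
    """One well of a 384-well microplate (rows A–P, columns 1–24)."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in _PLATE_ROWS:
            raise ParseError(f"well row {self.row!r} outside A-P")
        if not 1 <= self.column <= _PLATE_COLUMNS:
            raise ParseError(f"well column {self.column} outside 1-24")

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        """Parse "A1" or zero-padded "A01" into a canonical address."""
        m = _WELL_RE.fullmatch(text.strip())
        if m is None:
            raise ParseError(f"malformed well address {text!r}")
        return cls(m.group(1).upper(), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.row}{self.column}"


@dataclass(frozen=True)
class RawCall:
    """One well-level raw call, token kept verbatim."""

    well: WellAddress
    sample_id: str
    assay_id: str
    call_token: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ParseError("empty sample id")
        if not self.assay_id:
            raise ParseError("empty assay id")


@dataclass
class PlateResult:
    """All raw calls of one plate file, tagged with its source dialect."""

    plate_name: str
    dialect: Dialect
    calls: list[RawCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[WellAddress, str]] = set()
        for call in self.calls:
            key = (call.well, call.assay_id)
            if key in seen:
                raise DuplicateWellError(
                    f"plate {self.plate_name!r}: duplicate well/assay {call.well}/{call.assay_id}"
                )
            seen.add(key)


@dataclass(frozen=True)
class DetectorDesignation:
    """A pattern-conformant detector name: ``<assay>_<allele>``."""

    detector_name: str
    assay_name: str
    allele: str


def parse_detector_designation(detector_name: str) -> Optional[DetectorDesignation]:
    """Split a detector name on its LAST underscore into assay + allele.

    Detector names in allelic-discrimination software are arbitrary; automatic
    genotype inference only works when they follow the
    ``<arbitrary detector name>_<allele>`` convention (e.g. ``rs328_G`` or
    ``LPL-rs328_G``). Any other name yields ``None`` ("undetermined") and the
    conversion map must be completed manually. This function is total: it
    never raises.
    """
    if "_" not in detector_name:
        return None
    assay, _, allele = detector_name.rpartition("_")
    allele = allele.strip().upper()
    if not assay or allele not in "ACGT" or len(allele) != 1:
        return None
    return DetectorDesignation(detector_name, assay, allele)


# ---------------------------------------------------------------------------
# stream plumbing


def _read_text(source: Union[str, Path, io.IOBase]) -> str:
    if hasattr(source, "read"):
        data = source.read()
        return data.decode("utf-8") if isinstance(data, bytes) else data
    return Path(source).read_text(encoding="utf-8")


def _rows(text: str) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, parsed fields), skipping comments/blanks."""
    lines = text.splitlines()
    delim: Optional[str] = None
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if delim is None:
            delim = "\t" if "\t" in line else ","
        yield lineno, next(csv.reader([line], delimiter=delim))


def _header_fields(text: str) -> list[str]:
    for _, fields in _rows(text):
        return [f.strip() for f in fields]
    raise EmptyInputError("no non-comment lines in input")


def sniff_format(source: Union[str, Path, io.IOBase]) -> Dialect:
    """Identify the dialect of a plate export from its header row."""
    header = _header_fields(_read_text(source))
    if "Marker" in header:
        return Dialect.SDS
    if "Assay Id" in header:
        return Dialect.TYPER
    raise FormatError(
        f"unrecognised plate header {header!r}: expected a 'Marker' column "
        f"(SDS dialect) or an 'Assay Id' column (TYPER dialect)"
    )


def _column_index(header: list[str], required: tuple[str, ...]) -> dict[str, int]:
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"missing required columns {missing} in header {header!r}")
    return {c: header.index(c) for c in required}


# ---------------------------------------------------------------------------
# readers


def read_sds_export(source: Union[str, Path, io.IOBase], plate_name: str) -> PlateResult:
    """Read one single-plate allelic-discrimination export (SDS dialect).

    Call tokens (a detector name, "Both" or "Undetermined") are captured
    verbatim. ``#``-prefixed comment lines are skipped.
    """
    text = _read_text(source)
    rows = _rows(text)
    try:
        _, header = next(rows)
    except StopIteration:
        raise EmptyInputError(f"plate {plate_name!r}: empty input") from None
    idx = _column_index([f.strip() for f in header], _SDS_COLUMNS)

    calls: list[RawCall] = []
    seen: set[tuple[WellAddress, str]] = set()
    for lineno, fields in rows:
        try:
            well = WellAddress.parse(fields[idx["Well"]])
        except (ParseError, IndexError) as exc:
            raise ParseError(f"plate {plate_name!r} line {lineno}: {exc}") from None
        sample = fields[idx["Sample Name"]].strip()
        marker = fields[idx["Marker"]].strip()
        token = fields[idx["Call"]].strip()
        key = (well, marker)
        if key in seen:
            raise DuplicateWellError(
                f"plate {plate_name!r} line {lineno}: duplicate row for well "
                f"{well} marker {marker!r}"
            )
        seen.add(key)
        calls.append(RawCall(well, sample, marker, token))
    return PlateResult(plate_name, Dialect.SDS, calls)


def read_typer_export(source: Union[str, Path, io.IOBase]) -> list[PlateResult]:
    """Read a (possibly multi-plate, multiplexed) TYPER-dialect export.

    Rows are grouped by the Plate column, preserving first-seen plate order;
    the Genotype column ("A", "AG", "" for no call) is captured verbatim.
    """
    text = _read_text(source)
    rows = _rows(text)
    try:
        _, header = next(rows)
    except StopIteration:
        raise EmptyInputError("empty TYPER input") from None
    idx = _column_index([f.strip() for f in header], _TYPER_COLUMNS)

    plates: dict[str, list[RawCall]] = {}
    seen: set[tuple[str, WellAddress, str]] = set()
    for lineno, fields in rows:
        plate = fields[idx["Plate"]].strip()
        if not plate:
            raise ParseError(f"line {lineno}: missing Plate value")
        try:
            well = WellAddress.parse(fields[idx["Well"]])
        except (ParseError, IndexError) as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        sample = fields[idx["Sample Id"]].strip()
        assay = fields[idx["Assay Id"]].strip()
        token = fields[idx["Genotype"]].strip()
        key = (plate, well, assay)
        if key in seen:
            raise DuplicateWellError(
                f"line {lineno}: duplicate row for plate {plate!r} well {well} "
                f"assay {assay!r}"
            )
        seen.add(key)
        plates.setdefault(plate, []).append(RawCall(well, sample, assay, token))
    return [PlateResult(name, Dialect.TYPER, calls) for name, calls in plates.items()]


def read_archive(source: Union[str, Path, io.IOBase, bytes]) -> list[PlateResult]:
    """Read every member of a zip archive of plate files under one dialect.

    SDS members become one plate each, named after the member file; TYPER
    members contribute their Plate-column groups. Mixing dialects across
    members is an error.
    """
    if isinstance(source, bytes):
        source = io.BytesIO(source)
    with zipfile.ZipFile(source) as zf:
        members = [n for n in zf.namelist() if not n.endswith("/")]
        if not members:
            raise EmptyInputError("empty zip archive")
        results: list[PlateResult] = []
        archive_dialect: Optional[Dialect] = None
        for member in members:
            try:
                text = zf.read(member).decode("utf-8")
            except UnicodeDecodeError as exc:
                raise FormatError(f"unreadable archive member {member!r}: {exc}") from None
            try:
                dialect = sniff_format(io.StringIO(text))
            except FormatError as exc:
                raise type(exc)(f"archive member {member!r}: {exc}") from None
            if archive_dialect is None:
                archive_dialect = dialect
            elif dialect is not archive_dialect:
                raise MixedFormatError(
                    f"archive mixes dialects: {member!r} is {dialect.value}, "
                    f"earlier members are {archive_dialect.value}"
                )
            try:
                if dialect is Dialect.SDS:
                    results.append(read_sds_export(io.StringIO(text), Path(member).stem))
                else:
                    results.extend(read_typer_export(io.StringIO(text)))
            except ParseError as exc:
                raise type(exc)(f"archive member {member!r}: {exc}") from None
    return results


def read_plate_file(path: Union[str, Path]) -> list[PlateResult]:
    """Read a single plate file of either dialect (sniffed from the header)."""
    path = Path(path)
    dialect = sniff_format(path)
    if dialect is Dialect.SDS:
        return [read_sds_export(path, path.stem)]
    return read_typer_export(path)


def read_input(path: Union[str, Path]) -> list[PlateResult]:
    """Read a plate file or a zip archive of plate files (auto-detected)."""
    path = Path(path)
    if zipfile.is_zipfile(path):
        return read_archive(path)
    return read_plate_file(path)
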