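"""Sex-marker concordance checking.

Single-base differences between X- and Y-chromosomal gene copies
(amelogenin AMELX/AMELY, GYG2, ZFX/ZFY) let an autosomal-style SNP assay
double as a sex test: e.g. an amelogenin-type marker types females as
homozygotes (X/X) and males as heterozygotes (X/Y). Comparing this
genotypic sex with the expected phenotypic sex uncovers sample mix-ups.

The genotype→sex assignment is always user-supplied (different markers
encode sex differently), as is the sex coding of the phenotype file. By
design only the *discordant* records are ever persisted: full phenotype
files stay out of the genotype store.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Union

from .errors import CodingError, DuplicateKeyError, FormatError
from .genotype_core import Genotype, normalize_genotype

__all__ = [
    "Sex",
    "SexAssignment",
    "SexPhenotypes",
    "SexDiscordance",
    "SexCheckResult",
    "load_sex_phenotypes",
    "infer_sex",
    "sex_discordance_report",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


def _as_sex(value: Union[Sex, str]) -> Sex:
    if isinstance(value, Sex):
        return value
    try:
        return Sex(value.strip().lower())
    except ValueError:
        raise CodingError(f"cannot interpret {value!r} as a sex") from None


@dataclass
class SexAssignment:
    """User-supplied genotype→sex mapping for one sex-determination SNP."""

    mapping: dict[str, Sex]

    def __post_init__(self) -> None:
        normalised: dict[str, Sex] = {}
        for genotype, sex in self.mapping.items():
            normalised[str(normalize_genotype(genotype))] = _as_sex(sex)
        self.mapping = normalised

    def infer(self, genotype: Union[Genotype, str]) -> Sex:
        g = normalize_genotype(genotype)
        if g.is_missing:
            return Sex.UNKNOWN
        return self.mapping.get(str(g), Sex.UNKNOWN)


@dataclass
class SexPhenotypes:
    """Expected-sex records with their free-form token coding."""

    coding: dict[str, Sex]
    records: dict[str, str]  # sample_id -> raw token

    def sex_of(self, sample_id: str) -> Optional[Sex]:
        token = self.records.get(sample_id)
        return None if token is None else self.coding[token]

    def __len__(self) -> int:
        return len(self.records)


def load_sex_phenotypes(
    source: Union[str, Path, io.IOBase],
    coding: Mapping[str, Union[Sex, str]],
) -> SexPhenotypes:
    """Read the two-column (sample_id, sex token) phenotype TSV.

    The sex coding is free — the ``coding`` mapping must cover every token
    in the file. Duplicate sample IDs are rejected.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    sex_coding = {token: _as_sex(sex) for token, sex in coding.items()}

    records: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 2:
            raise FormatError(f"phenotype line {lineno}: expected two tab-separated columns")
        sample_id, token = fields[0], fields[1]
        if lineno == 1 and (sample_id.lower(), token.lower()) == ("sample_id", "sex"):
            continue  # header row
        if token not in sex_coding:
            raise CodingError(
                f"phenotype line {lineno}: sex token {token!r} absent from coding "
                f"{sorted(sex_coding)}"
            )
        if sample_id in records:
            raise DuplicateKeyError(f"duplicate phenotype record for sample {sample_id!r}")
        records[sample_id] = token
    return SexPhenotypes(coding=sex_coding, records=records)


def infer_sex(genotype: Union[Genotype, str], assignment: SexAssignment) -> Sex:
    """Genotypic sex of one genotype under the marker's assignment."""
    return assignment.infer(genotype)


@dataclass(frozen=True)
class SexDiscordance:
    sample_id: str
    genotypic_sex: Sex
    phenotypic_sex: Sex


@dataclass
class SexCheckResult:
    """Discordance list plus the full accounting of the manifest.

    discordant + concordant + unknown + missing_phenotype equals the
    number of samples checked. Samples without a phenotype record are
    counted as missing_phenotype (even if their genotype is also a
    no-call); genotypic unknowns with a phenotype count as unknown.
    Only the discordance records are ever written to the project store.
    """

    discordances: list[SexDiscordance] = field(default_factory=list)
    concordant: int = 0
    unknown: int = 0
    missing_phenotype: int = 0

    @property
    def discordant(self) -> int:
        return len(self.discordances)

    @property
    def total(self) -> int:
        return self.discordant + self.concordant + self.unknown + self.missing_phenotype


def sex_discordance_report(
    matrix_column: "pd.Series | Mapping[str, str]",
    assignment: SexAssignment,
    phenotypes: SexPhenotypes,
) -> SexCheckResult:
    """Compare genotypic against phenotypic sex for every sample.

    Only samples with both sexes known and unequal become discordance
    records; unknowns are tallied separately and never reported as
    discordant.
    """
    items = list(matrix_column.items())
    result = SexCheckResult()
    for sample_id, genotype in items:
        phenotypic = phenotypes.sex_of(sample_id)
        if phenotypic is None:
            result.missing_phenotype += 1
            continue
        genotypic = assignment.infer(genotype)
        if genotypic is Sex.UNKNOWN:
            result.unknown += 1
        elif genotypic is phenotypic:
            result.concordant += 1
        else:
            result.discordances.append(SexDiscordance(sample_id, genotypic, phenotypic))
    return result
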