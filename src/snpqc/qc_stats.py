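"""Per-SNP quality-control statistics.

The QC report for a SNP assay comprises the call rate, the expected and
real number of replicates, the absolute number of discordant replicates,
the discordance rate, the minor allele frequency (MAF) and a test of
Hardy-Weinberg equilibrium (HWE).

The HWE test is the classical Pearson chi-square with one degree of
freedom, no continuity correction by default: with n called genotypes and
estimated allele frequency p̂ = (2·n_AA + n_AB) / 2n, the expected genotype
counts are n·p̂², 2n·p̂q̂ and n·q̂², and X² = Σ (obs − exp)² / exp. A Yates
continuity correction is available behind a flag. Monomorphic SNPs give
X² = 0 with an undefined p-value.

Statistics whose denominator is empty are undefined, represented as
``None`` in memory and exported as the literal "NA" — never as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime
from typing import Optional, Sequence

from scipy import stats as _scipy_stats

from .errors import MultiAllelicError
from .genotype_core import Genotype, ReplicateGroup, ReplicateStatus
from .study import StudyDefinition

__all__ = [
    "GenotypeCounts",
    "genotype_counts",
    "call_rate",
    "minor_allele_freq",
    "ReplicateSummary",
    "replicate_summary",
    "hwe_chisq",
    "QCReport",
    "build_qc_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenotypeCounts:
    """Absolute genotype counts for one SNP over unique samples.

    ``n_aa`` counts allele1-homozygotes, ``n_bb`` allele2-homozygotes;
    alleles are alphabetically ordered. Alleles may be ``None`` only in the
    degenerate all-missing case with no allele information available.
    """

    n_aa: int
    n_ab: int
    n_bb: int
    allele1: Optional[str]
    allele2: Optional[str]
    n_missing: int = 0

    @property
    def n_called(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb

    @property
    def n_total(self) -> int:
        return self.n_called + self.n_missing

    def as_triple(self) -> tuple[int, int, int]:
        return (self.n_aa, self.n_ab, self.n_bb)


def genotype_counts(
    matrix_column: "pd.Series | Sequence[str]",
    alleles: Optional[tuple[str, str]] = None,
) -> GenotypeCounts:
    """Count genotype classes in one genotype-matrix column.

    The column holds canonical genotype strings, one per unique sample
    (missing samples included as "0/0"). When the assay's allele pair is
    known (from the conversion map) pass it in, so a monomorphic column is
    still classified correctly; otherwise the pair is inferred from the
    observed alleles. More than two distinct alleles is an error.
    """
    values = list(matrix_column)
    observed: dict[Genotype, int] = {}
    n_missing = 0
    alleles_seen: set[str] = set()
    for value in values:
        g = Genotype.from_string(value) if isinstance(value, str) else value
        if g.is_missing:
            n_missing += 1
            continue
        observed[g] = observed.get(g, 0) + 1
        alleles_seen.update(g.alleles)

    if alleles is not None:
        a, b = sorted(alleles)
        extra = alleles_seen - {a, b}
        if extra:
            raise MultiAllelicError(
                f"alleles {sorted(extra)} observed beyond declared pair {a}/{b}"
            )
    else:
        if len(alleles_seen) > 2:
            raise MultiAllelicError(f">2 distinct alleles observed: {sorted(alleles_seen)}")
        ordered = sorted(alleles_seen)
        if len(ordered) == 2:
            a, b = ordered
        elif len(ordered) == 1:
            a = b = ordered[0]
        else:
            return GenotypeCounts(0, 0, 0, None, None, n_missing)

    n_aa = observed.get(Genotype.from_alleles(a, a), 0)
    n_bb = 0 if a == b else observed.get(Genotype.from_alleles(b, b), 0)
    n_ab = 0 if a == b else observed.get(Genotype.from_alleles(a, b), 0)
    return GenotypeCounts(n_aa, n_ab, n_bb, a, b, n_missing)


def call_rate(counts: GenotypeCounts) -> Optional[float]:
    """Fraction of attempted samples with a usable genotype (None if n=0).

    The denominator is the full study manifest — including samples that
    never appeared in any plate file — with control wells excluded.
    """
    if counts.n_total == 0:
        return None
    return counts.n_called / counts.n_total


def minor_allele_freq(counts: GenotypeCounts) -> tuple[Optional[float], Optional[str]]:
    """MAF and minor allele; (None, None) when no genotype was called.

    A 0.5 tie reports the alphabetically first allele as minor.
    """
    n = counts.n_called
    if n == 0 or counts.allele1 is None:
        return None, None
    freq_a = (2 * counts.n_aa + counts.n_ab) / (2 * n)
    if freq_a <= 0.5:
        return freq_a, counts.allele1
    return 1.0 - freq_a, counts.allele2


@dataclass(frozen=True)
class ReplicateSummary:
    expected: int
    real: int
    discordant: int
    discordance_rate: Optional[float]


def replicate_summary(
    groups: Sequence[ReplicateGroup], study: Optional[StudyDefinition] = None
) -> ReplicateSummary:
    """Summarise replicate QC over the per-sample groups.

    ``expected`` counts samples plated at least twice (the replicates put
    on the plates); ``real`` counts those that actually produced two or
    more usable calls; ``discordant`` counts groups whose usable calls
    disagree. The discordance rate is discordant/real, undefined when no
    replicate produced usable data. A triplicate with one deviant call is
    one discordant replicate, not three pairwise ones.
    """
    expected = sum(1 for g in groups if len(g.calls) >= 2)
    real = sum(
        1 for g in groups
        if sum(1 for c in g.calls if not c.genotype.is_missing) >= 2
    )
    discordant = sum(1 for g in groups if g.status is ReplicateStatus.DISCORDANT)
    rate = discordant / real if real > 0 else None
    if study is not None and study.expected_replicate_count and \
            study.expected_replicate_count != expected:
        logger.warning(
            "study %r declares %d replicates but %d were detected on the plates",
            study.name, study.expected_replicate_count, expected,
        )
    return ReplicateSummary(expected, real, discordant, rate)


def hwe_chisq(
    counts: GenotypeCounts, *, yates: bool = False
) -> tuple[Optional[float], Optional[float]]:
    """Pearson chi-square test of Hardy-Weinberg equilibrium (1 df).

    Returns (chi2, p). A monomorphic SNP gives (0.0, None): with an allele
    fixed the test carries no information. With no called genotypes both
    are None.
    """
    n = counts.n_called
    if n == 0:
        return None, None
    p_hat = (2 * counts.n_aa + counts.n_ab) / (2 * n)
    q_hat = 1.0 - p_hat
    if p_hat == 0.0 or p_hat == 1.0:
        return 0.0, None
    expected = (n * p_hat * p_hat, 2 * n * p_hat * q_hat, n * q_hat * q_hat)
    chi2 = 0.0
    for obs, exp in zip(counts.as_triple(), expected):
        dev = abs(obs - exp)
        if yates:
            dev = max(dev - 0.5, 0.0)
        chi2 += dev * dev / exp
    p_value = float(_scipy_stats.chi2.sf(chi2, df=1))
    return chi2, p_value


@dataclass
class QCReport:
    """The full per-SNP QC record, statistics plus metadata."""

    snp_id: str
    creation_date: str
    operator: str = ""
    comment: str = ""
    call_rate: Optional[float] = None
    expected_replicates: int = 0
    real_replicates: int = 0
    discordant_replicates: int = 0
    discordance_rate: Optional[float] = None
    maf: Optional[float] = None
    minor_allele: Optional[str] = None
    hwe_chi2: Optional[float] = None
    hwe_p: Optional[float] = None
    counts: Optional[GenotypeCounts] = None

    STAT_FIELDS = (
        "call_rate",
        "expected_replicates",
        "real_replicates",
        "discordant_replicates",
        "discordance_rate",
        "maf",
        "minor_allele",
        "hwe_chi2",
        "hwe_p",
    )


def build_qc_report(
    snp_id: str,
    matrix_column: "pd.Series | Sequence[str]",
    groups: Sequence[ReplicateGroup],
    *,
    alleles: Optional[tuple[str, str]] = None,
    study: Optional[StudyDefinition] = None,
    operator: str = "",
    comment: str = "",
    creation_date: Optional[str] = None,
    yates: bool = False,
) -> QCReport:
    """Assemble the QC report for one SNP from its matrix column and groups."""
    counts = genotype_counts(matrix_column, alleles=alleles)
    maf, minor = minor_allele_freq(counts)
    chi2, p_value = hwe_chisq(counts, yates=yates)
    reps = replicate_summary(groups, study)
    return QCReport(
        snp_id=snp_id,
        creation_date=creation_date or datetime.now().isoformat(timespec="seconds"),
        operator=operator,
        comment=comment,
        call_rate=call_rate(counts),
        expected_replicates=reps.expected,
        real_replicates=reps.real,
        discordant_replicates=reps.discordant,
        discordance_rate=reps.discordance_rate,
        maf=maf,
        minor_allele=minor,
        hwe_chi2=chi2,
        hwe_p=p_value,
        counts=counts,
    )
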