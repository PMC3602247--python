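"""Plausibility check against reference-population genotype counts.

Observed genotype counts are compared with the counts reported for
reference populations (HapMap panels, 1000 Genomes super-populations) in a
local TSV lookup table, via a Pearson chi-square test on the 2×3
user-vs-reference contingency table of absolute genotype numbers. A strong
deviation from the matching ancestry flags errors — e.g. inverted detector
designations — that pass call-rate and HWE checks unnoticed.

Before testing, the allele pairs of the two sources are harmonised:
identical pairs compare directly, role-swapped pairs reorder the reference
counts, and pairs matching after reverse complement are strand-flipped.
Palindromic (A/T, C/G) SNPs are ambiguous — flip and swap are
indistinguishable — and compare directly with a warning flag. Anything
else is incompatible and no test is performed.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .errors import DuplicateKeyError, FormatError, ValidationError
from .qc_stats import GenotypeCounts

__all__ = [
    "REFERENCE_TABLE_COLUMNS",
    "ReferenceFrequencyTable",
    "load_reference_table",
    "Harmonization",
    "HarmonizationResult",
    "harmonize_alleles",
    "PopulationComparison",
    "compare_population",
    "compare_all",
]

logger = logging.getLogger(__name__)

REFERENCE_TABLE_COLUMNS = [
    "snp_id", "population", "source", "allele_a", "allele_b",
    "n_AA", "n_AB", "n_BB",
]
_SOURCES = {"HAPMAP", "KG"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class ReferenceFrequencyTable:
    """Per-SNP, per-population absolute genotype counts."""

    frame: pd.DataFrame

    def lookup(self, snp_id: str) -> pd.DataFrame:
        return self.frame[self.frame["snp_id"] == snp_id]

    def __len__(self) -> int:
        return len(self.frame)


def load_reference_table(source: Union[str, Path, io.IOBase]) -> ReferenceFrequencyTable:
    """Load and validate the reference genotype-count TSV.

    Columns: snp_id, population, source (HAPMAP|KG), allele_a, allele_b,
    n_AA, n_AB, n_BB. The (snp_id, population, source) triple is unique;
    counts are non-negative integers.
    """
    frame = pd.read_csv(source, sep="\t", dtype={"snp_id": str, "population": str,
                                                 "source": str, "allele_a": str,
                                                 "allele_b": str})
    missing = [c for c in REFERENCE_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"reference table missing columns {missing}")
    frame = frame[REFERENCE_TABLE_COLUMNS].copy()
    if frame.duplicated(subset=["snp_id", "population", "source"]).any():
        dups = frame[frame.duplicated(subset=["snp_id", "population", "source"])]
        raise DuplicateKeyError(
            f"duplicate (snp, population, source) rows: "
            f"{dups[['snp_id', 'population', 'source']].values.tolist()}"
        )
    for col in ("n_AA", "n_AB", "n_BB"):
        if (frame[col] < 0).any():
            raise ValidationError(f"negative count in column {col}")
        frame[col] = frame[col].astype(int)
    bad_source = set(frame["source"]) - _SOURCES
    if bad_source:
        raise ValidationError(f"unknown source labels {sorted(bad_source)}")
    for col in ("allele_a", "allele_b"):
        frame[col] = frame[col].str.upper()
        bad = set(frame[col]) - set("ACGT")
        if bad:
            raise ValidationError(f"invalid alleles {sorted(bad)} in column {col}")
    return ReferenceFrequencyTable(frame.reset_index(drop=True))


# ---------------------------------------------------------------------------
# allele harmonization


class Harmonization(str, Enum):
    DIRECT = "direct"
    ALLELE_SWAPPED = "allele_swapped"
    STRAND_FLIPPED = "strand_flipped"
    AMBIGUOUS = "ambiguous"
    INCOMPATIBLE = "incompatible"


@dataclass(frozen=True)
class HarmonizationResult:
    outcome: Harmonization
    swap_ref_counts: bool  # reference (AA, AB, BB) must be read as (BB, AB, AA)


def harmonize_alleles(
    user_alleles: tuple[str, str], ref_alleles: tuple[str, str]
) -> HarmonizationResult:
    """Align a reference allele pair with the user's allele pair.

    Idempotent normal form: applying the returned reordering yields a pair
    on which harmonisation is DIRECT (or AMBIGUOUS for palindromic SNPs).
    """
    user = tuple(a.upper() for a in user_alleles)
    ref = tuple(a.upper() for a in ref_alleles)
    flipped = tuple(_COMPLEMENT[a] for a in user)

    if set(user) == set(ref):
        if set(user) == set(flipped):  # A/T or C/G SNP: flip == swap
            return HarmonizationResult(Harmonization.AMBIGUOUS, user != ref)
        return HarmonizationResult(
            Harmonization.DIRECT if user == ref else Harmonization.ALLELE_SWAPPED,
            user != ref,
        )
    if set(flipped) == set(ref):
        return HarmonizationResult(Harmonization.STRAND_FLIPPED, flipped != ref)
    return HarmonizationResult(Harmonization.INCOMPATIBLE, False)


# ---------------------------------------------------------------------------
# the chi-square comparison


@dataclass
class PopulationComparison:
    """Result of comparing user genotype counts with one reference panel."""

    population: str
    source: str
    harmonization: Harmonization
    user_counts: GenotypeCounts
    ref_counts: GenotypeCounts  # aligned to the user's allele order
    chi2: Optional[float] = None
    df: int = 0
    p: Optional[float] = None
    small_count_warning: bool = False


def compare_population(
    user_counts: GenotypeCounts,
    ref_counts: GenotypeCounts,
    *,
    population: str = "",
    source: str = "",
    harmonization: Harmonization = Harmonization.DIRECT,
) -> PopulationComparison:
    """Pearson chi-square on the 2×3 user/reference genotype table.

    Genotype classes absent from both sources are dropped with the degrees
    of freedom reduced accordingly (df = k−1 for k surviving classes). The
    test is undefined (chi2, p = None) when fewer than two classes survive
    or either source has no genotypes. An expected cell below 5 sets the
    small-count warning.
    """
    result = PopulationComparison(
        population=population, source=source, harmonization=harmonization,
        user_counts=user_counts, ref_counts=ref_counts,
    )
    table = np.array([user_counts.as_triple(), ref_counts.as_triple()], dtype=float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return result  # undefined-test signal
    chi2, p, dof, expected = _scipy_stats.chi2_contingency(table, correction=False)
    result.chi2 = float(chi2)
    result.p = float(p)
    result.df = int(dof)
    result.small_count_warning = bool((expected < 5).any())
    return result


def _aligned_ref_counts(row: pd.Series, user_counts: GenotypeCounts,
                        harm: HarmonizationResult) -> GenotypeCounts:
    triple = (int(row["n_AA"]), int(row["n_AB"]), int(row["n_BB"]))
    if harm.swap_ref_counts:
        triple = (triple[2], triple[1], triple[0])
    return GenotypeCounts(*triple, allele1=user_counts.allele1,
                          allele2=user_counts.allele2)


def compare_all(
    snp_id: str,
    user_counts: GenotypeCounts,
    table: ReferenceFrequencyTable,
    population_filter: Optional[Sequence[str]] = None,
    *,
    alt_rs_id: Optional[str] = None,
) -> list[PopulationComparison]:
    """Compare one SNP with every matching reference population.

    The lookup key is the alternate rs-number when one is set (covering
    SNPs whose ID changed between builds), otherwise the SNP's own ID. A
    SNP absent from the table returns an empty list with a logged notice.
    Incompatible allele pairs yield a comparison row flagged incompatible
    with no test values.
    """
    key = alt_rs_id or snp_id
    rows = table.lookup(key)
    if rows.empty and alt_rs_id and snp_id != alt_rs_id:
        rows = table.lookup(snp_id)
    if rows.empty:
        logger.info("SNP %r (lookup key %r) not present in the reference table",
                    snp_id, key)
        return []
    if population_filter:
        wanted = set(population_filter)
        rows = rows[rows["population"].isin(wanted)]

    if user_counts.allele1 is None:
        logger.info("SNP %r: no called genotypes, skipping population comparison", snp_id)
        return []

    comparisons: list[PopulationComparison] = []
    user_pair = (user_counts.allele1, user_counts.allele2)
    for _, row in rows.iterrows():
        harm = harmonize_alleles(user_pair, (row["allele_a"], row["allele_b"]))
        if harm.outcome is Harmonization.INCOMPATIBLE:
            ref = GenotypeCounts(int(row["n_AA"]), int(row["n_AB"]), int(row["n_BB"]),
                                 row["allele_a"], row["allele_b"])
            comparisons.append(PopulationComparison(
                population=row["population"], source=row["source"],
                harmonization=harm.outcome, user_counts=user_counts, ref_counts=ref,
            ))
            continue
        ref = _aligned_ref_counts(row, user_counts, harm)
        comparisons.append(compare_population(
            user_counts, ref,
            population=row["population"], source=row["source"],
            harmonization=harm.outcome,
        ))
    return comparisons
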