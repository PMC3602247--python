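"""Genotype normalisation, conversion maps, replicates and the study matrix.

The conversion step is the second mandatory checkpoint of the workflow: raw
call tokens are mapped to normalised genotypes only through an explicitly
approved :class:`ConversionMap`. Inference is automatic when detector names
follow the ``<name>_<allele>`` convention (SDS) or when genotypes are plain
base strings (TYPER); anything else stays unmapped and must be completed by
hand before approval.

Genotypes are unordered allele pairs stored alphabetically ("A/G"); the
missing genotype is "0/0". Replicates — the same sample ID plated more than
once — are detected automatically from the call set, with no naming
convention required.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import (
    AmbiguousAssayError,
    CheckpointError,
    IncompleteMapError,
    InvalidAlleleError,
    NameCollisionError,
    StaleMapError,
)
from .plate_io import Dialect, PlateResult, RawCall, WellAddress, parse_detector_designation
from .study import IDClass, StudyDefinition, classify_id

__all__ = [
    "Genotype",
    "MISSING",
    "MISSING_CODE",
    "normalize_genotype",
    "ConversionMap",
    "infer_conversion_map",
    "approve_conversion",
    "SampleCall",
    "SNPCallSet",
    "apply_conversion",
    "ReplicateStatus",
    "ReplicateGroup",
    "collect_replicates",
    "resolve_replicates",
    "build_genotype_matrix",
]

_BASES = frozenset("ACGT")
MISSING_CODE = "0/0"


@dataclass(frozen=True, order=True)
class Genotype:
    """An unordered biallelic genotype, or the missing sentinel.

    Alleles are stored in ascending alphabetical order so "GA" and "AG"
    compare equal; the canonical text forms are "A/G" and "0/0".
    """

    allele1: Optional[str]
    allele2: Optional[str]

    def __post_init__(self) -> None:
        a, b = self.allele1, self.allele2
        if (a is None) != (b is None):
            raise InvalidAlleleError(f"half-missing genotype ({a!r}, {b!r})")
        if a is not None:
            if a not in _BASES or b not in _BASES:
                raise InvalidAlleleError(f"invalid allele in ({a!r}, {b!r})")
            if a > b:
                raise InvalidAlleleError("alleles must be in alphabetical order")

    @property
    def is_missing(self) -> bool:
        return self.allele1 is None

    @property
    def is_het(self) -> bool:
        return self.allele1 is not None and self.allele1 != self.allele2

    @property
    def alleles(self) -> tuple[str, ...]:
        return () if self.is_missing else (self.allele1, self.allele2)

    @classmethod
    def from_alleles(cls, a: str, b: str) -> "Genotype":
        a, b = a.strip().upper(), b.strip().upper()
        if a not in _BASES or b not in _BASES:
            raise InvalidAlleleError(f"invalid allele in {a!r}{b!r}")
        return cls(min(a, b), max(a, b))

    @classmethod
    def homozygous(cls, allele: str) -> "Genotype":
        return cls.from_alleles(allele, allele)

    @classmethod
    def from_string(cls, text: str) -> "Genotype":
        """Parse "A/G", "AG" or a missing code ("", "0/0", "00", "0")."""
        s = text.strip().replace("/", "")
        if s in ("", "0", "00"):
            return MISSING
        if len(s) != 2:
            raise InvalidAlleleError(f"cannot parse genotype {text!r}")
        return cls.from_alleles(s[0], s[1])

    def __str__(self) -> str:
        if self.is_missing:
            return MISSING_CODE
        return f"{self.allele1}/{self.allele2}"


MISSING = Genotype(None, None)


def normalize_genotype(raw_pair: Union[str, Genotype]) -> Genotype:
    """Canonicalise a two-base pair (or missing sentinel); idempotent."""
    if isinstance(raw_pair, Genotype):
        return raw_pair
    return Genotype.from_string(raw_pair)


# ---------------------------------------------------------------------------
# conversion maps (checkpoint 2)


@dataclass
class ConversionMap:
    """Mapping from raw call tokens to genotypes for one assay.

    ``None`` values mark tokens the automatic detection could not resolve;
    they must be edited in before approval. ``snp_id`` defaults to the assay
    ID; ``alt_rs_id`` optionally carries the rs-number under which reference
    panels know the SNP, for when the primary ID changed between builds.
    """

    assay_id: str
    mapping: dict[str, Optional[Genotype]] = field(default_factory=dict)
    approved: bool = False
    snp_id: Optional[str] = None
    alt_rs_id: Optional[str] = None

    @property
    def result_snp_id(self) -> str:
        return self.snp_id or self.assay_id

    @property
    def unmapped_tokens(self) -> list[str]:
        return [t for t, g in self.mapping.items() if g is None]

    @property
    def alleles(self) -> Optional[tuple[str, str]]:
        """The assay's (sorted) allele pair, when derivable from the map."""
        observed = sorted({a for g in self.mapping.values() if g and not g.is_missing
                           for a in g.alleles})
        if len(observed) == 2:
            return observed[0], observed[1]
        if len(observed) == 1:
            return observed[0], observed[0]
        return None


_SDS_BOTH = "Both"
_SDS_UNDETERMINED = "Undetermined"


def infer_conversion_map(
    plate_calls: Iterable[RawCall], assay_id: str, dialect: Dialect
) -> ConversionMap:
    """Suggest token→genotype conversions from the observed tokens.

    SDS: the two detector-name tokens are parsed via the ``<name>_<allele>``
    pattern; each maps to the homozygote of its allele, "Both" to the
    heterozygote and "Undetermined" to missing. Non-conformant detector names
    leave their tokens (and "Both") unmapped for manual completion. TYPER:
    one-base tokens are homozygotes, two-base tokens normalised genotypes,
    the empty token is a no-call.

    The returned map is NOT approved; :func:`apply_conversion` refuses it
    until :func:`approve_conversion` has been run.
    """
    tokens: list[str] = []
    for call in plate_calls:
        if call.assay_id == assay_id and call.call_token not in tokens:
            tokens.append(call.call_token)
    if not tokens:
        raise AmbiguousAssayError(f"assay {assay_id!r}: no call tokens observed")

    mapping: dict[str, Optional[Genotype]] = {}
    if dialect is Dialect.SDS:
        detectors = [t for t in tokens if t not in (_SDS_BOTH, _SDS_UNDETERMINED, "")]
        if len(detectors) != 2:
            raise AmbiguousAssayError(
                f"assay {assay_id!r}: expected exactly 2 detector tokens, "
                f"observed {detectors!r} (all tokens: {tokens!r})"
            )
        designations = [parse_detector_designation(t) for t in detectors]
        conformant = (
            None not in designations
            and designations[0].allele != designations[1].allele
        )
        for token in tokens:
            if token in ("", _SDS_UNDETERMINED):
                mapping[token] = MISSING
            elif conformant and token == _SDS_BOTH:
                mapping[token] = Genotype.from_alleles(
                    designations[0].allele, designations[1].allele
                )
            elif conformant and token in detectors:
                mapping[token] = Genotype.homozygous(
                    designations[detectors.index(token)].allele
                )
            else:
                mapping[token] = None  # manual completion required
    else:
        for token in tokens:
            s = token.strip().upper()
            if s == "":
                mapping[token] = MISSING
            elif len(s) == 1 and s in _BASES:
                mapping[token] = Genotype.homozygous(s)
            elif len(s) == 2 and set(s) <= _BASES:
                mapping[token] = Genotype.from_alleles(s[0], s[1])
            else:
                mapping[token] = None
    return ConversionMap(assay_id=assay_id, mapping=mapping)


def approve_conversion(
    cmap: ConversionMap,
    edits: Optional[Mapping[str, Union[Genotype, str, None]]] = None,
) -> ConversionMap:
    """Apply user edits and mark the map approved (checkpoint 2).

    Edits may override any suggestion (user authority at the checkpoint);
    genotypes may be given as strings ("A/G", "0/0"). A map with tokens
    still unmapped after edits cannot be approved.
    """
    mapping = dict(cmap.mapping)
    for token, value in (edits or {}).items():
        mapping[token] = normalize_genotype(value) if value is not None else None
    unmapped = [t for t, g in mapping.items() if g is None]
    if unmapped:
        raise IncompleteMapError(
            f"assay {cmap.assay_id!r}: unmapped tokens {unmapped!r} — "
            f"manual mapping required before approval"
        )
    return replace(cmap, mapping=mapping, approved=True)


# ---------------------------------------------------------------------------
# applying conversions


@dataclass(frozen=True)
class SampleCall:
    """One well-level genotype call with full provenance."""

    sample_id: str
    plate_name: str
    well: WellAddress
    genotype: Genotype


@dataclass
class SNPCallSet:
    """All well-level calls of one SNP for the study samples."""

    assay_id: str
    snp_id: str
    calls: list[SampleCall] = field(default_factory=list)
    alt_rs_id: Optional[str] = None
    alleles: Optional[tuple[str, str]] = None


def apply_conversion(
    plates: Sequence[PlateResult], study: StudyDefinition, cmap: ConversionMap
) -> SNPCallSet:
    """Convert every retained well of the assay to a normalised genotype.

    Wells whose IDs are controls, annulled or unknown (the checkpoint-1
    removal set) are excluded; every remaining well becomes exactly one
    call, missing genotypes included. Requires an approved map; a token
    absent from the map (file changed after inference) aborts.
    """
    if not cmap.approved:
        raise CheckpointError(
            f"assay {cmap.assay_id!r}: conversion map not approved "
            f"(checkpoint 2 not passed)"
        )
    lookup = study._sample_lookup()
    calls: list[SampleCall] = []
    for plate in plates:
        for call in plate.calls:
            if call.assay_id != cmap.assay_id:
                continue
            cls = classify_id(call.sample_id, study)
            if cls.klass is not IDClass.STUDY_SAMPLE:
                continue
            if call.call_token not in cmap.mapping:
                raise StaleMapError(
                    f"assay {cmap.assay_id!r}: token {call.call_token!r} at "
                    f"{plate.plate_name}/{call.well} absent from approved map"
                )
            canonical = lookup[study._fold(cls.id)]
            calls.append(
                SampleCall(canonical, plate.plate_name, call.well,
                           cmap.mapping[call.call_token])
            )
    return SNPCallSet(
        assay_id=cmap.assay_id,
        snp_id=cmap.result_snp_id,
        calls=calls,
        alt_rs_id=cmap.alt_rs_id,
        alleles=cmap.alleles,
    )


# ---------------------------------------------------------------------------
# replicates


class ReplicateStatus(str, Enum):
    SINGLE = "single"          # exactly one well
    CONCORDANT = "concordant"  # >=2 non-missing calls, all equal
    DISCORDANT = "discordant"  # >=2 non-missing calls, not all equal
    UNRESOLVED = "unresolved"  # >=2 wells but <2 non-missing calls


@dataclass
class ReplicateGroup:
    """All wells of one sample ID for one SNP, with concordance status."""

    sample_id: str
    calls: list[SampleCall]
    status: ReplicateStatus


def collect_replicates(callset: SNPCallSet) -> list[ReplicateGroup]:
    """Group calls by sample ID and grade replicate concordance.

    Replicates are detected purely from repeated sample IDs — no "QC-"
    prefix or other naming convention is needed. A sample plated three or
    more times still forms a single group.
    """
    by_sample: dict[str, list[SampleCall]] = {}
    for call in callset.calls:
        by_sample.setdefault(call.sample_id, []).append(call)

    groups: list[ReplicateGroup] = []
    for sample_id, calls in by_sample.items():
        non_missing = [c.genotype for c in calls if not c.genotype.is_missing]
        if len(calls) == 1:
            status = ReplicateStatus.SINGLE
        elif len(non_missing) < 2:
            status = ReplicateStatus.UNRESOLVED
        elif len(set(non_missing)) == 1:
            status = ReplicateStatus.CONCORDANT
        else:
            status = ReplicateStatus.DISCORDANT
        groups.append(ReplicateGroup(sample_id, calls, status))
    return groups


def resolve_replicates(group: ReplicateGroup, *, majority_vote: bool = False) -> Genotype:
    """Reduce a replicate group to the genotype entering the final list.

    Concordant groups (and singles) keep their unique non-missing genotype;
    groups with no usable call stay missing. Discordant groups resolve to
    missing by default — the conservative rule never fabricates a genotype.
    With ``majority_vote`` a strict majority among non-missing calls wins
    and ties fall back to missing.
    """
    non_missing = [c.genotype for c in group.calls if not c.genotype.is_missing]
    if not non_missing:
        return MISSING
    if group.status is not ReplicateStatus.DISCORDANT:
        return non_missing[0]
    if majority_vote:
        tally: dict[Genotype, int] = {}
        for g in non_missing:
            tally[g] = tally.get(g, 0) + 1
        best = max(tally.values())
        winners = [g for g, n in tally.items() if n == best]
        if len(winners) == 1:
            return winners[0]
    return MISSING


# ---------------------------------------------------------------------------
# the study genotype matrix


def build_genotype_matrix(
    study: StudyDefinition,
    callsets: Sequence[SNPCallSet],
    *,
    majority_vote: bool = False,
) -> pd.DataFrame:
    """Assemble the sample × SNP matrix of resolved genotype strings.

    Rows are the full manifest in manifest order — samples absent from all
    plate files appear with the missing code "0/0". Columns follow callset
    import order; a repeated SNP ID across callsets is a name collision.
    """
    snp_ids: list[str] = []
    for cs in callsets:
        if cs.snp_id in snp_ids:
            raise NameCollisionError(f"duplicate SNP id {cs.snp_id!r} across call sets")
        snp_ids.append(cs.snp_id)

    matrix = pd.DataFrame(
        MISSING_CODE, index=list(study.sample_ids), columns=snp_ids, dtype=object
    )
    matrix.index.name = "sample_id"
    for cs in callsets:
        for group in collect_replicates(cs):
            resolved = resolve_replicates(group, majority_vote=majority_vote)
            matrix.at[group.sample_id, cs.snp_id] = str(resolved)
    return matrix
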