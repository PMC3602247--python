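"""Study definitions and sample-ID classification.

A study is defined by its name, an ordered manifest of sample IDs, the
declared number of replicates on the plates, and the token sets marking
control wells (non-template controls "NTC", positive controls "PC") and
annulled samples ("ER" — DNA known to be flawed, relabelled on the plate so
no data is collected for it). Every well ID then falls into exactly one of
four classes: study sample, control, annulled, or unknown; the non-sample
classes form the first checkpoint's removal proposal.

Manifest samples that never appear on any plate still belong in the final
genotype lists and in every call-rate denominator — silently dropping them
would distort the QC values.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .errors import ConfigurationError, EmptyInputError
from .plate_io import PlateResult, WellAddress

__all__ = [
    "IDClass",
    "IDClassification",
    "StudyDefinition",
    "RemovalProposal",
    "create_study",
    "classify_id",
    "propose_removals",
    "missing_samples",
]

logger = logging.getLogger(__name__)

DEFAULT_CONTROL_TOKENS = frozenset({"NTC", "PC"})
DEFAULT_ANNULLED_TOKENS = frozenset({"ER"})


class IDClass(str, Enum):
    STUDY_SAMPLE = "study_sample"
    CONTROL = "control"
    ANNULLED = "annulled"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class IDClassification:
    id: str
    klass: IDClass


@dataclass
class StudyDefinition:
    """A study: named manifest plus control/annulled token configuration.

    ``case_insensitive`` folds case when matching plate IDs against the
    manifest; ``token_prefix_match`` additionally treats control/annulled
    tokens as prefixes (labs often number their controls NTC1, NTC2, ...).
    Both are off by default: silent case-folding can merge distinct IDs.
    """

    name: str
    sample_ids: list[str]
    expected_replicate_count: int = 0
    control_tokens: frozenset[str] = DEFAULT_CONTROL_TOKENS
    annulled_tokens: frozenset[str] = DEFAULT_ANNULLED_TOKENS
    active: bool = True
    case_insensitive: bool = False
    token_prefix_match: bool = False
    manifest_duplicates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise EmptyInputError(f"study {self.name!r}: empty sample manifest")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ConfigurationError(f"study {self.name!r}: duplicate manifest IDs")
        clash = (set(self.control_tokens) | set(self.annulled_tokens)) & set(self.sample_ids)
        if clash:
            raise ConfigurationError(
                f"study {self.name!r}: manifest IDs collide with control/annulled "
                f"tokens: {sorted(clash)}"
            )

    def _fold(self, text: str) -> str:
        return text.casefold() if self.case_insensitive else text

    def _sample_lookup(self) -> dict[str, str]:
        # folded plate ID -> canonical manifest ID; cached, manifests are
        # fixed after creation and studies can span tens of thousands of IDs
        cache = self.__dict__.get("_lookup_cache")
        if cache is None or len(cache) != len(self.sample_ids):
            cache = {self._fold(s): s for s in self.sample_ids}
            self.__dict__["_lookup_cache"] = cache
        return cache

    def _token_match(self, identifier: str, tokens: Iterable[str]) -> bool:
        ident = self._fold(identifier)
        for token in tokens:
            tok = self._fold(token)
            if ident == tok or (self.token_prefix_match and ident.startswith(tok)):
                return True
        return False


def create_study(
    name: str,
    sample_id_source: Union[str, Path, io.IOBase, Sequence[str]],
    expected_replicate_count: int = 0,
    control_tokens: Optional[Iterable[str]] = None,
    annulled_tokens: Optional[Iterable[str]] = None,
    *,
    case_insensitive: bool = False,
    token_prefix_match: bool = False,
) -> StudyDefinition:
    """Build a study from a manifest (one sample ID per line, '#' comments).

    Duplicate manifest lines are de-duplicated keeping the first occurrence;
    the duplicates are recorded on ``manifest_duplicates`` and logged.
    """
    if isinstance(sample_id_source, (str, Path)):
        lines: Iterable[str] = Path(sample_id_source).read_text(encoding="utf-8").splitlines()
    elif hasattr(sample_id_source, "read"):
        lines = sample_id_source.read().splitlines()
    else:
        lines = sample_id_source

    ids: list[str] = []
    duplicates: list[str] = []
    seen: set[str] = set()
    for line in lines:
        ident = line.strip()
        if not ident or ident.startswith("#"):
            continue
        if ident in seen:
            duplicates.append(ident)
            continue
        seen.add(ident)
        ids.append(ident)
    if not ids:
        raise EmptyInputError(f"study {name!r}: manifest contains no sample IDs")
    if duplicates:
        logger.warning("study %r: %d duplicate manifest IDs ignored: %s",
                       name, len(duplicates), duplicates[:10])

    return StudyDefinition(
        name=name,
        sample_ids=ids,
        expected_replicate_count=expected_replicate_count,
        control_tokens=frozenset(control_tokens) if control_tokens is not None
        else DEFAULT_CONTROL_TOKENS,
        annulled_tokens=frozenset(annulled_tokens) if annulled_tokens is not None
        else DEFAULT_ANNULLED_TOKENS,
        case_insensitive=case_insensitive,
        token_prefix_match=token_prefix_match,
        manifest_duplicates=duplicates,
    )


def classify_id(identifier: str, study: StudyDefinition) -> IDClassification:
    """Classify one plate ID: annulled beats control beats study sample.

    The precedence order makes the four classes a partition even under
    overlapping token configurations; anything unmatched is unknown.
    """
    ident = identifier.strip()
    if study._token_match(ident, study.annulled_tokens):
        return IDClassification(ident, IDClass.ANNULLED)
    if study._token_match(ident, study.control_tokens):
        return IDClassification(ident, IDClass.CONTROL)
    if study._fold(ident) in study._sample_lookup():
        return IDClassification(ident, IDClass.STUDY_SAMPLE)
    return IDClassification(ident, IDClass.UNKNOWN)


@dataclass(frozen=True)
class RemovalProposal:
    """One well proposed for removal at the first data checkpoint."""

    sample_id: str
    plate_name: str
    well: WellAddress
    klass: IDClass


def propose_removals(
    plates: Sequence[PlateResult], study: StudyDefinition
) -> list[RemovalProposal]:
    """List every (plate, well) whose ID is not a study sample.

    Controls, annulled samples and unrecognised IDs are each proposed once
    per well, even when the well carries several multiplexed assay rows.
    This is the first of the two mandatory data checkpoints: it must be
    confirmed before any genotype conversion happens.
    """
    proposals: list[RemovalProposal] = []
    seen: set[tuple[str, WellAddress]] = set()
    for plate in plates:
        for call in plate.calls:
            key = (plate.plate_name, call.well)
            if key in seen:
                continue
            cls = classify_id(call.sample_id, study)
            if cls.klass is not IDClass.STUDY_SAMPLE:
                seen.add(key)
                proposals.append(
                    RemovalProposal(cls.id, plate.plate_name, call.well, cls.klass)
                )
    return proposals


def missing_samples(study: StudyDefinition, plates: Sequence[PlateResult]) -> list[str]:
    """Manifest IDs absent from every plate, in manifest order.

    These samples must still appear in genotype lists (with the missing
    code) and count in call-rate denominators.
    """
    lookup = study._sample_lookup()
    present: set[str] = set()
    for plate in plates:
        for call in plate.calls:
            canonical = lookup.get(study._fold(call.sample_id.strip()))
            if canonical is not None:
                present.add(canonical)
    return [s for s in study.sample_ids if s not in present]
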