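"""Batch orchestration of the four-step import wizard and the project store.

The import runs parse → checkpoint 1 (removal confirmation) → conversion
inference → checkpoint 2 (per-assay map approval) → conversion, replicate
resolution and QC, and only then persists — a refusal at either checkpoint
aborts with the store untouched (atomic import).

The store is a plain versioned project directory (JSON metadata plus
delimiter-separated tables) rather than a relational database: the batch
tool is single-user, and files are diff-able and trivially backed up. An
embedded relational backend would slot in behind the same interface.

Layout::

    <root>/
      studies/<study>/study.json
      studies/<study>/results/<group>/<snp>/calls.csv
      studies/<study>/results/<group>/<snp>/qc.json
      studies/<study>/results/<group>/<snp>/conversion.json
      studies/<study>/sex_discordances/<snp>.json
"""

from __future__ import annotations

import json
import logging
import shutil
import uuid
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

from .errors import (
    CheckpointError,
    NameCollisionError,
    NotFoundError,
    StoreError,
)
from .genotype_core import (
    ConversionMap,
    Genotype,
    SNPCallSet,
    SampleCall,
    apply_conversion,
    approve_conversion,
    build_genotype_matrix,
    collect_replicates,
    infer_conversion_map,
)
from .plate_io import Dialect, PlateResult, WellAddress, read_input
from .qc_stats import GenotypeCounts, QCReport, build_qc_report
from .sex_check import SexDiscordance, Sex
from .study import RemovalProposal, StudyDefinition, propose_removals

__all__ = [
    "ProjectStore",
    "ImportedResult",
    "run_import",
    "load_config",
]

logger = logging.getLogger(__name__)


def _safe_name(name: str) -> str:
    cleaned = "".join(c if c.isalnum() or c in "-_." else "_" for c in name)
    if not cleaned:
        raise StoreError(f"cannot derive a directory name from {name!r}")
    return cleaned


@dataclass
class ImportedResult:
    callset: SNPCallSet
    qc_report: QCReport
    conversion: ConversionMap
    result_group: str


class ProjectStore:
    """File-backed, single-user project store with lossless round-trips."""

    def __init__(self, root: Union[str, Path]):
        self.root = Path(root)
        (self.root / "studies").mkdir(parents=True, exist_ok=True)

    # -- studies ----------------------------------------------------------

    def _study_dir(self, name: str) -> Path:
        return self.root / "studies" / _safe_name(name)

    def save_study(self, study: StudyDefinition) -> None:
        sdir = self._study_dir(study.name)
        sdir.mkdir(parents=True, exist_ok=True)
        payload = {
            "name": study.name,
            "sample_ids": study.sample_ids,
            "expected_replicate_count": study.expected_replicate_count,
            "control_tokens": sorted(study.control_tokens),
            "annulled_tokens": sorted(study.annulled_tokens),
            "active": study.active,
            "case_insensitive": study.case_insensitive,
            "token_prefix_match": study.token_prefix_match,
        }
        (sdir / "study.json").write_text(json.dumps(payload, indent=1), encoding="utf-8")

    def load_study(self, name: str) -> StudyDefinition:
        path = self._study_dir(name) / "study.json"
        if not path.exists():
            raise NotFoundError(f"study {name!r} not found in {self.root}")
        data = json.loads(path.read_text(encoding="utf-8"))
        return StudyDefinition(
            name=data["name"],
            sample_ids=list(data["sample_ids"]),
            expected_replicate_count=data["expected_replicate_count"],
            control_tokens=frozenset(data["control_tokens"]),
            annulled_tokens=frozenset(data["annulled_tokens"]),
            active=data["active"],
            case_insensitive=data["case_insensitive"],
            token_prefix_match=data["token_prefix_match"],
        )

    def list_studies(self) -> list[str]:
        names = []
        for path in sorted((self.root / "studies").glob("*/study.json")):
            names.append(json.loads(path.read_text(encoding="utf-8"))["name"])
        return names

    def deactivate_study(self, name: str, active: bool = False) -> StudyDefinition:
        study = self.load_study(name)
        study.active = active
        self.save_study(study)
        return study

    # -- results ----------------------------------------------------------

    def _result_dir(self, study: str, group: str, snp_id: str) -> Path:
        return (self._study_dir(study) / "results" / _safe_name(group)
                / _safe_name(snp_id))

    def has_result(self, study: str, group: str, snp_id: str) -> bool:
        return self._result_dir(study, group, snp_id).exists()

    def _write_result(self, rdir: Path, result: ImportedResult) -> None:
        rdir.mkdir(parents=True, exist_ok=True)
        cs = result.callset
        with open(rdir / "calls.csv", "w", encoding="utf-8", newline="") as fh:
            fh.write("sample_id,plate_name,well,genotype\n")
            for call in cs.calls:
                fh.write(f"{call.sample_id},{call.plate_name},{call.well},"
                         f"{call.genotype}\n")
        qc = asdict(result.qc_report)
        (rdir / "qc.json").write_text(json.dumps(qc, indent=1), encoding="utf-8")
        conv = {
            "assay_id": result.conversion.assay_id,
            "snp_id": cs.snp_id,
            "alt_rs_id": cs.alt_rs_id,
            "alleles": list(cs.alleles) if cs.alleles else None,
            "mapping": {t: (str(g) if g is not None else None)
                        for t, g in result.conversion.mapping.items()},
            "approved": result.conversion.approved,
        }
        (rdir / "conversion.json").write_text(json.dumps(conv, indent=1),
                                              encoding="utf-8")

    def save_result(self, study: str, result: ImportedResult,
                    overwrite: bool = False) -> Path:
        rdir = self._result_dir(study, result.result_group, result.callset.snp_id)
        if rdir.exists() and not overwrite:
            raise NameCollisionError(
                f"result {result.result_group}/{result.callset.snp_id} already "
                f"exists in study {study!r} (use overwrite)"
            )
        self._write_result(rdir, result)
        return rdir

    def load_result(self, study: str, group: str, snp_id: str) -> ImportedResult:
        rdir = self._result_dir(study, group, snp_id)
        if not rdir.exists():
            raise NotFoundError(f"result {group}/{snp_id} not found in study {study!r}")
        conv = json.loads((rdir / "conversion.json").read_text(encoding="utf-8"))
        calls: list[SampleCall] = []
        lines = (rdir / "calls.csv").read_text(encoding="utf-8").splitlines()[1:]
        for line in lines:
            sample_id, plate, well, genotype = line.split(",")
            calls.append(SampleCall(sample_id, plate, WellAddress.parse(well),
                                    Genotype.from_string(genotype)))
        callset = SNPCallSet(
            assay_id=conv["assay_id"], snp_id=conv["snp_id"], calls=calls,
            alt_rs_id=conv.get("alt_rs_id"),
            alleles=tuple(conv["alleles"]) if conv.get("alleles") else None,
        )
        qc_data = json.loads((rdir / "qc.json").read_text(encoding="utf-8"))
        counts = qc_data.pop("counts", None)
        report = QCReport(**qc_data)
        if counts is not None:
            report.counts = GenotypeCounts(**counts)
        cmap = ConversionMap(
            assay_id=conv["assay_id"],
            mapping={t: (Genotype.from_string(g) if g is not None else None)
                     for t, g in conv["mapping"].items()},
            approved=conv["approved"],
            snp_id=conv["snp_id"],
            alt_rs_id=conv.get("alt_rs_id"),
        )
        return ImportedResult(callset, report, cmap, group)

    def list_results(self, study: str) -> list[tuple[str, str]]:
        rroot = self._study_dir(study) / "results"
        out: list[tuple[str, str]] = []
        if rroot.exists():
            for qc in sorted(rroot.glob("*/*/qc.json")):
                out.append((qc.parent.parent.name, qc.parent.name))
        return out

    def search(self, study: str, text: str) -> list[tuple[str, str]]:
        """Case-insensitive substring search over result groups and SNP ids."""
        needle = text.casefold()
        return [(g, s) for g, s in self.list_results(study)
                if needle in g.casefold() or needle in s.casefold()]

    def delete_result(self, study: str, group: str, snp_id: str) -> None:
        rdir = self._result_dir(study, group, snp_id)
        if not rdir.exists():
            raise NotFoundError(f"result {group}/{snp_id} not found in study {study!r}")
        shutil.rmtree(rdir)
        gdir = rdir.parent
        if gdir.exists() and not any(gdir.iterdir()):
            gdir.rmdir()

    # -- sex discordances (only discordances are ever persisted) ----------

    def save_sex_discordances(self, study: str, snp_id: str,
                              discordances: Sequence[SexDiscordance]) -> Path:
        ddir = self._study_dir(study) / "sex_discordances"
        ddir.mkdir(parents=True, exist_ok=True)
        path = ddir / f"{_safe_name(snp_id)}.json"
        payload = [
            {"sample_id": d.sample_id, "genotypic_sex": d.genotypic_sex.value,
             "phenotypic_sex": d.phenotypic_sex.value}
            for d in discordances
        ]
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
        return path

    def load_sex_discordances(self, study: str, snp_id: str) -> list[SexDiscordance]:
        path = self._study_dir(study) / "sex_discordances" / f"{_safe_name(snp_id)}.json"
        if not path.exists():
            raise NotFoundError(f"no sex discordances stored for {snp_id!r}")
        return [
            SexDiscordance(d["sample_id"], Sex(d["genotypic_sex"]),
                           Sex(d["phenotypic_sex"]))
            for d in json.loads(path.read_text(encoding="utf-8"))
        ]


# ---------------------------------------------------------------------------
# the import wizard


def _group_assays(plates: Sequence[PlateResult]) -> dict[str, list]:
    assays: dict[str, list] = {}
    for plate in plates:
        for call in plate.calls:
            assays.setdefault(call.assay_id, []).append(call)
    return assays


def run_import(
    store: Optional[ProjectStore],
    study: StudyDefinition,
    source: Union[str, Path, Sequence[PlateResult]],
    result_group: Optional[str] = None,
    operator: str = "",
    comment: str = "",
    *,
    auto_approve: bool = False,
    confirm_removals: Optional[Callable[[list[RemovalProposal]], bool]] = None,
    confirm_conversion: Optional[
        Callable[[ConversionMap], Optional[Mapping[str, object]]]
    ] = None,
    alt_rs_ids: Optional[Mapping[str, str]] = None,
    conversion_edits: Optional[Mapping[str, Mapping[str, object]]] = None,
    overwrite: bool = False,
    majority_vote: bool = False,
) -> list[ImportedResult]:
    """Run the four-step import on one file/zip and persist the results.

    Checkpoint 1 presents the removal proposals, checkpoint 2 each assay's
    conversion map. ``auto_approve`` accepts both; otherwise the
    ``confirm_*`` callbacks decide (returning False / None aborts). Nothing
    is written to the store until every step has succeeded.
    """
    if isinstance(source, (str, Path)):
        plates = read_input(source)
        default_group = Path(source).stem
    else:
        plates = list(source)
        default_group = plates[0].plate_name if plates else "import"
    group = result_group or default_group

    # checkpoint 1: removal of controls/annulled/unknown wells
    removals = propose_removals(plates, study)
    if not auto_approve:
        if confirm_removals is None:
            raise CheckpointError("checkpoint 1 requires confirmation "
                                  "(pass auto_approve or confirm_removals)")
        if not confirm_removals(removals):
            raise CheckpointError("checkpoint 1 declined: import aborted")
    logger.info("checkpoint 1: %d wells proposed for removal", len(removals))

    dialect = plates[0].dialect if plates else Dialect.SDS
    assays = _group_assays(plates)

    # checkpoint 2: per-assay conversion approval
    approved: dict[str, ConversionMap] = {}
    for assay_id, calls in assays.items():
        cmap = infer_conversion_map(calls, assay_id, dialect)
        if alt_rs_ids and assay_id in alt_rs_ids:
            cmap.alt_rs_id = alt_rs_ids[assay_id]
        edits = (conversion_edits or {}).get(assay_id)
        if auto_approve:
            approved[assay_id] = approve_conversion(cmap, edits)
        else:
            if confirm_conversion is None:
                raise CheckpointError("checkpoint 2 requires confirmation "
                                      "(pass auto_approve or confirm_conversion)")
            user_edits = confirm_conversion(cmap)
            if user_edits is None and edits is None:
                raise CheckpointError(
                    f"checkpoint 2 declined for assay {assay_id!r}: import aborted"
                )
            merged = dict(edits or {})
            merged.update(user_edits or {})
            approved[assay_id] = approve_conversion(cmap, merged)

    # conversion, replicate resolution, QC
    callsets = [apply_conversion(plates, study, cmap) for cmap in approved.values()]
    if store is not None:
        for cs in callsets:
            if store.has_result(study.name, group, cs.snp_id) and not overwrite:
                raise NameCollisionError(
                    f"result {group}/{cs.snp_id} already exists (use overwrite)"
                )
    matrix = build_genotype_matrix(study, callsets, majority_vote=majority_vote)

    results: list[ImportedResult] = []
    for cs in callsets:
        groups = collect_replicates(cs)
        report = build_qc_report(
            cs.snp_id, matrix[cs.snp_id], groups,
            alleles=cs.alleles, study=study, operator=operator, comment=comment,
        )
        results.append(ImportedResult(cs, report, approved[cs.assay_id], group))

    # atomic persist: stage everything, then move into place
    if store is not None:
        staging = store.root / f".staging-{uuid.uuid4().hex[:8]}"
        try:
            for res in results:
                store._write_result(staging / _safe_name(res.callset.snp_id), res)
            for res in results:
                rdir = store._result_dir(study.name, group, res.callset.snp_id)
                if rdir.exists():
                    shutil.rmtree(rdir)
                rdir.parent.mkdir(parents=True, exist_ok=True)
                shutil.move(str(staging / _safe_name(res.callset.snp_id)), str(rdir))
        finally:
            shutil.rmtree(staging, ignore_errors=True)
    return results


# ---------------------------------------------------------------------------
# configuration


def load_config(path: Union[str, Path]) -> dict[str, str]:
    """Read a simple key=value configuration file ('#' comments allowed)."""
    config: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, _, value = line.partition("=")
        config[key.strip()] = value.strip()
    return config


def rebuild_matrix(store: ProjectStore, study: StudyDefinition,
                   selection: Sequence[tuple[str, str]]) -> "pd.DataFrame":
    """Re-assemble the genotype matrix for stored (group, snp) results."""
    callsets = [store.load_result(study.name, g, s).callset for g, s in selection]
    return build_genotype_matrix(study, callsets)
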