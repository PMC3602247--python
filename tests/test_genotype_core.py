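"""Genotype normalisation, conversion maps, replicates, the matrix."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpqc.errors import (
    AmbiguousAssayError,
    CheckpointError,
    IncompleteMapError,
    InvalidAlleleError,
    NameCollisionError,
    StaleMapError,
)
from snpqc.genotype_core import (
    Genotype,
    ReplicateStatus,
    SampleCall,
    SNPCallSet,
    apply_conversion,
    approve_conversion,
    build_genotype_matrix,
    collect_replicates,
    infer_conversion_map,
    normalize_genotype,
    resolve_replicates,
)
from snpqc.plate_io import Dialect, PlateResult, RawCall, WellAddress
from snpqc.study import create_study

_bases = st.sampled_from("ACGT")


class TestGenotype:
    def test_allele_order_canonicalized(self):
        assert str(normalize_genotype("GA")) == "A/G"
        assert str(normalize_genotype("AA")) == "A/A"

    def test_missing_forms(self):
        for text in ("", "0/0", "00", "0"):
            assert normalize_genotype(text).is_missing

    def test_invalid_allele_rejected(self):
        with pytest.raises(InvalidAlleleError):
            normalize_genotype("AN")

    @given(_bases, _bases)
    @settings(deadline=None)
    def test_symmetric_and_idempotent(self, a, b):
        g = Genotype.from_alleles(a, b)
        assert g == Genotype.from_alleles(b, a)
        assert normalize_genotype(str(g)) == g


def _sds_calls(tokens, assay="rs328"):
    return [RawCall(WellAddress("A", i + 1), f"S{i:03d}", assay, t)
            for i, t in enumerate(tokens)]


class TestInferConversion:
    def test_sds_detector_semantics(self):
        cmap = infer_conversion_map(
            _sds_calls(["rs328_C", "rs328_G", "Both", "Undetermined"]),
            "rs328", Dialect.SDS,
        )
        mapped = {t: str(g) for t, g in cmap.mapping.items()}
        assert mapped == {"rs328_C": "C/C", "rs328_G": "G/G",
                          "Both": "C/G", "Undetermined": "0/0"}
        assert not cmap.approved

    def test_typer_direct_reading(self):
        calls = [RawCall(WellAddress("A", i + 1), f"S{i}", "rs1", t)
                 for i, t in enumerate(["A", "AG", "G", ""])]
        cmap = infer_conversion_map(calls, "rs1", Dialect.TYPER)
        assert {t: str(g) for t, g in cmap.mapping.items()} == {
            "A": "A/A", "AG": "A/G", "G": "G/G", "": "0/0"}

    def test_nonconformant_sds_detectors_stay_unmapped(self):
        cmap = infer_conversion_map(
            _sds_calls(["probeFAM", "probeVIC", "Both"], assay="rs1"), "rs1", Dialect.SDS)
        assert set(cmap.unmapped_tokens) == {"probeFAM", "probeVIC", "Both"}

    def test_wrong_detector_count_is_ambiguous(self):
        with pytest.raises(AmbiguousAssayError):
            infer_conversion_map(_sds_calls(["rs1_A", "rs1_C", "rs1_G"], assay="rs1"),
                                 "rs1", Dialect.SDS)


class TestApprove:
    def test_complete_map_approves(self):
        cmap = infer_conversion_map(_sds_calls(["rs328_C", "rs328_G", "Both"]),
                                    "rs328", Dialect.SDS)
        assert approve_conversion(cmap).approved

    def test_unmapped_token_blocks_approval(self):
        cmap = infer_conversion_map(_sds_calls(["probeFAM", "probeVIC"], assay="rs1"),
                                    "rs1", Dialect.SDS)
        with pytest.raises(IncompleteMapError):
            approve_conversion(cmap)

    def test_manual_edits_complete_and_override(self):
        cmap = infer_conversion_map(
            _sds_calls(["probeFAM", "probeVIC", "Both"], assay="rs1"), "rs1", Dialect.SDS)
        approved = approve_conversion(
            cmap, {"probeFAM": "A/A", "probeVIC": "G/G", "Both": "0/0"})
        assert approved.approved
        assert approved.mapping["Both"].is_missing  # user override wins


class TestApplyConversion:
    @pytest.fixture()
    def setup(self):
        study = create_study("s", [f"S{i:03d}" for i in range(4)])
        tokens = ["rs1_A", "rs1_G", "Both", "Undetermined"]
        plate = PlateResult("p1", Dialect.SDS, _sds_calls(tokens, assay="rs1"))
        cmap = infer_conversion_map(plate.calls, "rs1", Dialect.SDS)
        return study, plate, cmap

    def test_unapproved_map_refused(self, setup):
        study, plate, cmap = setup
        with pytest.raises(CheckpointError):
            apply_conversion([plate], study, cmap)

    def test_cardinality_and_missing_kept(self, setup):
        study, plate, cmap = setup
        callset = apply_conversion([plate], study, approve_conversion(cmap))
        assert len(callset.calls) == 4  # every retained well, no-calls included
        genotypes = {c.sample_id: str(c.genotype) for c in callset.calls}
        assert genotypes["S003"] == "0/0"

    def test_non_sample_wells_excluded(self, setup):
        study, plate, cmap = setup
        plate.calls.append(RawCall(WellAddress("B", 1), "NTC", "rs1", "Undetermined"))
        callset = apply_conversion([plate], study, approve_conversion(cmap))
        assert all(c.sample_id.startswith("S") for c in callset.calls)

    def test_stale_token_detected(self, setup):
        study, plate, cmap = setup
        approved = approve_conversion(cmap)
        plate.calls.append(RawCall(WellAddress("B", 2), "S001", "rs1", "rs1_C"))
        with pytest.raises(StaleMapError):
            apply_conversion([plate], study, approved)


def _callset(calls):
    return SNPCallSet("rs1", "rs1", [
        SampleCall(s, "p1",
                   WellAddress("ABCDEFGHIJKLMNOP"[i // 24], i % 24 + 1),
                   normalize_genotype(g))
        for i, (s, g) in enumerate(calls)
    ])


class TestReplicates:
    @pytest.mark.parametrize(
        "genotypes,status",
        [(["A/G", "A/G"], ReplicateStatus.CONCORDANT),
         (["A/G", "G/G"], ReplicateStatus.DISCORDANT),
         (["A/G", "0/0"], ReplicateStatus.UNRESOLVED),
         (["0/0", "0/0"], ReplicateStatus.UNRESOLVED),
         (["A/G"], ReplicateStatus.SINGLE),
         (["A/G", "A/G", "G/G"], ReplicateStatus.DISCORDANT)],
    )
    def test_status_assignment(self, genotypes, status):
        groups = collect_replicates(_callset([("S1", g) for g in genotypes]))
        assert len(groups) == 1 and groups[0].status is status

    @pytest.mark.parametrize(
        "genotypes,resolved",
        [(["A/G", "A/G"], "A/G"), (["A/G", "G/G"], "0/0"),
         (["A/G", "0/0"], "A/G"), (["0/0", "0/0"], "0/0"), (["A/A"], "A/A")],
    )
    def test_conservative_resolution(self, genotypes, resolved):
        groups = collect_replicates(_callset([("S1", g) for g in genotypes]))
        assert str(resolve_replicates(groups[0])) == resolved

    def test_majority_vote_option(self):
        groups = collect_replicates(
            _callset([("S1", "A/G"), ("S1", "A/G"), ("S1", "G/G")]))
        assert str(resolve_replicates(groups[0])) == "0/0"
        assert str(resolve_replicates(groups[0], majority_vote=True)) == "A/G"

    def test_statuses_partition_samples(self, defect_truth):
        """single+concordant+discordant+unresolved = distinct sample IDs."""
        calls = [(s, defect_truth.truth.at[s, "rs328"])
                 for s in defect_truth.truth.index[:50]]
        calls += [(s, g) for s, g in calls[:5]]  # duplicate a few
        groups = collect_replicates(_callset(calls))
        assert len(groups) == len({s for s, _ in calls})


class TestMatrix:
    def test_rows_cover_full_manifest(self):
        study = create_study("s", ["S1", "S2", "S3"])
        cs = _callset([("S1", "A/G"), ("S2", "0/0")])
        matrix = build_genotype_matrix(study, [cs])
        assert list(matrix.index) == ["S1", "S2", "S3"]
        assert matrix.at["S3", "rs1"] == "0/0"  # absent sample, missing code

    def test_duplicate_snp_id_collides(self):
        study = create_study("s", ["S1"])
        with pytest.raises(NameCollisionError):
            build_genotype_matrix(study, [_callset([("S1", "A/G")]),
                                          _callset([("S1", "A/A")])])

    def test_empty_callset_list(self):
        study = create_study("s", ["S1", "S2"])
        matrix = build_genotype_matrix(study, [])
        assert matrix.shape == (2, 0)

    def test_discordant_groups_resolve_missing_in_matrix(self, defect_truth,
                                                         sds_fixture, defect_study):
        from snpqc.pipeline import run_import

        results = run_import(None, defect_study, sds_fixture.plates_zip,
                             auto_approve=True)
        matrix = build_genotype_matrix(defect_study, [r.callset for r in results])
        for sample in defect_truth.defects.discordant_ids:
            assert matrix.at[sample, "rs328"] == "0/0"
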