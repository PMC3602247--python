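"""Truth-known synthetic studies written as plate files.

The generator emulates the raw material of a plate-based genotyping
project: a sample manifest, per-SNP genotypes drawn under Hardy-Weinberg
equilibrium (or a stated inbreeding-style departure), a replicate plan,
control wells on every plate, and an injectable set of realistic defects —
discordant replicate pairs, no-call wells, mislabelled (unknown-ID) wells,
and manifest samples missing from every plate. The truth is fully
reproducible from (parameters, seed) and every defect is recorded in an
exact ledger, so pipeline outputs can be checked record-for-record.

Randomness uses one seed with explicit per-purpose sub-streams (genotypes,
replicate selection, each defect type, reference counts, sex), so changing
one defect count never shifts the other draws.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_core import Genotype, MISSING_CODE
from .plate_io import Dialect
from .sex_check import Sex

__all__ = [
    "SnpSpec",
    "Occurrence",
    "DefectLedger",
    "TruthStudy",
    "FixturePaths",
    "generate_truth",
    "inject_defects",
    "write_fixture",
    "REFERENCE_POPULATIONS",
]

# (population label, source, diploid sample count) — sizes follow the
# familiar reference panels: ~90 for the HapMap trios panels, several
# hundred for a 1000 Genomes super-population.
REFERENCE_POPULATIONS: tuple[tuple[str, str, int], ...] = (
    ("CEU", "HAPMAP", 90),
    ("YRI", "HAPMAP", 90),
    ("EUR", "KG", 379),
)

PLATE_ROWS = "ABCDEFGHIJKLMNOP"
PLATE_COLUMNS = 24


@dataclass(frozen=True)
class SnpSpec:
    """One simulated SNP: allele pair, minor-allele frequency, HWE flag.

    ``maf`` is the frequency of ``alleles[1]`` (the designated minor
    allele). With ``hwe=False`` genotypes are drawn with an inbreeding-style
    heterozygote deficit of coefficient ``inbreeding_f``:
    P(het) = 2pq(1-F), homozygotes gain Fpq each.
    """

    snp_id: str
    alleles: tuple[str, str]
    maf: float
    hwe: bool = True
    inbreeding_f: float = 0.0


@dataclass
class Occurrence:
    """One plated well-occurrence, in plate order."""

    sample_id: str          # label as plated (may be an unknown ID after defects)
    true_sample_id: str     # manifest identity ("" for injected unknowns)
    is_replicate: bool = False
    nocall: bool = False                       # well produced no data
    overrides: dict[str, str] = field(default_factory=dict)  # snp_id -> genotype


@dataclass
class DefectLedger:
    discordant_ids: list[str] = field(default_factory=list)
    nocall_ids: list[str] = field(default_factory=list)
    unknown_id_wells: list[tuple[str, str]] = field(default_factory=list)  # (new label, true sample)
    absent_ids: list[str] = field(default_factory=list)
    sex_mismatch_ids: list[str] = field(default_factory=list)


@dataclass
class TruthStudy:
    """A fully known synthetic study plus its defect ledger."""

    manifest: list[str]
    snps: list[SnpSpec]
    truth: pd.DataFrame             # manifest x SNP canonical genotype strings
    occurrences: list[Occurrence]   # plate order
    sex_truth: dict[str, Sex]
    seed: int
    sex_snp_id: Optional[str] = None
    defects: DefectLedger = field(default_factory=DefectLedger)

    @property
    def replicated_ids(self) -> list[str]:
        return [o.true_sample_id for o in self.occurrences if o.is_replicate]


def _substream(seed: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(purpose,)))


def _draw_genotypes(rng: np.random.Generator, spec: SnpSpec, n: int) -> list[str]:
    q = spec.maf
    p = 1.0 - q
    f = 0.0 if spec.hwe else spec.inbreeding_f
    probs = np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])
    probs = probs / probs.sum()
    a, b = spec.alleles
    genos = [str(Genotype.from_alleles(a, a)),
             str(Genotype.from_alleles(a, b)),
             str(Genotype.from_alleles(b, b))]
    draws = rng.choice(3, size=n, p=probs)
    return [genos[i] for i in draws]


def generate_truth(
    n_samples: int,
    snps: Sequence[SnpSpec],
    replicate_fraction: float = 0.1,
    seed: int = 0,
    *,
    sex_snp_id: Optional[str] = None,
    sample_prefix: str = "S",
) -> TruthStudy:
    """Generate a defect-free truth study.

    Samples are named ``S0001``..; a ``replicate_fraction`` of them is
    plated twice, the replicate wells appended after the primary block.
    With ``sex_snp_id`` an amelogenin-style sex marker is added whose
    genotype is A/A for females and A/G for males.
    """
    if not 0 <= replicate_fraction <= 1:
        raise ValueError("replicate_fraction outside [0, 1]")
    for spec in snps:
        if not 0 <= spec.maf <= 0.5:
            raise ValueError(f"{spec.snp_id}: maf outside [0, 0.5]")

    manifest = [f"{sample_prefix}{i + 1:04d}" for i in range(n_samples)]
    rng_geno = _substream(seed, 0)
    rng_repl = _substream(seed, 1)
    rng_sex = _substream(seed, 6)

    sex_truth = {
        s: (Sex.MALE if male else Sex.FEMALE)
        for s, male in zip(manifest, rng_sex.random(n_samples) < 0.5)
    }

    columns: dict[str, list[str]] = {}
    snp_list = list(snps)
    for spec in snp_list:
        columns[spec.snp_id] = _draw_genotypes(rng_geno, spec, n_samples)
    if sex_snp_id is not None:
        snp_list.append(SnpSpec(sex_snp_id, ("A", "G"), 0.5))
        columns[sex_snp_id] = [
            "A/G" if sex_truth[s] is Sex.MALE else "A/A" for s in manifest
        ]
    truth = pd.DataFrame(columns, index=manifest, dtype=object)
    truth.index.name = "sample_id"

    n_replicates = int(round(replicate_fraction * n_samples))
    replicated = sorted(rng_repl.choice(n_samples, size=n_replicates, replace=False))
    occurrences = [Occurrence(s, s) for s in manifest]
    occurrences += [Occurrence(manifest[i], manifest[i], is_replicate=True)
                    for i in replicated]
    return TruthStudy(
        manifest=manifest,
        snps=snp_list,
        truth=truth,
        occurrences=occurrences,
        sex_truth=sex_truth,
        seed=seed,
        sex_snp_id=sex_snp_id,
    )


def _other_genotype(genotype: str, alleles: tuple[str, str],
                    rng: np.random.Generator) -> str:
    a, b = alleles
    pool = [str(Genotype.from_alleles(a, a)), str(Genotype.from_alleles(a, b)),
            str(Genotype.from_alleles(b, b))]
    pool = [g for g in pool if g != genotype]
    return pool[int(rng.integers(len(pool)))]


def inject_defects(
    truth: TruthStudy,
    k_discordant: int = 0,
    k_nocall: int = 0,
    k_unknown_ids: int = 0,
    k_absent: int = 0,
    seed: Optional[int] = None,
    *,
    k_sex_mismatch: int = 0,
) -> TruthStudy:
    """Return a copy of the truth with exactly the requested defects.

    Discordant pairs and unknown-ID relabels draw from *replicated*
    samples (disjoint sets): a discordant sample's replicate well gets a
    different non-missing genotype on every SNP; an unknown-ID sample's
    replicate well is relabelled with an out-of-manifest ID, so the sample
    itself still appears once and only ``k_absent`` manifest samples end
    up missing. No-calls and absences draw from disjoint singleton
    samples. Infeasible counts raise ValueError.
    """
    seed = truth.seed if seed is None else seed
    occurrences = [replace(o, overrides=dict(o.overrides)) for o in truth.occurrences]
    ledger = DefectLedger()

    replicate_positions = [i for i, o in enumerate(occurrences) if o.is_replicate]
    singleton_ids = [o.true_sample_id for o in occurrences
                     if not o.is_replicate and o.true_sample_id not in
                     {occurrences[j].true_sample_id for j in replicate_positions}]

    if k_discordant + k_unknown_ids > len(replicate_positions):
        raise ValueError("not enough replicated samples for the requested defects")
    if k_nocall + k_absent > len(singleton_ids):
        raise ValueError("not enough singleton samples for the requested defects")

    rng_disc = _substream(seed, 2)
    rng_nocall = _substream(seed, 3)
    rng_unknown = _substream(seed, 4)
    rng_absent = _substream(seed, 5)
    rng_sexmm = _substream(seed, 7)

    chosen_rep = rng_disc.choice(len(replicate_positions),
                                 size=k_discordant + k_unknown_ids, replace=False)
    discordant_pos = [replicate_positions[i] for i in chosen_rep[:k_discordant]]
    unknown_pos = [replicate_positions[i] for i in chosen_rep[k_discordant:]]

    alleles_by_snp = {s.snp_id: s.alleles for s in truth.snps}
    for pos in discordant_pos:
        occ = occurrences[pos]
        for snp_id in truth.truth.columns:
            occ.overrides[snp_id] = _other_genotype(
                truth.truth.at[occ.true_sample_id, snp_id],
                alleles_by_snp[snp_id], rng_disc,
            )
        ledger.discordant_ids.append(occ.true_sample_id)

    for i, pos in enumerate(unknown_pos):
        occ = occurrences[pos]
        label = f"X-UNKNOWN-{i + 1:02d}"
        ledger.unknown_id_wells.append((label, occ.true_sample_id))
        occurrences[pos] = replace(occ, sample_id=label, true_sample_id="",
                                   is_replicate=False)
    _ = rng_unknown  # reserved sub-stream: relabel targets come from rng_disc's split

    chosen_single = rng_nocall.choice(len(singleton_ids),
                                      size=k_nocall, replace=False)
    nocall_ids = {singleton_ids[i] for i in chosen_single}
    remaining = [s for s in singleton_ids if s not in nocall_ids]
    absent_idx = rng_absent.choice(len(remaining), size=k_absent, replace=False)
    absent_ids = {remaining[i] for i in absent_idx}

    kept: list[Occurrence] = []
    for occ in occurrences:
        if occ.true_sample_id in absent_ids:
            continue
        if occ.true_sample_id in nocall_ids:
            occ = replace(occ, nocall=True)
        kept.append(occ)
    ledger.nocall_ids = sorted(nocall_ids)
    ledger.absent_ids = sorted(absent_ids)

    if k_sex_mismatch:
        candidates = [s for s in truth.manifest
                      if s not in absent_ids and s not in nocall_ids]
        idx = rng_sexmm.choice(len(candidates), size=k_sex_mismatch, replace=False)
        ledger.sex_mismatch_ids = sorted(candidates[i] for i in idx)

    return replace(truth, occurrences=kept, defects=ledger)


# ---------------------------------------------------------------------------
# writing fixture files


@dataclass
class FixturePaths:
    plate_files: list[Path]
    plates_zip: Path
    manifest: Path
    reference_table: Path
    sex_phenotypes: Path


def _well_label(index_in_plate: int) -> str:
    row = PLATE_ROWS[index_in_plate // PLATE_COLUMNS]
    col = index_in_plate % PLATE_COLUMNS + 1
    return f"{row}{col}"


def _layout(truth: TruthStudy, plate_capacity: int,
            controls_per_plate: int = 2) -> list[list[tuple[str, Occurrence]]]:
    """Assign occurrences to plates row-major, controls heading each plate."""
    usable = plate_capacity - controls_per_plate
    if usable <= 0:
        raise ValueError("plate capacity leaves no room for sample wells")
    plates: list[list[tuple[str, Occurrence]]] = []
    for start in range(0, len(truth.occurrences), usable):
        chunk = truth.occurrences[start:start + usable]
        wells: list[tuple[str, Occurrence]] = []
        controls = [Occurrence("NTC", "", nocall=True), Occurrence("PC", "")]
        for i, occ in enumerate(controls[:controls_per_plate] + chunk):
            wells.append((_well_label(i), occ))
        plates.append(wells)
    return plates


def _occurrence_genotype(truth: TruthStudy, occ: Occurrence, snp_id: str) -> str:
    if occ.nocall:
        return MISSING_CODE
    if snp_id in occ.overrides:
        return occ.overrides[snp_id]
    if occ.true_sample_id and occ.true_sample_id in truth.truth.index:
        return truth.truth.at[occ.true_sample_id, snp_id]
    # control or unknown-ID well: controls yield no call, mislabelled wells
    # still carry a real genotype (drawn from the relabelled sample is gone,
    # so draw a deterministic heterozygote-free default: the major homozygote)
    spec = next(s for s in truth.snps if s.snp_id == snp_id)
    return str(Genotype.homozygous(spec.alleles[0]))


def _sds_token(snp_id: str, alleles: tuple[str, str], genotype: str) -> str:
    g = Genotype.from_string(genotype)
    if g.is_missing:
        return "Undetermined"
    if g.is_het:
        return "Both"
    return f"{snp_id}_{g.allele1}"


def _typer_token(genotype: str) -> str:
    g = Genotype.from_string(genotype)
    if g.is_missing:
        return ""
    return "".join(g.alleles)


def write_fixture(
    truth: TruthStudy,
    dialect: Dialect = Dialect.SDS,
    plate_capacity: int = 384,
    path: Path | str = ".",
) -> FixturePaths:
    """Write the truth study as plate files plus manifest/reference/sex files.

    SDS: one file per plate per SNP (detector names ``<snp>_<allele>``,
    heterozygotes as "Both", no-calls as "Undetermined"). TYPER: a single
    multi-plate multi-assay file with genotypes as base strings and the
    empty string for no-calls. A zip of all plate files is always written
    alongside. The reference table draws per-population genotype counts
    under HWE at each SNP's truth MAF; the sex phenotype file follows the
    sex truth with the ledger's mismatches flipped.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    plates = _layout(truth, plate_capacity)
    dialect = Dialect(dialect)
    plate_files: list[Path] = []

    autosomal = [s for s in truth.snps]
    if dialect is Dialect.SDS:
        for p, wells in enumerate(plates, start=1):
            for spec in autosomal:
                fp = root / f"plate{p:02d}_{spec.snp_id}.csv"
                lines = ["# synthetic allelic-discrimination export",
                         "Well,Sample Name,Marker,Call"]
                for well, occ in wells:
                    geno = _occurrence_genotype(truth, occ, spec.snp_id)
                    token = _sds_token(spec.snp_id, spec.alleles, geno)
                    lines.append(f"{well},{occ.sample_id},{spec.snp_id},{token}")
                fp.write_text("\n".join(lines) + "\n", encoding="utf-8")
                plate_files.append(fp)
    else:
        fp = root / "typer_plates.tsv"
        lines = ["Plate\tWell\tSample Id\tAssay Id\tGenotype"]
        for p, wells in enumerate(plates, start=1):
            for well, occ in wells:
                for spec in autosomal:
                    geno = _occurrence_genotype(truth, occ, spec.snp_id)
                    lines.append(
                        f"P{p:02d}\t{well}\t{occ.sample_id}\t{spec.snp_id}\t"
                        f"{_typer_token(geno)}"
                    )
        fp.write_text("\n".join(lines) + "\n", encoding="utf-8")
        plate_files.append(fp)

    plates_zip = root / "plates.zip"
    with zipfile.ZipFile(plates_zip, "w") as zf:
        for fp in plate_files:
            zf.write(fp, arcname=fp.name)

    manifest_path = root / "manifest.txt"
    manifest_path.write_text(
        "# sample manifest\n" + "\n".join(truth.manifest) + "\n", encoding="utf-8"
    )

    reference_path = root / "reference.tsv"
    rng_ref = _substream(truth.seed, 8)
    ref_lines = ["\t".join(["snp_id", "population", "source", "allele_a",
                            "allele_b", "n_AA", "n_AB", "n_BB"])]
    for spec in truth.snps:
        if spec.snp_id == truth.sex_snp_id:
            continue  # sex markers are not in population panels
        q = spec.maf
        p = 1.0 - q
        for population, source, n in REFERENCE_POPULATIONS:
            counts = rng_ref.multinomial(n, [p * p, 2 * p * q, q * q])
            ref_lines.append("\t".join([
                spec.snp_id, population, source, spec.alleles[0], spec.alleles[1],
                str(counts[0]), str(counts[1]), str(counts[2]),
            ]))
    reference_path.write_text("\n".join(ref_lines) + "\n", encoding="utf-8")

    sex_path = root / "sex_phenotypes.tsv"
    mismatch = set(truth.defects.sex_mismatch_ids)
    token = {Sex.MALE: "m", Sex.FEMALE: "f"}
    flip = {Sex.MALE: Sex.FEMALE, Sex.FEMALE: Sex.MALE}
    sex_lines = ["sample_id\tsex"]
    for sample in truth.manifest:
        sex = truth.sex_truth[sample]
        if sample in mismatch:
            sex = flip[sex]
        sex_lines.append(f"{sample}\t{token[sex]}")
    sex_path.write_text("\n".join(sex_lines) + "\n", encoding="utf-8")

    return FixturePaths(
        plate_files=plate_files,
        plates_zip=plates_zip,
        manifest=manifest_path,
        reference_table=reference_path,
        sex_phenotypes=sex_path,
    )
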