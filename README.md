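# snpqc

Batch processing, merging and quality control of plate-based SNP
genotyping exports.

Targeted SNP genotyping on 384-well microplates — endpoint allelic
discrimination (TaqMan/KASPar-style) and multiplexed single-base-extension
with mass-spectrometric readout (iPLEX-style) — produces one export file
per plate in a vendor dialect, with raw calls that still have to be
merged, mapped to genotypes, checked and reformatted before any analysis.
Doing this by hand in a spreadsheet is where genotyping studies go wrong:
files get concatenated in the wrong order, detector labels get swapped,
duplicated samples are never actually compared. `snpqc` is a small batch
tool for wet labs that automates exactly this stretch of the pipeline,
from raw plate files to a merged, QC'd genotype matrix, with two explicit
user checkpoints (which wells to drop, how to convert raw calls) so that
nothing silently changes the data.

## What it computes

For each SNP assay, over the full study manifest (samples absent from
every plate file count as missing — leaving them out would inflate the
call rate):

- **call rate** = called / (called + missing), controls excluded;
- **replicates**: samples plated ≥2 times are detected automatically from
  repeated IDs; *expected* counts plated replicates, *real* counts those
  with ≥2 usable calls, and a group whose usable calls disagree is one
  *discordant* replicate (discordance rate = discordant / real). Discordant
  replicates resolve to the missing genotype — the tool never fabricates a
  call;
- **minor allele frequency** (MAF) with the minor allele, from genotype
  counts *(n_AA, n_AB, n_BB)*;
- **Hardy-Weinberg equilibrium**: Pearson chi-square with 1 df comparing
  *(n_AA, n_AB, n_BB)* against *(n p̂², 2n p̂q̂, n q̂²)* where
  p̂ = (2n_AA + n_AB)/2n; monomorphic SNPs report an undefined p-value;
- **reference-population plausibility**: a 2×3 Pearson chi-square of the
  user's genotype counts against a local table of per-population counts
  (HapMap-panel / 1000 Genomes-super-population style), after allele
  harmonisation (swap, strand flip, palindromic-SNP warning). A strong
  deviation from the matching ancestry catches inverted detector labels
  that pass call rate and HWE;
- **sex concordance**: genotypes of an X/Y marker (amelogenin, ZFX/ZFY …)
  mapped to sex by a user-supplied assignment and compared with expected
  phenotypic sex; only the discordances are ever stored.

Exports: per-SNP and merged genotype lists and QC reports as CSV or XLSX
(text-typed cells, threshold highlighting, undefined values as `NA`),
population-comparison tables, and PLINK PED/MAP.

## Worked example

Generate a synthetic 200-sample study (one SNP at MAF 0.3, 10%
replicates, with 3 discordant pairs, 5 no-call wells, 2 mislabelled wells
and 1 absent sample injected) and run it through the pipeline:

```python
from pathlib import Path
from snpqc.fixtures import SnpSpec, generate_truth, inject_defects, write_fixture

truth = generate_truth(200, [SnpSpec("rs328", ("A", "G"), 0.3)],
                       replicate_fraction=0.1, seed=42)
truth = inject_defects(truth, k_discordant=3, k_nocall=5,
                       k_unknown_ids=2, k_absent=1, seed=42)
write_fixture(truth, "SDS", path=Path("fixture"))
```

```sh
$ snpqc --store proj init-study lipase fixture/manifest.txt --replicates 20
study 'lipase': 200 samples

$ snpqc --store proj import lipase fixture/plates.zip --group taqman \
        --operator "M. Weiss" --auto-approve
taqman/rs328: call rate 0.955, MAF 0.348168 (G), replicates 18/18, \
discordant 3, HWE p 0.492407

$ snpqc --store proj compare lipase taqman rs328 --reference fixture/reference.tsv
CEU (HAPMAP, direct): chi2 7.16297, df 2, p 0.0278344
YRI (HAPMAP, direct): chi2 0.250819, df 2, p 0.882136
EUR (KG, direct): chi2 2.10364, df 2, p 0.349301
```

Reading the output: 191 of the 200 manifest samples got a usable genotype
(the absent sample, the 5 no-call wells and the 3 discordant replicates
are all missing, hence 0.955); 18 replicate pairs survived on the plates
(two were relabelled as unknown wells and removed at checkpoint 1) and
exactly the 3 injected discordant pairs are flagged; HWE is clean. The
population chi-squares compare the observed counts with each reference
panel — here only CEU drifts, as this particular seeded panel draw sits
farther from the sample.

Without `--auto-approve` the import pauses at both checkpoints, printing
the removal list and the per-assay token→genotype conversion map for
confirmation, exactly as a technician would review them.

A sex-marker run on a 100-sample study with two deliberately flipped
phenotype records:

```sh
$ snpqc --store proj2 sex-check sexdemo amel AMEL \
        --phenotypes sexfix/sex_phenotypes.tsv \
        --coding m=male --coding f=female \
        --assignment A/A=female --assignment A/G=male
discordant 2, concordant 98, unknown 0, missing phenotype 0
  S0026: genotypic male, phenotypic female
  S0039: genotypic male, phenotypic female
```

## Layout

- `src/snpqc/plate_io.py` — plate dialects, zip archives, detector names
- `src/snpqc/study.py` — manifests, controls, removal proposals
- `src/snpqc/genotype_core.py` — conversion maps, replicates, the matrix
- `src/snpqc/qc_stats.py` — call rate, MAF, replicate summary, HWE
- `src/snpqc/pop_compare.py` — allele harmonisation, population chi-square
- `src/snpqc/sex_check.py` — sex-marker concordance
- `src/snpqc/report_export.py` — CSV/XLSX/PED+MAP export, highlighting
- `src/snpqc/fixtures.py` — truth-known synthetic studies
- `src/snpqc/pipeline.py` — import wizard, project store
- `src/snpqc/cli.py` — the `snpqc` command

See `docs/methods.md` for the statistical model, parameter defaults and
design decisions.
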