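# Methods

## The processing model

`snpqc` models a targeted genotyping project as a *study*: an ordered
manifest of sample IDs, a declared replicate count, and token sets naming
control wells (defaults `NTC`, `PC`) and annulled samples (default `ER` —
DNA known to be flawed, relabelled on the plate so no data is collected).
Raw data arrives as plate exports in one of two delimiter-separated
dialects:

- **SDS** (endpoint allelic discrimination): one file per plate, header
  `Well,Sample Name,Marker,Call`, one row per well and marker. The call is
  a per-allele detector name for homozygotes, `Both` for heterozygotes,
  `Undetermined` for no-calls.
- **TYPER** (multiplexed mass-spectrometry typing): one file spanning
  plates and assays, header `Plate,Well,Sample Id,Assay Id,Genotype`,
  genotypes as plain base strings (`A`, `AG`) and the empty string for
  no-calls.

These are documented fixture dialects carrying the information real
vendor exports carry (well, sample, assay, call); other vendor variants
are future adapters behind the same reader interface. Files may be zipped;
all members of one archive must share a dialect.

Processing runs as a four-step wizard with two mandatory checkpoints:

1. parse and merge the plate files;
2. **checkpoint 1** — every well whose ID is not a study sample (control,
   annulled, unknown) is proposed for removal, once per well, and must be
   confirmed;
3. infer per-assay conversion maps and have each approved
   (**checkpoint 2**), then convert every retained well to a normalised
   genotype;
4. resolve replicates, assemble the genotype matrix, compute the QC
   report, persist.

A refusal at either checkpoint aborts with the store untouched.

## Genotype conversion

Genotypes are unordered allele pairs stored alphabetically (`A/G`), with
`0/0` as the missing code — chosen for an unambiguous round-trip to PLINK
PED. For SDS assays the two detector names are parsed with the
`<arbitrary name>_<allele>` convention, split on the *last* underscore so
assay names may themselves contain underscores; each detector token maps
to the homozygote of its allele, `Both` to the heterozygote,
`Undetermined` to missing. Non-conformant detector names (and any odd
TYPER token) are left unmapped and must be completed by hand before the
map can be approved — automation never guesses. An SDS assay exposing a
number of detector tokens other than two is rejected as ambiguous.

Sample-ID matching against the manifest is exact and case-sensitive after
whitespace stripping (silent case-folding can merge distinct IDs); a
study-level switch enables case-insensitive matching, and another enables
prefix matching of control tokens (`NTC1`, `NTC2`, …).

## Replicates

Replicates are detected purely from repeated sample IDs in a call set —
no naming convention. A sample's wells form one group with status
*single* (1 well), *concordant* (≥2 usable calls, all equal),
*discordant* (≥2 usable calls, unequal) or *unresolved* (≥2 wells, <2
usable calls). The QC report counts groups, not pairs: a triplicate with
one deviant call is one discordant replicate. *Expected* = groups with ≥2
wells, *real* = groups with ≥2 usable calls, discordance rate =
discordant/real (undefined at real = 0). Discordant groups resolve to the
missing genotype; a majority-vote alternative exists behind a flag (off
by default) because the conservative rule never fabricates a genotype.
The declared study-level replicate count is cross-checked against the
detected count and a mismatch is a warning, not an error.

## Statistics

All statistics for a SNP are computed over the unique samples of the
full manifest — a manifest sample absent from every plate file counts in
the call-rate denominator as missing, since dropping it would silently
inflate the call rate. Undefined statistics are `None` in memory and the
literal `NA` in every export, never 0.

**HWE.** Pearson chi-square, 1 df, no continuity correction (Yates
available behind a flag; an exact test is an explicit extension point).
With n called genotypes and p̂ = (2n_AA + n_AB)/2n, expected counts are
(n p̂², 2n p̂q̂, n q̂²) and X² = Σ(obs − exp)²/exp; the p-value is the
upper tail of χ²₁ (scipy). Monomorphic SNPs give X² = 0 with an
undefined p-value.

**MAF.** freq(allele₁) = (2n_AA + n_AB)/2n, MAF = min(f, 1−f); a 0.5 tie
reports the alphabetically first allele as minor.

**Population comparison.** Observed counts vs. a reference population's
absolute genotype counts as a 2×3 contingency table, Pearson chi-square
without correction. The genotype-level (2×3) test is the default because
reference panels report absolute genotype numbers; an allele-level 2×2
variant would discard the genotype distribution. Columns whose total is
zero are dropped with df reduced to k−1 (no pooling rules invented);
fewer than two surviving columns, or an empty row, makes the test
undefined. An expected cell < 5 attaches a small-count warning. Before
testing, allele pairs are harmonised: equal sets compare directly (counts
reordered if the roles are swapped), sets equal after reverse complement
are strand-flipped, and palindromic A/T / C/G SNPs — where flip and swap
are indistinguishable — proceed as direct with an `ambiguous` flag.
Anything else is incompatible and gets no test. Lookups use the SNP's
alternate rs-number when one is set, covering IDs that changed between
dbSNP builds. Reference data is a local TSV
(`snp_id population source allele_a allele_b n_AA n_AB n_BB`); the tool
performs no network access.

**Sex check.** A designated X/Y-difference marker (amelogenin-style) is
mapped to sex by a user-supplied genotype→sex assignment — no built-in
defaults, since AMELX/AMELY, GYG2 and ZFX/ZFY assays encode sex
differently. Phenotype files use a free token coding supplied alongside.
Samples without a phenotype record count as `missing_phenotype`; called
but unassigned or missing genotypes as `unknown`; only samples with both
sexes known and unequal become discordance records, and only those
records are ever persisted — full phenotype files never enter the
genotype store. Replicates are resolved first, so a discordant sex-SNP
replicate is missing and hence `unknown`.

## The synthetic-study generator

`snpqc.fixtures` generates truth-known studies so the whole pipeline is
testable without any external data. Genotypes are drawn per SNP under
HWE (p², 2pq, q²) at the specified MAF, or with an inbreeding-style
heterozygote deficit (P(het) = 2pq(1−F)) when disequilibrium is wanted. A
fraction of samples (default 10%, a common lab duplication rate) is
plated twice; every plate carries an `NTC` and a `PC` well; wells are
assigned row-major on 384-well plates with overflow spilling to further
plates. Defects are injected with exact ledgers: discordant replicate
pairs (the replicate well gets a different non-missing genotype),
no-call wells, wells relabelled with out-of-manifest IDs, samples removed
from all plates, and flipped sex-phenotype records. Relabelled wells are
drawn from *replicated* samples so the victim sample still appears once —
otherwise a relabelling would also manufacture a missing sample and the
defect classes would confound each other. The reference table is drawn
multinomially under HWE at the truth MAF for three panels (CEU and YRI at
n = 90, HapMap-trio-panel scale; EUR at n = 379, super-population scale).
All randomness flows from one seed through fixed per-purpose sub-streams,
so changing one defect count never shifts the other draws.

What the generator does *not* emulate: raw fluorescence or mass spectra
(calls are taken as given), plate-position effects, contamination
gradients, genotyping error that is correlated with genotype, or
population structure. Passing tests therefore demonstrate that the
*bookkeeping and statistics* are correct on data whose truth is known,
not that any upstream calling algorithm is accurate.

## Storage and export

The project store is a versioned directory of JSON metadata and CSV call
tables (study definitions, per-result calls + QC + approved conversion
map, sex discordances), chosen over an embedded relational database
because the tool is single-user batch software and files are diff-able
and trivially backed up. Imports are atomic: results are staged and moved
into place only after every assay has converted. Spreadsheet exports
write every cell text-typed to block auto-conversion of genotypes and
identifiers into dates or numbers. Default highlight rules flag
`hwe_p < 0.05`, `call_rate < 0.95` and `discordance_rate > 0`; only the
first is a field-wide convention strong enough to hard-code, all three
are overridable.

## Problem sizes and verification

The test suite verifies the HWE chi-square against a brute-force oracle
exhaustively for all genotype triples with n ≤ 30, and the population
chi-square against a margins-based oracle exhaustively for all 2×3 tables
with cells ≤ 6, both to 1e-9. Type-I error of the HWE test is checked by
simulating 2,000 HWE-true studies of n = 500 at MAF 0.3 (rejection rate
within [0.03, 0.07] at α = 0.05). End-to-end defect recovery runs at
n = 200 with 3 discordant, 5 no-call, 2 relabelled and 1 absent defect;
merge invariance — one import versus four partial imports of the same
wells yielding identical statistics — is exercised at 20,000 samples,
the scale the tool is intended to handle in one run. The acceptance
script (`scripts/acceptance.py`) recomputes all of these from scratch
under a user-supplied seed.

## Known limitations

- Binary vendor files, cluster plots and raw intensities are out of
  scope; only the two text dialects are read.
- Strictly biallelic SNPs; a third observed allele is an error, not a
  degenerate case.
- The HWE test is asymptotic; at very small n or extreme MAF an exact
  test would be preferable (extension point, not implemented).
- Single-user store: concurrent writers are out of contract.
- No Mendelian/pedigree checks and no association testing — the tool ends
  where PLINK begins, which is why PED/MAP export exists.
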