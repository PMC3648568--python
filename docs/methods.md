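# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, and the numerical and design choices made where the
procedure left room.

## Differential tests

Per-feature contrasts of +QTL vs −QTL lines use a two-sample Welch *t* test
on log₂ intensities. Expression DEG calls use raw *p* < 0.001; genomic-DNA
differential-hybridization (single-feature polymorphism) calls use raw
*p* < 0.05. No multiplicity adjustment is applied at the feature level:
the downstream window and enrichment statistics are built on these raw
threshold decisions, and adjusting them would change the meaning of every
derived count. The two soil-drying severities (FTSW 0.5 and 0.2) are pooled
as replicates of the line contrast by default, because the contrast of
interest is line, not treatment; per-severity calls are available by
passing a single stress level.

The Welch test replaces a mixed-model array analysis whose design files
are not part of this package's inputs; it is declared, closed-form, and
oracle-checkable. Degenerate inputs: groups with zero variance and equal
means give *p* = 1; zero variance and unequal means give the smallest
positive float (so *p* ∈ (0, 1] always holds). At two or three replicates
per group the Welch test is conservative (its Satterthwaite degrees of
freedom are estimated); the calibration tests therefore compare observed
false-positive rates against the test's achievable size, measured by an
independent route, and additionally require they never exceed the nominal
level.

## Sliding-window aggregation

Windows of 1000 kb advance by 500 kb along each chromosome; windows are
clipped at chromosome ends rather than discarded, so every interior feature
contributes to exactly two windows. Features are assigned to windows by
midpoint. Each window's count of significant features is tested one-sided
against Binomial(n_w, p̂₀) with p̂₀ the genome-wide significant fraction;
windows with *p* below the (raw, unadjusted) threshold α = 0.01 are
significant, and overlapping or abutting significant windows merge into
aggregation regions. A label-permutation null (shuffling significance flags
over feature positions, ≥ 1000 shuffles) is available behind a flag as a
sensitivity check on the binomial model.

Two deliberate distinctions:

- **DEG hotspot scan** (`window_scan` + `merge_regions`): raw per-window
  threshold, no multiplicity adjustment. Over ~950 windows this
  intentionally over-calls — the output is an exploratory hotspot list.
- **Chip polymorphic-region caller** (`chip_polymorphic_regions`): the same
  geometry, but the window threshold is Bonferroni-corrected
  (α / n_windows) by default. This caller's product is a genome-wide
  shortlist of blocks for marker development; at a raw per-window 1%
  threshold a ~950-window genome is expected to yield several false
  windows per scan, which would defeat that purpose. The planted-block
  windows in realistic simulations reach *p* ≈ 10⁻³⁰ or smaller, so the
  correction costs essentially no power. The uncorrected behaviour is
  available via `genomewide_correction=False`.

Because the binomial test is exact and discrete, its achievable size is
below the nominal α (typically 0.03–0.04 at α = 0.05 with ~60 features per
window). The calibration suite computes the exact per-window rejection
probability from the model's own critical values and checks the observed
rejection count against that (Poisson-binomial) band over disjoint windows,
plus the conservative upper bound.

## Fisher-exact enrichment

`fisher_exact_2x2` conditions on both margins (hypergeometric null). The
one-sided "greater" p-value is the upper hypergeometric tail; the
two-sided p-value follows the minimum-likelihood rule (sum of all
margin-fixed tables no more probable than observed, with a 1 + 1e-7
tolerance). Zero-margin tables are degenerate: *p* = 1 and an undefined
(NaN) odds ratio; otherwise the sample cross-product ratio is reported,
infinite when only the concordant diagonal is populated. The enrichment
universe defaults to all catalog genes; a tested-genes universe is
available. One-sided "greater" is the default because enrichment is the
question being asked. Raw p-values are the decision column; a
Benjamini–Hochberg column is emitted alongside in tabular output for the
reader and never gates anything.

## QTL scans

Genotypes are additive codes 0/1/2 (recurrent homozygote / heterozygote /
donor homozygote). Per position, LOD = (n/2)·log₁₀(RSS₀/RSS₁) with
RSS₁ floored at 10⁻¹²·RSS₀ (caps LOD in perfect-fit degeneracies);
R² = 1 − RSS₁/RSS₀; the additive effect is half the difference between
homozygote class means at observed markers (kg/ha) and the per-allele
regression slope at pseudomarkers. Missing genotypes: pairwise deletion in
single-marker mode; imputation from immediate flanking markers (two-state
conditioning under Haldane recombination fractions) in interval mode, and
column-mean imputation inside the vectorized permutation pass. Peak ties
break toward the smaller genomic coordinate. Monomorphic markers record
LOD 0 with a warning.

Interval scans evaluate a grid at `step_cM` that always includes the
observed marker positions, so a pseudomarker coinciding with a marker
reproduces the single-marker LOD exactly. The composite scan forward-selects
up to `n_cofactors` marker covariates by residual correlation (candidates
correlated > 0.999 with already-selected cofactors are dropped with a
warning) and excludes cofactors within 10 cM of the test position; its LOD
and R² are partial quantities relative to the cofactor model. With zero
cofactors it is bit-identical to the interval scan.

The permutation threshold is the (1 − α) quantile (`method="higher"`) of
genome-wide max-LOD over phenotype permutations of the single-marker scan;
with m permutations the resulting genome-wide type-I error is k/(m + 1)
for the k-th largest permuted value, ≈ 0.00995 at α = 0.01 with m = 200.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of a `SimulationConfig`; each combines
the config seed with a fixed stream tag, so generators are independently
and jointly reproducible. Defaults encode the study layout:

- **Genome**: 12 chromosomes × 40 Mb (uniform lengths — a simplification;
  real rice chromosomes span ~23–43 Mb), 40 000 uniformly placed gene
  models, one probe per gene.
- **Expression**: two +QTL/−QTL BIL pairs × three tissues × two drying
  severities × 3 replicates. Gene baseline N(8, 1.5), per-tissue offset
  N(0, 1), Gaussian noise sd 0.4 on the log₂ scale (a standard oligoarray
  residual assumption; the original experiments' replicate counts and
  residual variances are not published, so these are package defaults, not
  the study's values). Planted DEGs (background rate 1%, elevated inside
  hotspot intervals; the four default hotspots sit on the chip-defined
  blocks of chr2/4/9/10) receive a ±2.0 log₂-fold line effect — 5 noise
  sd, chosen so that a 3-replicate Welch contrast at *p* < 0.001 has
  > 99% per-gene power and planted-recall tests are meaningful.
- **Hybridization**: probes in planted polymorphic blocks hybridize
  2.0 log₂ units (5 noise sd) weaker in the +QTL line, emulating donor
  sequence mismatch; at 3 replicates the per-probe flag power is ≈ 0.99.
- **Mapping populations**: two-state donor-homozygote chains along each
  chromosome with stationary donor frequency 1/16 (backcross-derived
  default, residual heterozygosity collapsed; configurable) and
  adjacent-locus autocorrelation (1 − 2r)² under Haldane's map at a fixed
  4 cM/Mb — a rice-average conversion where only relative positions
  matter. Phenotype (kg/ha, mean 1500, residual sd 400) is the sum of
  planted additive effects plus normal error; each effect is calibrated
  against the realized genotype variance and the error vector is
  residualized against the planted genotype columns, so planted QTL explain
  their requested R² essentially exactly (the stated guarantee is ±0.03 at
  n ≥ 400; the construction achieves much better, leaving QTL–marker
  recombination as the only attenuation a scan sees).
- **Trials**: the packaged tables transcribe, cell by cell, the
  multi-location grain yields of the IR64 QTL-introgression lines (IRRI
  dry-season screening with environments DS10/DS11, and the seven South
  Asia target sites), including the printed LSD(0.05) rows; simulated mode
  draws site × entry yields with configurable entry effects.

What passing tests on this material does **not** show: recovery of the
original experiments' DEG counts, aggregation-region counts, enrichment
p-values or LOD/R² values — those depend on the deposited array data and
field phenotypes. The suite validates the machinery (calibration, power,
exactness, determinism) on data with known truth, plus exact reproduction
of the packaged trial arithmetic.

## Yield-advantage arithmetic

Advantages are exact cell differences against the check entry (IR64),
computed per environment and regime; environments missing the check are
excluded with a warning. The target-site summary range is reported over
cells whose advantage is at least the environment's printed LSD(0.05)
(`exclude_below_lsd=True`): three raw cells (271, 519 and 723 kg/ha) fall
below their site LSD and are excluded from the headline range, which the
LSD filter reproduces exactly; the screening-trial summary uses no filter,
with each season compared against its own check value. All advantages
remain in the output table with a `significant` flag either way.

## Coordinates and naming

Internally all coordinates are 0-based half-open; GFF3 input (1-based
inclusive) is converted on read, BED passes through, and display strings
use the 1-based megabase style of the QTL literature ("chr9:14.6–16.5 Mb").
Chromosome names are normalized to `chr<N>`. Gene-to-interval and
gene-to-window assignment defaults to the midpoint rule (a gene belongs to
at most one non-overlapping interval; tiling intervals partition a
chromosome); start and any-overlap rules are available, since the original
assignment rule for DEG-to-QTL overlap is not documented anywhere we could
rely on.

## Problem sizes in the checks

The acceptance suite uses 200 null genomes (30k genes) for window
calibration and power, 50 seeds for chip-region recovery, 100 seeds at
n = 450 for QTL recovery, and 500 outer replicates (200 permutations each,
11 markers × 3 chromosomes, n = 200) for threshold calibration; the
acceptance script uses the same designs at moderately smaller replicate
counts. These sizes give the stated binomial bands useful width while
keeping the full suite fast on one core.

## Known limitations

- Uniform chromosome lengths and uniform gene placement; no G×E structure
  across trial sites; no probe-level cross-hybridization.
- Planted DEG status is shared across tissues within a pair (per-tissue
  DEG truth would need per-tissue effect draws).
- The composite scan's cofactor count is user-specified (no information
  criterion); collinear cofactors are dropped, not re-searched.
- Joint multi-population (connected) QTL analysis is out of scope;
  populations are scanned separately and results concatenated.
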