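# Methods

nipkit re-implements, as a tested pipeline, the quantitative procedures used
to characterize candidate NOD2-interacting proteins (NIPs) and to test the
genes encoding them for association with inflammatory bowel disease (IBD):
family-based transmission disequilibrium testing, BRET saturation-curve
analysis, a multi-evidence interaction-scoring rubric, and qPCR / reporter
summaries. The original raw data (pedigree genotypes, plate readings, Cts)
are not publicly available, so a seeded synthetic-data module generates
inputs with the statistical structure each stage assumes; the published
summary numbers (T/U count pairs, component scores, the SNP panel, printed
fold values) are used directly as worked inputs where the pipeline consumes
them.

## Transmission disequilibrium testing

**Model.** For a marker allele or a 1–3-SNP haplotype h, count over
heterozygous parents of affected children the transmissions T (parent passed
h) and non-transmissions U. Under the null of no linked association,
T ~ Binomial(T+U, ½) and

    chi2 = (T − U)² / (T + U)

is asymptotically χ²(1) (McNemar form). This statistic reproduces every
published T/U → p pair to the printed precision (two pairs differ by one
unit in the last printed digit, consistent with rounding in the source).

**Subgroups.** Families are classed CD-only / UC-only / mixed from the
diagnoses of their affected members (any indeterminate-colitis case or a
CD+UC combination makes a family mixed), and CD-only families are split by
whether any member carries one of the three main NOD2 mutations (R702W,
G908R, 1007fs). Affected status for counting follows the subgroup: CD
subsets count CD children, UC counts UC children, IBD counts any of CD / UC
/ IC. Indeterminate colitis is therefore "affected" only in the IBD
subgroup.

**Trio phasing.** Haplotype windows are phased per complete trio by
exhaustive enumeration of parental haplotype decompositions consistent with
Mendelian transmission. A trio is informative for a window when every
consistent assignment implies the same unordered set of per-parent
(transmitted, untransmitted) haplotype pairs; otherwise it is ambiguous and
dropped. This criterion (agreement of the aggregate contribution rather than
of the assignment itself) makes a 1-SNP window reduce exactly to classical
allele-level TDT counting, where the both-parents-heterozygous /
heterozygous-child configuration contributes a transmitted and an
untransmitted copy of each allele. Counting requires both parents genotyped
at the window: a lone heterozygous parent is never counted, avoiding the
known missing-parent transmission bias. X-linked panels count maternal
transmissions only (hemizygous males are coded as homozygous);
pseudoautosomal panels are treated as autosomal. Families failing the
Mendel check at a marker are excluded at that marker only.

**Known limitation — phase-certainty correlation.** Dropping ambiguous
trios is not innocuous: when a parent is heterozygous at two or more window
SNPs, the trios that remain phase-certain are disproportionately those in
which the child resolves *both* parental transmissions at once, so the two
contributions are positively correlated (±2 steps on T−U), while the
compensating net-zero configurations are ambiguous and dropped. The McNemar
denominator then understates the variance and multi-SNP windows are mildly
anti-conservative. The effect grows with haplotype diversity: under the
default simulated block (below) the pooled type-I error of the full scan is
≈0.055 at α = 0.05 (size-1 windows are calibrated at ≈0.049). Removing it
would require fractional (EM-style) trio counting or a score test, both out
of scope here; consumers should read borderline multi-SNP p-values
accordingly.

**Multiple testing and replication.** Bonferroni correction is applied per
gene within each subgroup, with n_tests the number of haplotype tests
actually performed for that gene after the major-haplotype frequency filter
(default > 0.05, matching the published tables). Windows with multiple
affected siblings count every parent→affected-child transmission, the
classical (non-independent) convention. A significant primary haplotype is
"replicated" only when the same window and alleles are over-transmitted
(T > U, raw p < 0.05) in the replication cohort; a significant but different
haplotype of the same gene is classified `different_haplotype` and treated
as non-replication.

**QC.** Hardy–Weinberg equilibrium is tested on founders only (1-df
chi-square of observed vs expected genotype counts at sample allele
frequencies) to avoid relatedness inflation; per-marker call rate is flagged
below a configurable 0.99 threshold, reflecting the >99% genotyping success
rate of the panels modelled.

## BRET titrations

Each titration point is x = mean fluorescence / mean luminescence of a
triplicate (acceptor:donor expression proxy, dimensionless) and
y = (sample 530/480 ratio − donor-only 530/480 ratio) × 1000 in mBRET units,
with the background taken per plate and per condition from donor-only
wells. The one-site model y = BRETmax·x / (BRET50 + x) is fitted by
least squares (`scipy.optimize.curve_fit`, deterministic start at
BRETmax₀ = max y, BRET50₀ = median positive x, parameters bounded
non-negative); an ordinary least-squares line is the non-specific
(bystander) alternative. Classification:

* `below_threshold` — plateau estimate (fitted BRETmax, or max observed y
  if the fit failed) under 50 mBRET;
* `nonspecific_linear` — fitted BRET50 beyond 2 × the largest observed x
  (no plateau reached inside the titration) or the line fitting at least as
  well as the hyperbola;
* `specific` otherwise, with an advisory warning when r² < 0.98.

Ligand (MDP) modulation compares two specific fits by relative change:
BRET50 falling by more than the tolerance (default 15%) with stable BRETmax
is an affinity increase (apparent-Kd decrease, the RICK-like behaviour);
BRETmax falling with stable BRET50 is a BRETmax decrease (the CHMP5-like
behaviour). The source reports directions only, so the 15% tolerance is this
package's choice; it is configurable.

## Interaction scoring

Y2H points pool hits across screens (1 hit → 5, 2–3 → 10, >3 → 15, +5 for
hits in ≥2 independent screens, capped at 20 — the bracket reading that
reproduces every cross-checkable published component), co-IP maps
{none, weak, one orientation, both orientations} → {0, 5, 10, 20}, and BRET
maps {none, hyperbolic, MDP-modulated hyperbolic} → {0, 10, 20}; totals
range 5–60. Because raw per-screen hit counts are only partially published,
component points can also be supplied directly; out-of-rubric component
values (the packaged table contains one co-IP value of 15) are accepted
verbatim but logged as rubric violations rather than silently rescored.

## Expression and reporter assays

ΔΔCt uses two housekeeping genes (GAPDH, TBP); the normalizer is the
arithmetic mean of their mean Cts (equivalent to the geometric mean of
their expression), amplification efficiency is fixed at 2, replicates are
averaged before differencing. Folds use the signed-reciprocal convention
(ratio 0.5 → −2.0) with |fold| ≥ 2 called significant. Reporter assays are
summarized as firefly/renilla RLU with the SEM over replicates; an siRNA
experiment is accepted when ≥70% of target mRNA is knocked down (the
fraction-remaining boundary of 0.30 is inclusive).

## Synthetic data

`simulate_cohort` draws founder haplotypes per gene block from configured
frequencies (Hardy–Weinberg at the block level) and transmits one haplotype
per parent to each affected child, biased to a designated risk haplotype
with probability τ when the parent is risk-heterozygous (τ = 0.5 is the
null). Default class sizes mirror the modelled cohort: 104 + 78
NOD2-mutated/wild-type CD-only, 59 UC-only and 102 mixed families (343
total), one affected child per family by default (configurable for
affected-sib designs). The default block is a cascade of four tag-SNP
haplotypes with frequencies (0.55, 0.25, 0.12, 0.08) — one dominant major
haplotype and tree-like minor ones, the structure typical of candidate-gene
LD blocks and of the best-characterized block in the modelled panel (major
haplotype ≈0.56). Missing calls are injected per genotype; Mendelian errors
are injected only where an incompatible genotype exists, so the Mendel
check recovers exactly the injected count. What the generator does **not**
emulate: realistic inter-block LD, ascertainment, population stratification,
genotyping error that stays Mendel-consistent — so passing calibration and
power tests here demonstrates correctness of the counting machinery, not
robustness to those real-data complications.

`simulate_titration` produces triplicate wells per acceptor dose (default
dose ladder 0–800 ng) whose derived points follow the one-site hyperbola
plus Gaussian mBRET noise, with donor-only background wells and optional
MDP multipliers on BRETmax/BRET50. `simulate_ct` shifts target Cts by
−log₂(effect) with stable housekeeping genes. All generators are
byte-reproducible per seed.

## Problem sizes and numerical choices

The calibration study uses 150-trio cohorts × 2,000 seeds (≈38,000 pooled
haplotype tests) and the transmission-level null uses 2,000 × 200 meioses;
parameter-recovery uses 200 titrations at σ = 5 mBRET. Ties (T = U) report
chi-square 0 and p = 1; zero-information units (T + U = 0) are no-test rows
and are omitted from scan output rather than reported as p = 1. The
half-missing PED genotype convention promotes to fully missing with a
logged warning. Fit non-convergence is reported as a failed fit, never
silently replaced by the linear model.
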