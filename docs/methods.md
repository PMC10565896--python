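# Methods

## The relaxed-selection model

A gene coding for a cooperative trait confers part of its fitness benefit
on neighboring cells. If the genetic relatedness between interacting cells
is *r*, the first-order inclusive-fitness effect of a deleterious mutation
in such a gene is reduced from *s* to *s*·*r*: the carrier loses only the
fraction of the gene's benefit that returns to carriers. `kinsig` takes
this reduction as its generative model:

* every gene evolves as an independent haploid Wright–Fisher population of
  size N (free recombination between genes, complete linkage within);
* mutations arrive at rate *u* per site per generation; a fraction
  (default 0.75, matched to the codon-level average) land on
  nonsynonymous-capable positions and are deleterious, the rest are
  synonymous and neutral;
* fitness is multiplicative, w = (1 − s_eff)^k over the k deleterious
  alleles carried, with s_eff = r·s for cooperative genes and s for
  private and background genes;
* sites follow the infinite-sites idealization within a gene: a currently
  segregating position cannot be hit again (the draw is rejected and
  redrawn); positions freed by loss or fixation become available again, so
  long runs cannot exhaust the gene;
* after a burn-in (default 10·N generations, from a monomorphic start),
  n haplotypes are sampled without replacement.

No group-structured simulation is attempted: the paper-level theory
specifies only the direction of the effect, and the r·s reduction is the
standard first-order reduction consistent with it. Mutation–selection
balance then predicts per-site nonsynonymous diversity π_N ≈ 2u/s_eff when
2·N·s_eff ≫ 1, which is both the oracle the simulator is tested against
and the basis of the relatedness estimator.

### Outgroup branch

Divergence is generated separately: substitution proposals arrive as a
Poisson process at `expected_Ks` proposals per site along the outgroup
branch, each proposing one of the three alternative bases uniformly;
synonymous proposals fix with probability 1, nonsynonymous ones with
probability ω (default 0.2). With this parameterization the NG86-estimated
Ks recovers `expected_Ks` without material bias (verified to ±0.01 at
Ks = 0.3 in the suite). When `outgroup_omega_relaxed` is on (default),
cooperative genes use ω/r capped at 1 — a convenience that makes divergence
contrasts testable; the theory predicts only the direction of the
divergence elevation, not a quantitative ω scaling, and the flag can be
turned off.

### Expression generator

Co-expressed sets share a smooth latent profile (standardized random walk
over timepoints); member log-levels are positive-slope affine transforms of
the profile plus Gaussian noise, exponentiated, and median-normalized per
gene. The noise SD is calibrated by bisection against the *realized*
set-mean pairwise Spearman correlation, so a planted block hits its target
ρ within ±0.05 (checked over 20 seeds). Non-members follow independent
profiles. What this emulates: block-correlated co-regulation across ~11
biofilm timepoints. What it does not: count noise, batch structure,
missing measurements, or realistic marginal expression distributions —
passing tests say nothing about those.

## Default simulation conditions

| parameter | default | rationale |
|---|---|---|
| sample_size n | 31 | strain panel size of the motivating study |
| population_size N | 1000 | desk-scale WF population; θ set via u |
| gene_length_bp | 900 | typical bacterial CDS length |
| per_site_mutation_rate u | 5×10⁻⁶ | θ = 2Nu = 0.01/site, matching ~1% natural diversity |
| selection_coefficient s | 0.01 | 2Ns = 20: purifying but drift-visible |
| true_relatedness r | 0.79 | the study's headline estimate |
| fraction nonsynonymous | 0.75 | codon average |
| burn_in | 10·N | neutral-site equilibration |
| outgroup_expected_Ks | 0.3 | subspecies-scale synonymous divergence |
| missingness_rate | 0.05 | exercises the ≥80% call-rate filter |

Property tests run a diffusion-matched scaling of these conditions
(N = 250, s = 0.04, u = 2×10⁻⁵, L = 600): the population-scaled parameters
2Ns and θ = 2Nu — which govern the diffusion-limit dynamics — are identical
to N = 1000 with s = 0.01 and u = 5×10⁻⁶, while each gene simulates in
~50 ms. The recovery harness uses 20 cohorts of 40 cooperative + 40
private genes per r ∈ {0.25, 0.5, 1.0}; neutral calibration uses 500 genes
at s = 0.

## Statistics

* **π** — mean pairwise differences per pair (every pair weighted equally,
  mismatches counted only where both sequences are called: pairwise
  deletion), divided by the *effective* length
  (mapped_fraction × gene length). With no missing data this equals the
  allele-count form exactly (oracle-checked).
* **Synonymous/nonsynonymous partition** — NG86 fractional site counts on
  the reference codon; each segregating column is labeled by the amino-acid
  effect of its alternate allele; codons with several segregating positions
  are resolved by averaging over substitution orderings (pathways through
  premature stops discarded unless unavoidable). π_S and π_N divide by the
  NG86 site counts scaled by the mapped fraction.
* **Tajima's D** — Tajima (1989) constants; undefined (NaN) at S = 0,
  never 0.
* **Fu & Li** — D*/F* from total singleton counts; D/F additionally when an
  outgroup row permits polarizing singletons (a singleton is derived when
  the outgroup carries the other allele; unpolarizable sites are skipped).
  Variance constants follow the corrected forms of Simonsen, Churchill &
  Aquadro (1995). Validated against an independently coded constants oracle
  and by neutral calibration (mean within 3·SE of 0 over 500 genes).
* **McDonald–Kreitman** — polymorphism = segregating in-sample; divergence
  = fixed in-sample and differing from the outgroup; a site that is both
  counts as polymorphism only. Counts are pathway-averaged per codon
  (fractional); Fisher's exact test uses the rounded table, NI and DoS the
  fractional one. NI is undefined when Ps, Dn or Ds is 0. The conservative
  variant drops polymorphisms with minor-allele frequency < 0.15 (the
  common low-frequency exclusion; configurable, since the exact published
  cutoff is not recoverable).
* **Ka/Ks** — NG86 with site counts averaged over the two sequences,
  pathway-averaged differences, Jukes–Cantor correction
  d = −(3/4)·ln(1 − 4p/3); flagged undefined at p ≥ 3/4. Cross-checked
  loosely (±25%) against seqinr's LWL85-style `kaks` in R, and exactly
  against a hand-worked single-substitution example.

Undefined statistics propagate as NaN and are dropped listwise by the
comparison layer.

## Comparison battery

Test family is an explicit per-variable configuration, never an automatic
normality decision (defaults: π, π_S, Ks → Welch ANOVA with Games–Howell;
π_N, Ka, ratios → Kruskal–Wallis with Dunn). Dunn p-values are unadjusted
by default (Holm/Bonferroni by flag). The paired mode aggregates per
trait-group medians of the two classes and applies the exact Wilcoxon
signed-rank test (full sign-assignment distribution by convolution for
n ≤ 25, tie/continuity-corrected normal approximation above; zero
differences dropped and reported). Null calibration of the omnibus
families is checked on identically distributed synthetic classes (1,000
replicates) rather than on 200 full simulated cohorts, which would
dominate the suite's runtime for the same information.

## Co-expression bootstrap

The observed set's mean pairwise Spearman ρ (average-rank ties) is
compared with B random same-size sets drawn uniformly without replacement
from all measured genes — including the candidate's own members, since the
procedure mirrors "a random set of the same size" with no exclusion.
The empirical p is add-one, p = (1 + #{null ≥ obs})/(1 + B), so it is never
exactly 0. Genes with constant profiles after normalization have no defined
correlation and are removed from the universe. The implementation uses the
Gram identity on unit-normalized rank rows (sum over pairs of dot products
= ‖Σz‖² − k), verified against a pair-by-pair scipy loop.

## Enrichment

One-sided upper-tail exact binomial (over-representation is the
directional prediction). The genomic fraction f is computed over genes
with a known category only. Because the exact test is discrete it is
conservative; the calibration test therefore checks that the empirical
rejection rate never *exceeds* the nominal level, which is the
scientifically dangerous direction. The cooperative-vs-private 2×2
chi-square (continuity-corrected) is provided for direct contrasts.

## Relatedness estimator

r̂ = median π(private) / median π(cooperative), default on nonsynonymous π
(selection acts there under the model; all-sites π is also reported).
Medians, not means, because per-gene diversity is heavily right-skewed.
The CI is a percentile bootstrap over genes within each class. r̂ > 1 is
reported as-is with a flag (no detectable relaxation), clipped only in the
headline field. The estimator is this package's own definition, derived
from the balance relation π ∝ u/s_eff ⇒ π_coop/π_priv = 1/r, and is
validated by recovery: over 20 simulated cohorts per condition the mean r̂
lands within ±0.1 of r ∈ {0.25, 0.5, 1.0}. Single cohorts scatter
substantially (SD ≈ 0.1–0.2 at 25–40 genes/class) — the worked example in
the README shows a cohort at true r = 0.5 estimating 0.39 with a CI that
covers the truth.

Assumptions, made explicit by the recovery harness: the magnitude and
distribution of selection coefficients must be the same on average across
classes. A deliberate violation cell (private genes under 2× stronger
selection at true r = 1) produces r̂ ≈ 0.5 — the confound is reported, not
hidden.

## Numerical and design choices

* Coordinates: 1-based inclusive in VCF/GFF, 0-based half-open internally.
* Threshold ties (call rate exactly 0.8, mapped fraction exactly 0.5) are
  retained — "at least" is inclusive.
* Missing genotypes become N in the alignment and are handled by pairwise
  deletion; strains are never dropped.
* Indels never enter the popgen statistics; they are kept in a side channel
  solely for frameshift annotation. Pipelines requesting
  `drop_indels: false` are refused rather than silently honored.
* Deleterious annotation reimplements exactly the two consumed variant
  classes (stop_gained, frameshift) from the genetic code, strand-aware,
  excluding the annotated terminal stop.
* The WF kernel is a numba routine; per-generation work is O(N·S) on the
  currently segregating sites, with fixed/lost columns recycled each
  generation. All randomness flows from named integer seeds
  (`numpy.random.SeedSequence` spawns per-gene streams), making fixtures
  byte-identical under a fixed seed.
* Multi-allelic VCF rows are decomposed per alternate allele; a strain
  carrying a different alternate is treated as missing for that record.

## Known limitations

* Haploid, panmictic, constant-N populations: no demography, no
  within-gene recombination, no epistasis, no spore dormancy.
* The r·s reduction is a first-order model; real social selection may be
  frequency- or condition-dependent.
* The ω/r outgroup scaling is a testing convenience, not a calibrated
  divergence theory; only the direction of the divergence contrast should
  be interpreted.
* NG86/JC saturates above p ≈ 0.75 and is mildly biased at high divergence.
* The estimator's ±0.1 recovery is demonstrated at the simulated
  conditions above; real data add misannotation, conditional expression
  and selection-coefficient heterogeneity that the simulator does not
  emulate.
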