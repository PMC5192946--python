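# Methods

`popdemog` analyzes phased multilocus haplotype alignments from structured
populations — the typical shape of a continental-island phylogeographic
survey: a handful of nuclear loci a few hundred bp long, a dozen-odd
populations with 14–16 phased haplotypes each, per-site nucleotide diversity
of a few parts per thousand. This note records the models, conventions and
numerical choices behind each stage, and what the shipped tests do and do
not establish.

## Site matrices and missing data

All statistics operate on a binary haplotype × segregating-site matrix.
Missing data are handled by **complete deletion**: any alignment column with
`-` or `N` in an ingroup sequence is removed entirely and the analyzed
length `L` decremented, matching the default of the standard desktop tools
for per-population tables. Columns with three or more ingroup alleles
violate the infinite-sites assumption of the downstream estimators; they are
excluded from the matrix but retained in `L`, and their count is reported.
An optional BED-like mask drops further columns (e.g. mononucleotide
repeats flagged upstream); no repeat detector is included — masking is a
data-preparation concern.

Without an outgroup, allele coding is deterministic: 0 is the major allele,
ties resolved to the allele of the first haplotype row. With an outgroup, a
column is polarized (0 = ancestral) only when every outgroup sequence
agrees and matches one ingroup allele; otherwise the column stays in the
matrix unpolarized and is used by every statistic except Fay & Wu's *H*,
which needs derived-state orientation and silently skips unpolarized
columns (the skipped count is available on the matrix).

## Summary statistics

* π is the mean number of pairwise differences (per locus and per site);
  θ_W = S/(a_n·L) with a_n = Σ_{i<n} 1/i.
* Tajima's *D* uses the 1989 variance constants exactly and is undefined
  (NaN, reported blank) when S = 0 — never coerced to 0 in reports.
* Fay & Wu's *H* is reported **unnormalized** (θ_π − θ_H as per-locus
  totals, θ_H = Σ 2 S_i i²/(n(n−1))), the convention behind desktop-tool
  outputs of order ±1–2 on loci of this size.
* R_M is the Hudson–Kaplan bound: all column pairs showing four gametes
  define incompatible intervals, and R_M is the maximum number of pairwise
  disjoint ones (intervals sharing only an endpoint are disjoint — the
  implied crossovers fall in different inter-site gaps). The greedy
  right-endpoint scan is exact for this objective; tests verify it against
  exhaustive search.
* The largest non-recombining block is the longest contiguous stretch whose
  columns pass all pairwise four-gamete tests. Published tables rarely
  define the block boundary; here a block spanning columns j..k runs from
  the midpoint between columns j−1 and j to the midpoint between k and k+1,
  clamped to [0, alignment length]. The inclusive column-span alternative
  can be obtained from the returned column interval.
* Multilocus per-population values pool by **site concatenation**
  (Σ pairwise differences / Σ L; Σ S/a_n over Σ L; *D* from pooled totals).
  This reproduces the per-site definitions exactly and matches common tool
  behavior; an unweighted per-locus mean is available by flag. When loci
  differ in sample size, pooled *D* uses the rounded mean n for its
  variance constants — exact whenever n is constant across loci, the usual
  case.

## Coalescent simulator

Time is measured in units of 4N₀ generations and θ = 4Nμ per locus (the
conventions of `ms`), so k lineages coalesce at rate k(k−1)/ρ(t) where ρ is
the relative population size, and mutations are Poisson with mean
θ × total branch length, placed uniformly on branches at unique positions
in (0, 1). Five models:

| model | backwards-in-time size ρ(t) |
|---|---|
| SNM | 1 |
| EXP | exp(−g·t) (growth toward the present) |
| BOT | 1 for t < t_b, then 1/severity (severity = θ₀/θ_A) |
| BOT_EXP | exp(−g·t) for t < t_b, then exp(−g·t_b)/severity |
| IM2 | two demes θ₁, θ₂ merging into θ_A at t_split |

Waiting times under time-varying size are drawn by analytic inversion of
the cumulative hazard per epoch (no discretization). In IM2, θ₁ doubles as
the 4N₀ reference; each lineage migrates backwards at rate m/2 with
m = 4N₀M, mirroring the two directional arrows of an
isolation-with-migration diagram. Degenerate corners reduce exactly to
simpler models (EXP g=0 ≡ SNM, BOT severity=1 ≡ SNM, BOT_EXP g=0 ≡ BOT,
IM2 t_split=0 ≡ panmixia at θ_A), which the tests check distributionally,
and the simulator is cross-validated against msprime on the TMRCA
distribution.

There is **no intralocus recombination**: analyses of this kind restrict to
non-recombining blocks, so recombination is a preprocessing concern
(R_M and the block statistic), not a simulation feature. Simulated loci are
infinite-sites, so under extreme prior draws a locus may carry more
mutations than its nominal bp length; such draws produce summary vectors
far from any real observation and are eliminated by the rejection step.

## Neutrality tests

Significance for *D* and *H* comes from coalescent simulation under the
standard neutral model, by default **conditioned on the observed S** (each
replicate places exactly S mutations multinomially on branches by length) —
the convention of the common desktop implementation; fixed-θ conditioning is
available by flag. p-values are empirical with the add-one correction
(1 + #extreme)/(n_reps + 1); *D* is two-tailed (2·min of the tail
probabilities, capped at 1), *H* one-tailed low by default, as the statistic
was designed to detect an excess of high-frequency derived alleles. The
default replicate count is 10,000. Type-I error at α = 0.05 is verified to
lie in [0.03, 0.07] by simulation.

The HKA test solves the 1987 moment equations — per-locus θ_i, divergence
time T (in 2N_a generations) and, in the two-species variant, the size
ratio f = N_b/N_a — and sums (obs − exp)²/var over all cells, with the
variance formulas including the θ² terms. The solver is a bounded
trust-region least-squares on log-parameters started from the closed form
that is exact when sample sizes are equal across loci; convergence is
checked to 1e−6 of the data scale and failure raises with diagnostics.
df = L−1 (one species) or 2L−2 (two species: polymorphism in both species
plus divergence, minus L+2 fitted parameters). The two-species variant is
the default. Under null simulations the X² mean is within 10% of df.

## Rejection ABC

The four single-population models are compared by plain rejection:
per-model reference tables of equal size pair prior draws with the summary
vector of a dataset simulated at the observed design. The summary set is
the msABC-style multilocus reduction — means and variances across loci of
S, π (per-locus totals), θ_W, Tajima's *D* and the haplotype count — plus a
monomorphic-locus counter; *D* at monomorphic loci enters as 0 with that
counter as the indicator, because dropping such rows would bias acceptance
toward high-θ draws. For IM2 fits the vector holds both populations'
reductions plus the mean and variance of per-locus D_xy.

Summaries are centered and scaled by the median absolute deviation pooled
across models (robust to the heavy-tailed variance summaries), distance is
Euclidean, and the accepted set is the tolerance fraction nearest rows
pooled across models. Model posterior probabilities are the per-model
shares of that set; parameter posteriors are each model's accepted draws.
The recommended production scale is 10⁵ simulations per model with 0.5%
accepted; the CLI default, the tests and the acceptance script use
10⁴/model with about 1% to keep
runtimes at minutes on one CPU (the statistical behavior — recovery rates,
coverage — is verified at that scale). No regression adjustment is applied:
model choice by raw rejection share keeps the procedure transparent, and a
local-linear correction can be layered on the accepted draws if needed.

Point estimates are modes of a Gaussian-kernel density (Silverman
bandwidth, 512-point grid over the sample range; ties resolve to the lower
value); intervals are 95% HPD — the shortest window containing ⌈0.95n⌉
sorted draws, verified against exhaustive window search. The mode may sit
at an HPD edge; no ordering between them is assumed. Posterior predictive
checks resample accepted parameter vectors, re-simulate, and report each
observed summary's quantile in its predictive distribution.

Known behavior: rejection ABC is approximate — HPD coverage at the
simulation scales used measures ≈ 94–96% for θ and the IM2 split time
(within the nominal 95%, but under-coverage at looser tolerances is
expected and should be re-checked for new designs). With weak growth,
SNM/EXP confusion is inherent (the models coincide at g = 0); model
posteriors split accordingly rather than inflating a single model.

## Isolation with migration and time scales

IM2 fits report, per accepted draw, the derived quantities of standard IM
reporting: mutation-scaled split time t = t_split·θ₁ (per locus of mean
length, i.e. t = Tμ), and population migration rates 2NM = m/2 (receiving
deme 1) and (m/2)·θ₂/θ₁ (deme 2) — algebraically identical to
2NM = 0.5·θ·m in mutation-scaled parameters. Conversion to years is
T = t/μ with μ the per-locus-per-year mutation rate; coalescent units are
t/θ_ref. In place of likelihood-ratio tests of nested zero-migration
models (an MCMC machinery this package deliberately does not implement),
the CLI reports the posterior mass below a configurable migration
threshold — a statement about the posterior, not a calibrated test, and
documented as such.

## Synthetic data generator

`generate_island_study` writes the exact formats the readers consume.
Defaults: 4 island populations × 16 phased haplotypes, 8 loci of 339–470
bp, θ = 0.004/site under SNM — diversity in the range observed for nuclear
loci in outcrossing shrubs. Sequences are threaded from simulated site
matrices (one substitution per segregating column, ancestral base uniform,
derived base uniform over the other three); the outgroup carries the
ancestral allele at every segregating site plus private substitutions at a
rate defaulting to 10× the maximum within-species θ, so polarization is
unambiguous by construction (a flag enables mispolarization for robustness
studies). Populations not joined in an explicit IM2 pair are simulated
independently: their D_xy reflects no shared history and pooled
across-population statistics are not meaningful for them — use pairs when
between-population structure matters. No sequencing error, phasing error
or indels are simulated, so passing recovery tests demonstrates estimator
correctness on clean data, not robustness to upstream artifacts.

Truth records (seed + full config) regenerate every file byte-for-byte.

## Problem sizes in tests and the acceptance script

Analytic moment checks use 20,000 replicates (3 standard errors); model
identities 10,000 per model; type-I error 2,000 datasets at 1,000 null
replicates per test; estimator calibration 200 study replicates; ABC
recovery 10⁴ simulations/model with 50 datasets per condition; coverage 100
fits per parameter. The acceptance script repeats the same computations at
half scale for the slowest blocks. These sizes were chosen so each
statistical assertion has comfortable Monte-Carlo margin while the whole
suite runs in minutes on a single CPU.

## Limitations

* No recombination within loci, no selection, no more-than-two-population
  joint fits; the multi-island history is summarized by independent
  single-population fits plus pairwise IM2.
* Fixed-S conditioning for the neutrality tests is a convention, not an
  exact likelihood; both conditionings are exposed.
* ABC results depend on priors and the summary set; both are configuration,
  and defaults are package choices, not estimates.
* The pooled Tajima's *D* across loci with unequal sample sizes uses an
  approximation (rounded mean n); per-locus values are always exact.
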