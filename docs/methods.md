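# Methods

`dhqtl` implements the analysis chain used to dissect a quantitative
trait in a doubled-haploid (DH) plant population — here, head-splitting
resistance (HSR) in cabbage: trait scoring, replicated-design ANOVA,
major-gene/polygene mixed-inheritance segregation analysis, genetic-map
utilities, and QTL scanning with permutation thresholds.  Because no
raw phenotypes or genotypes from such studies are bundled, every stage
is exercised against a synthetic-study generator that reproduces the
statistical structure the analysis assumes.

## The DH setting

A DH line is produced by doubling a haploid derived from one F1 gamete:
every locus is homozygous for either the first parent's allele ('a') or
the second parent's ('b'), each with probability 1/2, and only one
round of meiosis separates the line from the F1.  Consequences used
throughout:

* two genotype classes per locus, expected 1:1 (the segregation
  distortion test is a 1-df chi-square against that ratio, flagged at
  p <= 0.01);
* *k* segregating major genes produce 2^k equally frequent genotype
  classes;
* no dominance parameters are estimable, so all genetic models are
  additive(-epistatic).

Map distances use Kosambi's function, d = 25·ln((1+2r)/(1−2r)) cM, and
its inverse r = tanh(d/50)/2; the simulator and the interval-mapping
genotype probabilities use the same inverse so map units are coherent
end to end.

## Synthetic studies

`simulate_study` draws a map (nine linkage groups, 241 markers,
1065.9 cM total by default, mirroring the reference map summary), DH
genotypes, and phenotypes.

Meiosis is a two-state Markov chain along each chromosome: the first
marker allele is a fair coin and the allele switches across each
interval independently with probability `inverse_kosambi(interval)`.
This assumes no crossover interference between intervals; the reference
map does not state its interference model, so this is our modelling
choice, not a reproduction of it.

Phenotypes follow the mixed-inheritance model.  With x_j = +1 for the
'a' allele at major gene j (the susceptible parent, matching the
all-positive printed additive effects) and −1 otherwise, a plant's
value is

    y = m + Σ_j x_j d_j + Σ_{j<k} x_j x_k i_jk + x_1 x_2 x_3 i_123
          + g_line + e,

with one polygenic deviate g_line ~ N(0, σ²_pg) per line and
independent plant noise e ~ N(0, σ²).  The polygenic effect is a single
normal deviate rather than many explicit loci, because the downstream
analysis only identifies σ²_pg.  Major genes are snapped to their
nearest marker by default so recovery tests can compare against an
observable truth; `snap_genes_to_markers=False` keeps them off-marker
for harder tests.

Default parameters are the reference study's estimated 2011
architecture: m = 37.78, d = (20.4, 8.59, 15.89), i = (3.64, 10.94,
−0.86, −5.81), σ²_pg = 38.94, σ² = 22.38, n = 157 lines.  One caveat
discovered while building the oracles: those printed effects imply a
major-gene variance of Σ effects² ≈ 909.87 under the orthogonal ±1
design, while the printed variance partition says σ²_mg = 451.22 — the
two printed blocks are mutually inconsistent.  `default_config()`
keeps the printed effects (the architecture's shape);
`variance_matched_config()` shrinks all effects by a common factor so
the closed-form major-gene variance equals 451.22, which makes the
generating major-gene heritability 88.0% and is the condition used for
heritability-recovery checks.

What the generator does **not** emulate: segregation distortion (the
real map had 58% distorted markers; an optional distortion coefficient
is out of scope here), genotyping error, linked major genes on one
chromosome by default, non-normal environmental noise, and
genotype-by-year interaction.  Passing tests therefore demonstrate
correctness of the estimators under their own assumptions, not
robustness to those violations.

The split-measurement generator inverts the trait scoring: it draws
per-plant grades from Binomial(5, index/100) — so the expected
recomputed head-splitting index equals the target exactly — and
realises each grade as a split geometry (layer count, arc length,
width, height, circumference) that the grading rules map back to it.

## Trait scoring

A head's relative split area is S = (a·b)/(c·d/2)·100, from the arc
length a and width b of the largest split, head height c and largest
circumference d.  Grades 0–5 follow the layer-count/S rule table (S ≥
50 promotes the 2, 3–5 and 6–10 layer classes by one grade; more than
ten layers is grade 5 regardless).  The line-level head-splitting
index is Σ grades/(5n)·100 over the n observed plants; missing plants
simply reduce the denominator, and the per-line plant count is reported
so short lines are visible.  Resistance categories are half-open bands
on the index — [0,5], (5,15], (15,35], (35,50], (50,100] — because the
conventional printed band edges (5.0 / 5.1 …) would leave a continuous
index in (5.0, 5.1) unclassified.

## Replicated-design ANOVA

The field design divides lines into blocks and lays the blocks out in a
randomized complete block design with replicates.  The fixed-effects
decomposition is

    y ~ block + line(block) + replication + block×replication + error,

computed as a direct balanced between-group SS decomposition after
aggregating records to (line, replicate) plot means.  For 155 lines in
14 blocks with 3 replicates this yields the df structure 13 / 141 / 2 /
26 / 282 (corrected total 464).  F for every non-error source is taken
against the error mean square; which denominator the original analysis
used is not stated, and with its raw data unavailable the choice is
untestable either way.  The error mean square is the environmental
variance estimate σ̂² handed to the segregation analysis — following
the reference convention in which the ANOVA error MS equals the σ² of
the genetic-parameter table.  A two-way year + line decomposition of
line-by-year means (interaction as error) covers the combined-years
table.

Descriptive statistics use bias-adjusted sample skewness and *excess*
kurtosis (the reference tables print negative kurtosis).  Correlations
are pairwise-complete Pearson r with two-tailed p and 0.05/0.01 stars.

## Segregation analysis

With k major genes, line values follow a 2^k-component Gaussian
mixture with proportions fixed at 1/2^k (Mendelian DH expectation; no
distortion adjustment by default).  Component means are constrained to
μ = Xβ, where X is the ±1 genotype design (classes enumerated
lexicographically, '+' first) with columns for the mean, additive
effects and the chosen epistasis level, and a common within-component
variance σ²_w = σ²_pg + σ² absorbs polygenes and environment.

Fitting is IECM: E-step posteriors under the fixed proportions; CM-step
1 updates β by generalized least squares with the component posterior
masses as weights; CM-step 2 updates σ²_w, floored at the supplied
σ²_e (a constrained M-step, so the EM ascent property is preserved —
asserted on every run).  Initialisation splits the sorted sample into
2^k quantile groups; 10 restarts with jittered initial means keep the
best likelihood; tolerance 1e-8 on the log-likelihood, at most 2000
iterations; non-convergence is flagged on the result rather than
raised; a restart whose component empties is discarded.  The k = 0
model reduces exactly to the sample mean and MLE variance.

The DH-applicable catalog crosses k = 0..3 with the admissible
epistasis options and polygene presence (14 models).  The classical
38-model catalog also contains F2/backcross models whose 1:2:1
proportions never apply to DH data; they are deliberately not
enumerated.  Model choice: AIC = −2lnL + 2p ranks all fits; within a
2-AIC window of the minimum, the candidate with the fewest significant
goodness-of-fit statistics (most passes) wins, then lower AIC, with
parameter count breaking exact ties.

Goodness of fit transforms the sample through the fitted CDF and tests
the transforms for uniformity: U1², U2², U3² are the squared normalised
first three shifted-Legendre moments (each χ²(1) under the null — the
classical U-statistic formulas are not printed in the source
literature we had, so the contract is the χ²(1) null, verified by
calibration tests); nW² is the Cramér–von Mises statistic compared to
the 0.461 / 0.743 critical values (P < 0.05 / P < 0.01); D_n is the
Kolmogorov sup-distance with its asymptotic p.  Diagnostics are
withheld below n = 8.

First-order parameters come from the component means by weighted least
squares against the design; for the saturated 3-gene full-epistasis
model this is the orthogonal (Hadamard) inverse, exact to rounding.  An
explicit permutation argument lets callers reorder externally supplied
means, because mixture component labels are only identified up to
permutation.  Second-order parameters: σ²_pg = max(σ²_w − σ²_e, 0),
σ²_mg = σ²_p − σ²_pg − σ²_e (σ²_p the sample variance of line values),
heritabilities as percentages of σ²_p.  At n ≈ 157 the common-variance
estimate of the saturated mixture is biased low (free means absorb
polygenic spread), so recovered major-gene heritability runs a few
points above truth; the recovery suite quantifies this.

## QTL scanning

*Single-marker regression* is the LOD backbone: LOD =
(n/2)·log10(RSS0/RSS1); the additive effect is half of (mean of
'b'-class − mean of 'a'-class), i.e. positive when the second parent's
allele raises the trait — the sign is defined purely numerically and
annotated in reports, since verbal "resistance-enhancing allele"
conventions are ambiguous about trait direction.

*Interval mapping* evaluates a grid (default 1 cM, marker positions
always included) per linkage group.  QTL genotype probabilities per
line come from the nearest non-missing flanking markers under the
no-interference Markov model with inverse-Kosambi recombination
fractions (single-sided transitions at chromosome ends or when one
side is entirely missing; probability 1/2 with no information).  A
two-component normal mixture weighted by those priors is maximised by
EM; LOD is against the single-normal null and R² = 1 − σ̂²/σ̂²_0.  At a
fully genotyped marker the priors are 0/1 and the fit reduces to the
marker regression exactly (tested to 1e-6).

*MQM-style cofactor scan*: interval mapping on residuals of the
phenotype regressed on cofactor markers, excluding cofactors within a
10 cM window (default) of the evaluated position.  Without explicit
cofactors, `QtlScan.fit(method="mqm")` takes the markers nearest the
peaks of a preliminary IM scan, following the usual MQM workflow.

*ICIM-style scan*: stepwise marker selection (entry p < 0.001, removal
p > 0.002, partial-F tests, selection capped at n/5 terms), then
interval mapping on the phenotype adjusted by all selected markers
except the two flanking the current interval, using the step-1
coefficients.  Selecting zero markers degrades to plain IM exactly.

*Hits*: local maxima above the LOD threshold (default 3.28), kept
greedily by LOD with ≥ 20 cM separation within a group, each with a
1-LOD support interval and flanking markers; named trait + chromosome
number + positional ordinal (e.g. "Hsr 4.2"); reports append per-run
summed PVE.

*Permutation thresholds* shuffle the phenotype against intact
genotypes and take the empirical (1−α) quantile of per-permutation
genome-wide maximum LOD.  The default evaluates each permutation's
maximum over marker positions by vectorised single-marker regression
(missing calls mean-imputed for this purpose): since IM equals marker
regression at markers, and at ~4.4 cM spacing the genome-wide maximum
is attained at or adjacent to a marker, the fast scan tracks the full
IM maximum closely (checked in the tests) while making 1000
permutations routine.  `method="im"` runs the full grid per
permutation for the exact version.

## Pipeline and CLI

`run_pipeline` executes simulate → score → describe/ANOVA → segregation
→ map summary → scan from one `RunConfig` (YAML-serialisable); every
output is tab-delimited text carrying the seed and a hash of the
analytic settings, reruns are bit-identical under a fixed seed, and
existing intermediates are reused when resuming.  The `dhqtl` CLI
exposes the stages as subcommands (simulate, score, describe,
segregate, mapstats, scan, permute, run, validate) with defaults
matching the reference analysis settings (LOD 3.28, 1000 permutations,
p_in 0.001, p_out 0.002, 1 cM step).

## Test sizes and numerical choices

Stochastic suites are sized for routine runs on one CPU: goodness-of-
fit and distortion calibrations use 1000 simulations against 3-SE
binomial bounds (the distortion bound is around the exact attained
level of the discrete test, ~1.06% at n = 157); ICIM recovery uses 40
replicate studies at n = 157 against the ≥ 70% per-locus detection
bound; permutation type-I calibration uses 200 outer replicates of
200-permutation thresholds; heritability recovery averages 200
refitted studies against a ±5-point band.  Degenerate inputs are
handled explicitly: zero-length intervals (r = 0), recombination
fractions capped at 0.4999, variance floors at σ²_e, empty mixture
components trigger jittered restarts, monomorphic markers and
constant phenotypes are errors or LOD-0 as contracted.

## Known limitations

* Marker grouping/ordering (JoinMap's role) is out of scope; maps are
  accepted as given.
* The mean-interval headline convention divides total length by marker
  count, not interval count; both are computed and labelled.
* Mixture component labels are identified only up to permutation;
  first-order estimates from a blind fit may differ from the
  generating effects by a relabelling even when the fit is good.
  Variance-based quantities (heritabilities) are unaffected.
* The saturated 8-component fit at n ≈ 157 overestimates major-gene
  heritability by a few points (see above).
* No multi-environment or epistasis QTL scans; no bit-compatibility
  with MapQTL/IciMapping.
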