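# Methods

## Scope and data model

The package analyzes a taste–reward brain circuit at three levels: anatomical
connection strength from probabilistic tractography, directed (effective)
connectivity from ROI time series, and group-level statistics. Raw imaging is
out of scope: the input contracts start where a tractography run or ROI
extraction ends (streamline-count tables, time × region matrices), and
synthetic generators produce all inputs with known ground truth.

## Circuit taxonomy

Regions are identified by label + hemisphere only; the 16-label vocabulary
and the allowed seed→target pair table are fixed. Per hemisphere the table
yields 49 ipsilateral pairs — thalamus→{3 insula subregions, frontal
operculum}; each insula subregion→8 targets (amygdala nuclei, ventral
striatum, medial PFC, 4 OFC subregions); substantia nigra→ventral striatum;
each amygdala nucleus→4 targets; each OFC subregion→3 targets — 98 tracts in
total. Enumeration is ordered (hemisphere, seed, target) so outputs are
diff-stable. The frontal operculum appears only as a thalamic target, never
as a seed. Atlas coordinates are deliberately not carried: they belong to an
atlas, not to the connection-strength arithmetic.

## Connection strength

With `p_st = count/total_samples` (total samples = seed voxels × samples per
voxel, default 5000), seed total probability `P_seed = Σ_targets p`, reverse
probability `p_ts`, and target volume `V` in voxels:

```
strength = ((p_st / P_seed) · (p_st + p_ts)/2) / V
```

The grouping makes the result linear in the bidirectional mean probability
and inverse-linear in target volume. Path-length correction multiplies each
count by the tract's mean path length before dividing by total samples
(probtrackx distance-correction semantics), applied before normalization.
Choices made where the procedure was underdetermined: `P_seed` sums over the
in-circuit targets recorded for that seed (whole-brain totals are not part
of the input contract); a missing reverse run degrades to `p̄ = p_st` with a
warning; a seed reaching nothing yields strength 0 with a warning rather
than an error, so one bad seed cannot abort a subject table. Pathway FA is
the visitation-count-weighted mean over traversed voxels and is undefined
when no voxel is visited.

## Effective connectivity

**Score.** Subjects are z-scored per column (ML convention, 1/n). A DAG's
score is `BIC = Σ_nodes n ln σ̂²(node|parents) + (|edges| + |vars|) ln n`,
minimized; additive constants common to all models are dropped. The score is
decomposable, and local contributions are computed from per-subject ML
covariance matrices, so search cost is independent of T after one pass over
the data. Residual variances are floored at 1e−12 to keep logs finite under
near-collinearity. For multiple subjects each candidate's local contribution
is the arithmetic mean of per-subject contributions, each with its own
sample size — subjects stay individually standardized and no concatenation
is performed, so one aberrant subject cannot dominate through length alone.

**Search.** GES over CPDAGs with insert/delete operators and their standard
validity tests (clique and semi-directed-path conditions). After every
accepted move the PDAG is re-completed: consistent DAG extension
(Dor–Tarsi), then the pattern of that DAG (v-structures + Meek rules 1–3,
which are complete without background knowledge). Forward phase inserts
while BIC strictly decreases (tolerance 1e−10), backward phase deletes
likewise; score ties break by lexicographic (source, target) label order, so
the search is fully deterministic. The search trace records every accepted
operator with its score delta. Brute-force enumeration of all labelled DAGs
(25 on 3 nodes, 543 on 4) verifies that the search attains the global BIC
optimum's equivalence class on 3 variables and in ≥90% of 4-variable
datasets; the remaining cases are genuine greedy local optima whose scores
are verified to be no better than the global optimum — greedy equivalence
search is only asymptotically global, and with the exact population
covariance the implementation recovers the true CPDAG in every tested
random 8-node DAG.

**Orientation.** Edges the search leaves undirected are reversible under the
Gaussian likelihood, but not under non-Gaussian disturbances: for a linear
pair, regressing effect on cause leaves residuals independent of the
regressor, regressing cause on effect does not, and a likelihood ratio of
the two orderings detects the asymmetry. Two pitfalls shape the design.
First, the residual density must not assume super-Gaussianity: a Laplace
likelihood ratio picks the wrong direction essentially always under uniform
(sub-Gaussian) noise (0/100 in a direct check at n=1000), so the default
scores each ordering by approximate differential entropies using Hyvärinen's
maximum-entropy approximation (constants 79.047, 7.4129, γ=0.37457), which
is accurate in both regimes; the pure-Laplace variant is retained as an
option for known super-Gaussian data. Second, raw pairwise ratios are
distorted by common causes (~13% wrong on true edges in the 8-node
simulations), so ratios are evaluated along a recursively estimated causal
order: the variable whose pairwise ratios least contradict exogeneity is
extracted, regressed out of the rest, and the recursion continues on
residuals — each edge's ratio is then computed with its possible confounders
already removed, which brought orientation errors on correctly recovered
edges to ≈0 in the same simulations. The post-processor re-examines edges
the search had compelled as well as undirected ones: finite-sample
v-structure errors otherwise propagate (~22% of compelled directions wrong
at n=1000), capping precision near 78%, whereas re-orienting every skeleton
edge reaches ~93%. The skeleton is never changed; edges are directed in
decreasing order of |ratio|, a direction that would close a directed cycle
is flipped (the flip cannot itself close one), and an exactly-zero ratio
keeps the search's own state for that edge. For jointly Gaussian data the
ratio converges to 0 and no reliable orientation is claimed.

**Group comparison.** Each group (per hemisphere) is fitted independently;
the comparison table classifies each recovered skeleton edge as shared,
group-unique, or direction-reversed. Parametric comparison of edge
coefficients across separately searched graphs is deliberately not offered.

## Group statistics

`anova_from_summary` reconstructs the one-way fixed-effects F from printed
group moments (MSB/MSW with sample SDs), which reproduces a published
demographic table's F values from its own printed summaries within rounding
(all five checked values agree within 1%). The brain-level test is a linear
model with group indicator contrasts plus binary covariates (medication,
comorbidity flags); the group effect is the extra-sum-of-squares F against
the covariates-only model, which reduces exactly to one-way ANOVA when no
covariates are supplied. An omnibus multivariate statistic (Wilks/Pillai) is
not implemented: the per-variable F values are what a summary table prints,
and the omnibus variant is underdetermined from summaries. Dunnett's T3 is
approximated through the studentized-maximum-modulus bound computed as
`1 − (1 − p)^m` on Welch-df t statistics — an approximation (exact SMM
tables differ across sources) that is conservative under independence;
Monte-Carlo calibration keeps familywise error ≤ 0.05. Kruskal–Wallis,
simple regression and BH-FDR delegate to scipy/statsmodels behind the
package's interfaces; the FDR family is whatever p-value vector the caller
assembles (the CLI applies it per method across variables and records the
choice in the output).

## Synthetic generators

All generators are pure functions of (spec, seed); the acceptance script and
tests derive every stream from explicit seeds.

*SEM time series.* Each time point is an i.i.d. draw of `x = Bᵀx + e`,
solved by matrix inversion of `I − Bᵀ` (equivalent to topological
substitution); noise families gaussian/uniform/laplace/centered-exponential,
all scaled to the requested SD. Rows are i.i.d. by design — no HRF, no
autocorrelation — because the search consumes extracted ROI series and its
scores assume exchangeable rows; an optional double-gamma HRF convolution
exists but is off by default. Consequences for interpretation: passing
recovery tests shows the search/orientation machinery is correct under the
model's own assumptions; it does not show robustness to hemodynamic
smoothing, scanner drift or motion, which real fMRI adds. The default
8-node circuit spec (thalamus→insula→amygdala/OFC→striatum with hypothalamic
and cingulate inputs, |β| 0.4–0.7, uniform noise, 20 subjects × 200 time
points) mirrors the study's group sizes and a typical task-fMRI volume
count. Random-DAG specs draw Bernoulli(0.3) edges over a random order
(expected degree ≈ 2.1, the usual benchmark density) with |β| ∈ [0.3, 0.8]
and random signs.

*Task schedule.* 280 trials — 100 sucrose-CS, 100 null-CS, 80 saliva-CS —
with exact 80/20 reinforcement counts rather than i.i.d. Bernoulli draws, so
every invariant is deterministic and testable; the 10 fixed initial
reinforced sucrose trials count inside both the 100 sucrose trials and the
80 reinforced ones, keeping all printed totals true; the remaining 270
trials are a seeded uniform shuffle.

*Streamline counts.* Per-tract baseline probabilities drawn log-uniformly
(defaults 0.005–0.05), per-subject counts negative-binomial (dispersion 20)
around probability × total samples, reverse-direction runs at half the
forward probability, volumes from the taxonomy, path lengths uniform 10–60
mm with per-subject jitter; group effects multiply designated tracts' means.

*Behavioral tables.* Per-group normal draws affinely rescaled so sample mean
and SD (n−1) match the target moments exactly, which makes summary-form and
raw-data analyses agree to machine precision.

## Problem sizes and numerical conventions

The orientation-performance simulation uses 100 replicates of 8-node SEMs at
n = 1000; structure-recovery checks use 50 replicates of 20 subjects × 200
time points; statistical calibrations use 2000 Monte-Carlo replicates
(400 for the post-hoc power check). TSV artifacts use tab separators, UTF-8,
Unix newlines and 17-significant-digit floats, and are read back with
round-trip float parsing, so write/read cycles are bit-exact.

## Known limitations

Pattern search assumes i.i.d. rows and linear relations; temporal
autocorrelation in real BOLD data violates the effective sample size behind
`k ln n`. The orientation step needs genuinely non-Gaussian disturbances —
on Gaussian data it (correctly) refuses to orient. Greedy search can return
a local optimum on adversarial finite samples. Connection-strength
normalization divides by the in-circuit seed total, so adding regions to the
taxonomy rescales strengths; comparisons are only meaningful within one
taxonomy. Dunnett's T3 is an approximation, not the exact
studentized-maximum-modulus quantile.
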