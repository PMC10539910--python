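# Methods

This note records the models implemented in `soilbiome`, the assumptions they
make, the defaults chosen where the design was open, and what the synthetic
validation does and does not demonstrate.

## Fertility scoring

Each indicator x is transformed to a membership value in [0.1, 1.0].
S-type (AP, AK): 0.1 below the lower limit L, rising linearly to 1.0 at the
sufficiency limit U. Parabola-type (pH, SOM, AN, TN): 0.1 outside (L, U),
linear ramps into an optimal plateau [O1, O2] at 1.0. Default limits (native
units; SOM/TN g/kg, AN/AP/AK mg/kg):

| indicator | kind | L | O1 | O2 | U |
|---|---|---|---|---|---|
| pH | parabola | 5 | 5.5 | 7 | 7.5 |
| SOM | parabola | 15 | 25 | 35 | 45 |
| AN | parabola | 30 | 50 | 70 | 100 |
| TN | parabola | 0.9 | 1.4 | 2.5 | 3.5 |
| AP | s-type | 20 | — | — | 40 |
| AK | s-type | 100 | — | — | 150 |

Weights come from a PCA of the z-scored indicators (units differ by orders of
magnitude, so scaling is mandatory). The default convention is the
*communality share*: each indicator's summed squared loadings over components
with eigenvalue > 1, normalised to sum 1; a *first-component loading share*
variant is available. With mutually uncorrelated indicators the spectrum is
degenerate at 1 and component retention is seed-dependent — weights are then
only exchangeable in expectation, which is what the test suite checks.
IFI = Σ W·N; in the weighted sum, W denotes the PCA weight (it is the
quantity constrained to sum to 1) and N the membership value. Class
boundaries: IFI < 0.55 → LF, [0.55, 0.75) → MF, ≥ 0.75 → HF; both boundaries
are closed on the side of the higher class and the convention is recorded in
run metadata. With fewer than 7 samples PCA weights are unreliable and the
high-level scorer falls back to equal weights with a warning (the low-level
`pca_weights` stays strict).

## Diversity and group statistics

Alpha diversity is computed on raw counts (no rarefaction by default — an
optional subsampling-without-replacement helper exists), Shannon in natural
log, Chao1 always in the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) to
avoid the F2 = 0 discontinuity. Bray–Curtis is computed on relative
abundances, so sequencing-depth differences do not masquerade as
composition differences. NMDS is non-metric (isotonic) MDS on the
precomputed dissimilarity, best of 50 random restarts, 300 iterations,
tolerance 1e-7, reporting Kruskal stress-1. ANOSIM and Mantel use
permutation p-values of the form (1 + b)/(1 + m), never exactly zero.
Group means are compared by one-way ANOVA with Fisher's LSD pairwise tests
on the pooled error variance; the compact letter display assigns one letter
per maximal clique of the "not significantly different" graph, so two groups
share a letter exactly when their LSD test does not reject.

Environmental distance is Euclidean on z-scored variables (zero-variance
variables dropped with a warning). Distance decay regresses within-group
community dissimilarity on environmental (or spatial) distance by least
squares; significance comes from a Mantel test on the group's submatrices,
since pair distances are not independent observations.

## Constrained ordination

Community matrices are Hellinger-transformed (square root of relative
abundances) before RDA; `none` and `log1p` are available. Predictors are
z-scored and numerically collinear columns dropped. Conditional term effects
use forward selection: at each step the candidate adding the most explained
variance enters (ties broken by column order, so the procedure is
deterministic given a seed), and its pseudo-F — added SS over one df against
the residual SS of the enlarged model — is tested by unrestricted permutation
of the reduced-model residuals, vectorised over replicates. The conditional
"explains %" telescope: they sum exactly to the full model's explained
variance. Note the entered term at each step is the maximum over candidates
while the permutation null does not re-run the selection; empirically the
overall type-I rate at α = 0.05 stays within the calibration band checked by
the tests.

Variance partitioning uses Ezekiel's adjusted R² for the seven non-empty set
unions and inclusion–exclusion for the unique, pairwise and triple fractions;
the residual is 1 − adjR²(all). The decomposition is an exact identity
(fractions + residual = 1), negative fractions are reported rather than
truncated, and a set left empty contributes zero, so a single-set partition
reduces to that set's adjusted R². Per-group VPA is skipped when a group has
fewer samples than predictors + 3.

## Co-occurrence networks

Edges are pairs of prevalence-filtered OTUs (default: present in ≥ 1/3 of the
group's samples — this filter is not standardised in the field and changes
node counts, so it is prominently configurable) whose Spearman correlation of
relative abundances satisfies |ρ| > 0.6 and p < 0.001 (t-approximation). No
multiple-testing correction is applied by default, matching the fixed
thresholds as the statement of record; a Benjamini–Hochberg flag exists.
Modules come from greedy (CNM) modularity maximisation on the unweighted,
unsigned graph; isolated nodes become singleton modules; ties resolve by node
id. Zi is the within-module degree z-score (0 where the module's degree
spread is zero), Pi = 1 − Σ_m (k_im/k_i)², and roles use the thresholds
Zi = 2.5, Pi = 0.62. Average path distance averages over connected pairs
only, because thresholded networks are routinely fragmented.

## Community assembly

**Sloan neutral model.** N is the mean sample total count and the detection
limit d = 1/N. The expected occurrence frequency of a taxon with mean
relative abundance p is 1 − BetaCDF(d; Nm·p, Nm(1−p)). Nm is fitted by
untransformed least squares over OTUs with 0 < p < 1 (log-spaced grid on
[1, 1e7] then bounded refinement), R² = 1 − SSE/SST (may be negative), and
the 95% envelope applies a Wilson binomial interval at the observed number
of samples to the predicted frequency; OTUs are labelled above/within/below
but not interpreted. A known caveat, quantified in the validation: when the
census is a finite multinomial draw, the true detection probability
P(count ≥ 1) is a smooth (beta-binomial) function of abundance, whereas the
fitted form assumes a sharp threshold at d; at high migration (m ≈ 0.5) this
inflates the fitted Nm by roughly 20%, so Nm estimates at high m should be
read as upper bounds. The noise-free inversion (frequencies generated from
the fitted form itself) recovers Nm to better than 1%.

**betaMNTD / betaNTI.** Abundance-weighted (by default) mean
nearest-taxon patristic distance between communities, averaged over both
directions. The null shuffles taxa labels across all tree tips — a
permutation of the patristic matrix — and betaNTI is the z-score of the
observed value against 999 (tests: 199) replicates; the replicate count is
recorded in output metadata. Pairs with zero null spread are flagged NaN and
excluded from fractions. betaNTI is invariant to uniform branch-length
scaling.

**Raup–Crick (Bray–Curtis).** Each null replicate rebuilds every sample with
its observed richness (species drawn without replacement with probability
proportional to occupancy) and observed total abundance (remaining
individuals multinomial, proportional to summed relative abundance), both
estimated from the analysed group's samples only; ties take half weight:
RC = 2((#{BC_null < BC_obs} + ½#{=})/n_null − ½) ∈ [−1, 1]. Because the null
re-estimates its weights from the data, RC on data generated by the null
procedure itself centres slightly above zero — the self-consistency test
pools several tables and allows that offset.

**Process classification.** betaNTI > 2 → heterogeneous selection,
< −2 → homogeneous selection; otherwise RCbray > 0.95 → dispersal
limitation, < −0.95 → homogenizing dispersal, else undominated. Fractions
are reported per group over within-group pairs (consistent with per-group
percentages; whether between-group pairs should contribute is genuinely
ambiguous, and the within-group choice is flagged here). The neutral-model
and null-model routes answer related but different questions and are always
reported side by side, never merged.

## Synthetic data generator

The generator's role is to produce inputs whose assembly regime and fertility
structure are known, at the scale of a regional survey (~123 fields in three
fertility classes).

* **Chemistry**: per-sample normal draws around LF/MF/HF group profiles
  (means and standard errors of the 13 measured variables from a three-class
  survey of that size); SE × √41 converts a group standard error to a
  per-sample SD at the default group size of 41 (= 123/3). Draws truncate at
  0; pH clips into (0, 14).
* **Phylogeny**: pure-birth tree (dendropy), scaled to height 1, tips named
  OTU0000…; per-tip environmental optima evolve by Brownian motion along the
  tree so selection leaves a phylogenetic signal — without it betaNTI could
  not distinguish selection from drift.
* **Metacommunity**: ranked lognormal abundances (σ_log = 1.5). Phylum labels
  are assigned to contiguous clades so Proteobacteria + Acidobacteria +
  Actinobacteria exceed 60% of relative abundance, matching the taxonomic
  profile of agricultural soils.
* **Regimes**: *neutral* draws each sample's composition from
  Dirichlet(N·m·p) — the stationary approximation of Sloan's model — then a
  multinomial census of N individuals; *selection* weights the metacommunity
  by exp(−(env − optimum)²/2σ²) with the z-scored simulated pH as the
  environmental axis (pH is the canonical driver of soil bacterial
  composition); *dispersal-limited* samples from local metacommunities
  perturbed by a log-Gaussian field with exponential spatial correlation
  (decay length 0.2 on a unit square), so similarity decays with distance.
  Defaults: 30 samples × 150 OTUs, N = 10 000, m = 0.5, σ = 0.5.

What passing on synthetic data shows: the estimators recover the generating
regime and parameters under the model families they assume. What it does not
show: robustness to compositional artefacts of real sequencing (PCR bias,
variable depth, chimeras), to non-Brownian trait evolution, or to regimes
mixing selection and dispersal in one landscape. The generator also produces
denser, more correlated communities under selection than real surveys show,
so synthetic network properties (density, modularity) should not be compared
to empirical tables quantitatively.

## Numerical choices and problem sizes

Permutation tests default to 999 replicates; the validation suite runs 199
for null models and 500-replicate calibration batteries, sizes chosen to
keep the full validation under a minute while leaving binomial error on
type-I rates near ±1%. The NCM recovery scenario uses 100 samples × 300
OTUs; assembly recovery 30 × 150; the panmictic distance-decay battery 50
seeds at 20 × 100. A single global seed derives per-stage seeds by hashing
the stage name, so any stage reruns in isolation with identical output.

## Known limitations

* Raw sequence processing (denoising, OTU picking, taxonomy assignment) is
  out of scope; the pipeline starts from a count table.
* The NCM fit's Nm bias at high migration (above) is inherent to the
  sharp-threshold detection approximation.
* Greedy modularity is resolution-limited on very small modules; the Zi–Pi
  thresholds (2.5 / 0.62) are conventions, not estimates.
* The RDA permutation scheme tests each entered term without re-running the
  forward selection inside the null; selection bias on the first entered
  term is possible in small candidate sets, though calibration stays within
  the tested band.
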