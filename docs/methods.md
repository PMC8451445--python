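# Methods

## The problem this package addresses

Sika deer (*Cervus nippon*) reshape cool-temperate forest understoreys, but
individual plant species differ enormously in how vulnerable they are:
some are selected by deer from the moment a population establishes and
collapse within years, others are browsed only after preferred forage is
depleted, and others are eaten yet persist. `browsevuln` implements a
space-for-time analysis of this process over sites that differ in *deer
establishment class* — how long deer have been present (since before 1978;
1979–2003; 2004–2011; 2012–2014) — combining three evidence streams:

1. **Understory coverage.** Twenty 2×2 m plots per site, percent cover per
   species scored at 5 % intervals, trace cover recorded as 1 %.
2. **Browsing damage.** For each species present at a site, ten plant
   units (ramets or current-year shoots) classified into four ordinal
   damage classes — CL1 none, CL2 1–10 %, CL3 11–50 %, CL4 51–100 % — and
   summarised by the mean damage grade

   MDG = (0·CL1 + 5·CL2 + 30·CL3 + 75·CL4) / N,  range 0–75.

3. **Diet DNA.** Fecal samples profiled by trnL P6-loop metabarcoding: each
   read is assigned to a plant taxon by exact sequence identity against a
   reference database, and a sample is summarised by each taxon's share of
   its assigned reads (relative read abundance).

## Statistical machinery

* **Diversity.** Per-site species richness and Shannon–Wiener H′ (natural
  log, shares of summed plot cover), compared across establishment classes
  by GLM (Poisson/log for richness, Gaussian/identity for H′) with
  likelihood-ratio χ² tests. Coefficients come from statsmodels' IRLS.
* **Composition.** Bray–Curtis dissimilarity on site-level cover (plots
  summed before the distance is taken) or on per-sample read proportions.
  One-factor PERMANOVA partitions the Gower-centred squared-distance
  matrix; p-values come from label permutations (999 by default), restricted
  to within-stratum shuffles when samples are blocked by site. Because
  establishment class is constant within a site, the site-blocked diet test
  is deliberately unresolvable (p ≈ 1) whenever diet varies mostly between
  sites — this asymmetry is the analysis's point, not a defect. An
  exhaustive mode (n ≤ 8) enumerates all n! permutations for exact small-
  sample p-values and is used by the test-suite oracle.
* **Dispersion.** A betadisper-style check: principal-coordinate embedding
  with imaginary-axis correction for negative eigenvalues, distances to
  group centroids, one-way F assessed by permuting those distances. Sums
  of squares at machine-noise scale are treated as exactly zero so
  identical group geometries give F = 0 rather than a ratio of rounding
  errors.
* **Ordination.** Non-metric MDS minimising Kruskal stress-1; SMACOF
  majorisation with isotonic (primary tie) regression, 20 starts — metric
  principal coordinates first, Gaussian jitter thereafter — best stress
  reported.
* **Space.** dbMEM eigenvectors: inter-site distances truncated at the
  longest minimum-spanning-tree edge (larger entries set to 4× the
  threshold), positive-eigenvalue principal coordinates retained. Each
  vector is tested marginally by permutation: squared correlation against
  a univariate response (detrended on x, y first), or the Gower-projection
  R² against a distance matrix. Forward selection is intentionally not
  implemented; distance-matrix responses are not detrended because the raw
  data matrix is not available at that interface.
* **Mixed model (fidelity mode).** A Poisson GLMM with per-site random
  intercept, fitted by maximising the Laplace-approximated marginal
  likelihood (inner Newton per site, outer Nelder–Mead). It exists to
  mirror plot-level analyses that include site as a random effect; it is
  not on the main pipeline path.

## Profiles, clustering, and the gap statistic

Each species is reduced to a 4-vector over establishment classes, ordered
oldest→youngest (Y1978, Y2003, Y2011, Y2014): class means of site-level
summed cover, of MDG (cells where a species was not surveyed are excluded,
since absence of a survey is not absence of damage), or of mean per-sample
read proportion. The coverage and MDG streams keep only species observed
in at least one site of every class; the read stream keeps every detected
taxon. Species never browsed anywhere are dropped from the damage stream.

Profiles are scaled by their own maximum before K-means (the clustering
should capture the *shape* of variation across classes, not abundance);
`raw` and `z` modes are available because this choice is genuinely open.
K-means uses k-means++ with 10 restarts; the cluster count is chosen by
the gap statistic with B = 50 uniform reference sets drawn over each
dimension's observed range, s_k = sd(log W*)·√(1+1/B), and the smallest k
with Gap(k) ≥ Gap(k+1) − s_{k+1}.

## From clusters to vulnerability groups

K-means indices are arbitrary, so each cluster is translated into a
semantic label from its centroid shape:

* coverage: **decline** iff the Y1978 value is the centroid's minimum *and*
  at most 0.75 of its peak. The margin matters: a flat cluster's argmin
  lands on Y1978 a quarter of the time by chance, and without the margin
  whole tolerant clusters get misread as declines.
* damage: **early** if damage is already ≥ half its peak at the youngest
  class; **gradual** if it peaks at Y1978 while low at Y2014; else other.
* diet: **recent** / **old** if the youngest-class share exceeds the
  Y1978 share by ≥ 0.25 of the peak (or vice versa); else other.

A species is *early-browsed* if its damage cluster is early, it is on the
G4 list (absent from all Y1978 sites yet browsed elsewhere — plants that
plausibly disappeared under browsing), or its diet cluster is recent.
The editable YAML rule table then assigns groups, first match wins:
no evidence → unclassified; coverage unaffected → E (diet evidence) or
F (damage only); coverage declined → A (early) or C (late); coverage
unknown (species failed the every-class presence filter) → B (early) or
D (late). Every assignment records the rule that fired, and species
matching no rule are reported, never dropped. The E/F split follows the
evidence stream (E diet-detected, F damage-only); this is a declared
default, not a claim about any particular field system.

## The synthetic generator

`simulate()` draws a complete study under the emulated design: 22 sites
(5/4/4/9 per class) on a 300×200 km box with a class–longitude gradient,
20 plots/site, occupancy-Bernoulli × gamma-magnitude cover snapped to the
field grid, damage from an ordinal logit (cutpoints 1/3/5 on the latent
scale; a palatability-neutral intensity of ≈ 1 yields MDG ≈ 5–10), and 63
fecal samples with Dirichlet-multinomial composition (concentration 40)
and negative-binomial depth (mean 6 700 ≈ 420 000 reads / 63 samples,
dispersion 2). Default species mix: 10 A, 8 B, 10 C, 8 D, 6 E, 6 F and 12
unbrowsed/undetected "neutral" species — a deliberately scaled-down
roster whose archetype trajectories (declared in the module) mirror the
grouping semantics above. The `neutral` archetype is strictly unbrowsed
(latent intensity −30) so that no-evidence species genuinely exercise the
unclassified path. The three `*_effect` knobs interpolate every class
profile toward its mean: 0 produces an exact permutation-null study used
for calibration tests.

What the generator does *not* emulate: sequencing error and PCR bias
(reads are exact copies of reference sequences, plus planted too-short
reads), seasonal diet shifts, pellet substructure within a sample,
between-site habitat heterogeneity beyond the random draws, and real
floristic structure. Passing tests therefore demonstrate that the
pipeline's inference machinery is correct and calibrated under its own
model, not that the ecological conclusions transfer to any particular
forest.

## Numerical choices and problem sizes

Permutation p-values use the (1 + count)/(1 + B) estimator; seeds are
mandatory in pipeline mode, and all stage seeds derive from one
`SeedSequence`. NMDS convergence tolerance is 1e-7 with 300 iterations.
The end-to-end recovery check runs 50 replicate studies through
simulate → score → cluster → classify (the permutation-test arms are not
needed for recovery and are exercised separately); null-calibration checks
use 500 label-exchange datasets (n = 30, 199 permutations) and 120
zero-effect studies. The acceptance script reruns the full pipeline once
and 10 recovery replicates.

## Known limitations

Exact-match read assignment is conservative: real P6 reads with
sequencing errors would inflate `no_match`; there is no mismatch
tolerance by design. The gap statistic uses the simpler uniform-box
reference; a PCA-aligned reference is available but not default. The
Laplace GLMM assumes a single random-intercept level. The rule table's
E/F distinction and the weak G4 reading (`strict` mode available) are
configurable because the underlying integration is genuinely
under-determined; changing them changes group membership, which is why
both ship as explicit configuration rather than constants.
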