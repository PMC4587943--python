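# Methods and design notes

## Data model and classification

A *region* carries an area (km², entering the model only through the
offset), religion shares of total population, and area fractions of four
aggregated anthrome classes (Dense Settlements + Villages → Settled;
Forested + Wildlands → Natural; Croplands and Rangelands pass through).
Fire counts are held as a dense integer panel over
(region, weekday 1=Mon…7=Sun, year) with explicit zeros, because the
likelihood treats yearly totals per weekday as conditionally independent
replicates sharing one mean.

Classification rules, with their threshold conventions taken literally:

* **Religion.** A region is Christian (Muslim) when that faith is *strictly
  over* 75% of the Christian + Muslim total; otherwise mixed. Regions where
  Christian + Muslim believers are under 50% of the total population are
  excluded (only the Abrahamic faiths prescribe a weekly rest day), as are
  regions with missing religion data. Missingness is encoded as empty CSV
  cells, never zero, because a zero share is a legitimate value.
* **Anthrome.** The single class covering *at least* 50% of area
  (inclusive) wins; otherwise Mixed. The only possible tie is exactly
  0.5/0.5; it resolves deterministically Cropland > Natural > Rangeland >
  Settled with a logged warning (ties are measure-zero in real data).
* **Exclusions** apply in order: cumulative fire density below
  0.1 counts·km⁻² over the study period (strict), then the religion-share
  rule, then missing data; the report attributes each region to the first
  rule it fails. The ordering is a convention — overlaps are possible in
  principle — and the report makes it explicit.

## Likelihood and priors

Counts are negative binomial with shape θ (variance μ + μ²/θ) and log-mean

    ln μ_iW = ln(area_i) + x_iWᵀα + z_i ,

with corner-constrained dummy coding in the fixed, documented level order
(religion: Christian, Muslim, Mixed; weekday 1…7; anthrome: Cropland,
Natural, Rangeland, Settled, Mixed; reference = first level). Contrast
results are invariant to the coding choice, which the test suite verifies
by exact reparameterisation.

The spatial term z follows an intrinsic CAR (ICAR) prior on the region
contiguity graph: log-density `((n−k)/2)·ln τ − (τ/2)·Σ_{i~j}(z_i−z_j)²`
with n nodes and k connected components, identified by sum-to-zero per
component; isolated regions have z fixed at 0. No generalised-variance
scaling of τ by graph structure is applied — τ is the raw pairwise
precision, the convention of the ICAR literature this analysis follows.

Priors (the source analysis used an INLA-family engine without stating
them; these are weakly-informative defaults of that engine family, all
configurable through `PriorSpec`): α_j ~ N(0, 31.6²) i.i.d.;
ln θ ~ N(0, 10²); τ ~ Gamma(shape 1, rate 5·10⁻⁵). The θ prior is placed
on the log scale, which is also the sampling scale.

## Posterior computation

`fit_mcmc` runs an adaptive Metropolis-within-Gibbs sampler, one
independent stream per chain (spawned from the user seed, so runs are
exactly reproducible). Blocks per sweep:

1. **α (joint MALA).** A Metropolis-adjusted Langevin proposal
   preconditioned by the inverse Fisher information of a penalised IRLS
   fit at initialisation; the scalar step adapts toward 57% acceptance
   during burn-in and freezes afterwards. Chains start at the IRLS mode
   plus overdispersed noise.
2. **ln θ** — scalar random walk, step adapted toward 44% acceptance
   (skipped when θ is fixed, which the toy oracles use).
3. **z (coloured single-site).** A greedy graph colouring partitions
   regions so that no two same-colour regions are adjacent; within a
   colour the full conditionals are mutually independent given the rest,
   so all sites of a colour are proposed and accepted/rejected in one
   vectorised step. Per-colour steps adapt toward 44%.
4. **Translation moves.** Region-level design columns (religion/anthrome
   dummies — constant across weekdays within a region) are confounded with
   the spatial field: the likelihood is flat along `α_j → α_j + δ,
   z → z − δ·u_j` where `u_j` is the column's region-level pattern. A
   dedicated move proposes exactly this shift; η is unchanged, so
   acceptance involves only the ICAR and coefficient priors. Without these
   moves the sampler's effective sample size for region-level effects
   collapses by two orders of magnitude.
5. **τ** — conjugate draw from `Gamma(a + (n−k)/2, b + q(z)/2)`, `q` the
   ICAR quadratic form (verified analytically in the tests).
6. **Recentring.** z is recentred to mean zero per component; on a
   connected graph the subtracted mean is added to the intercept, leaving
   the likelihood exactly invariant. On disconnected graphs the
   compensation cannot be absorbed by a single intercept and the recentring
   is the standard approximation; the synthetic lattices are connected.

Defaults: 4 chains × 5,000 iterations, 2,000 burn-in, thinning 2 —
a 100-region, 21-coefficient interaction model fits in ~10 s on one CPU
with split R-hat ≈ 1.00 and ESS ≈ 2,000 for every fixed effect. All
adaptation freezes at the end of burn-in, preserving detailed balance for
the retained draws. R-hat > 1.1 attaches a warning to the samples rather
than failing.

The likelihood code exploits the replicate structure: the μ-dependent part
collapses over years (`Σ_t y_t·ln μ` becomes `Ȳ·ln μ`), so only the
θ-update touches per-observation log-gamma terms. The log-likelihood of
every retained draw is stored with the draw; DIC uses these stored values,
and a test asserts they equal an independent recomputation.

## DIC

`DIC = D̄ + p_D` with `D = −2·log-likelihood` *conditional on z* (the
random effects count as parameters, matching how INLA-family engines report
DIC for such models — whether the source analysis integrated z out is not
stated, so the choice is documented here). The plug-in deviance is
evaluated at the posterior means of α and z and at θ = exp(mean ln θ); the
plug-in rule is isolated in one function so alternatives are testable.

## Contrasts and contour probabilities

Contrasts compare linear-predictor cell means
`(intercept + religion + weekday + interaction)` between two
(religion, weekday) cells. Offsets and spatial effects are excluded: they
are constant across weekdays within a region and the cross-religion
hypotheses are defined net of them; anthrome terms, when present, are held
at the reference level and cancel.

The contour probability of zero — one minus the content of the HPD
interval just covering zero — is estimated by density ordering:
`p̂ = (1/S)·Σ 1[f̂(x_s) ≤ f̂(0)]` with a Gaussian-kernel density estimate
computed on a binned grid whose nodes include 0 exactly. Two numerical
choices matter:

* the ordering bandwidth is **twice** Silverman's rule — only the density
  *ordering* enters, and for near-Gaussian posteriors smoothing does not
  move the HPD boundary (a Gaussian smoothed by a Gaussian keeps the same
  ordering) while it suppresses estimation noise;
* the comparison allows one standard error of KDE noise at zero, so ties
  on a flat mode resolve toward inclusion; a perfectly symmetric sample
  then yields p̂ = 1 rather than 1 − O(noise).

Accuracy: tail values (p ≲ 0.05) are reliable to a few 10⁻⁴ at S = 10⁶ and
about 10⁻³ at S = 10⁵; near-mode values (p ≳ 0.5) carry noise of order
0.01–0.02, which is irrelevant for testing. The normal-approximation
variant `2Φ(−|mean|/sd)` is always reported alongside.

Benjamini–Hochberg adjustment is the standard step-up rule applied jointly
across the 15-contrast family (`min_{j≥i} p_(j)·m/j`, capped at 1, stable
under ties). Note that BH-adjusted values are *not* idempotent under
re-adjustment — (0.1, 0.9) adjusts to (0.2, 0.9), which re-adjusts to
(0.4, 0.9) — so the invariants tested are elementwise dominance and order
preservation, plus equality with a brute-force implementation and with
statsmodels.

## Synthetic data

The generator emulates the study design, not the satellite data: a
rows × cols lattice (rook or queen contiguity) of regions with log-normal
areas (median 2,000 km², log-sd 0.5); religion labels grown from a northern
Muslim seed and a southern Christian seed by graph distance with a mixed
band between (clustering strength interpolates toward i.i.d. labels; the
default 0.9 produces join-count statistics far above the permutation
null); anthrome fractions from a Dirichlet with configurable class weights
(cropland-leaning by default; `{"Cropland": 1.0}` gives the cropland-only
stratum the contrast analysis targets); religion *fractions* drawn so the
labels classify back correctly, exercising the classification code.

Counts follow the model itself: a fresh ICAR draw z (sampled exactly via
the eigendecomposition of each component Laplacian restricted to its
non-null eigenspace), log-means with religion-specific rest-day deficits —
Sunday −0.21 for Christian regions, Friday −0.21 for Muslim regions, the
magnitude of the published cropland contrasts — and NB replicates drawn
through a gamma–Poisson mixture, keeping the generator independent of the
pmf code it tests. Defaults: 10×10 lattice, **nine** annual replicates
(the study's replication), θ = 3 (matching the residual log-scale noise
the published contrast sds imply), τ = 2 (spatial sd ≈ 0.3–0.4, large
relative to the per-region likelihood noise, so the ICAR term genuinely
matters), base log-density −3 (≈ 100 fires per region-weekday-year at the
median area — well above the exclusion threshold, as the analysed regions
are). Recovery tests use three years where speed matters; the truth record
returned with every panel includes the corner-coded coefficient vector for
the religion × weekday design, so recovery is checked coefficient by
coefficient.

What the generator does *not* emulate: satellite detection geometry,
overpass gaps, cloud-cover missingness, false-alarm contamination,
irregular region shapes and sizes, or religion/land-use gradients within a
region. Passing tests therefore demonstrate the statistical machinery is
correct under the model's own assumptions, not that the substantive
findings would reproduce from raw data.

## Problem sizes

The test suite's simulation studies are sized for a single CPU: parameter
recovery uses ten seeds of the 10×10 / 3-year / 4×5,000-iteration setting;
model selection uses five seeds each of deficit and null data at the
default nine-year replication with 2×4,000-iteration chains; smaller
property checks use 4×4 or 5×5 lattices. The full suite runs in about four
minutes; the acceptance script in seconds.

## Known limitations

* The MALA preconditioner is the z = 0 Fisher information; it is not
  re-estimated after burn-in. Mixing is excellent for the model spaces
  enumerated here; heavily confounded designs beyond them may need the
  covariance re-adaptation this package deliberately omits for simplicity.
* DIC is conditional on z; integrated (marginal) DIC is not implemented.
* Absolute DIC values and posterior summaries from the original
  atmospheric-data analysis are not reproducible without the original
  region system and fire detections; the pipeline reproduces the
  *structure* of those results (which model wins, which contrasts are
  negative, the multiplicity arithmetic) on synthetic data.
* Disconnected contiguity graphs use approximate recentring (see above);
  exact handling would require one intercept per component.
* Polygon ingestion computes queen contiguity by pairwise `touches`,
  which is O(n²) and intended for small systems.
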