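# Methods

This note documents the statistical models, the conventions that make the
numbers reproducible, what the synthetic-data generators do and do not
emulate, and the design choices made where more than one defensible option
existed.

## Interspecific allometry

The regression units are **species-level means**: specimens are averaged
per species (equal weight per specimen) before any interspecific model is
fitted. Specimens missing glossa or prementum contribute to the IT mean
only; the proboscis mean is the mean of per-specimen glossa+prementum sums,
matching the measurement definition (the proboscis is not measured
directly, it is the sum of its parts).

Both response and predictor enter on the natural-log scale, so the fitted
line `ln L = a_f + b ln IT` is the power function `L = exp(a_f) · IT^b`.
Seven candidate models per response are fitted on one common species set
(listwise deletion happens once, before fitting, so all AIC values compare
the same data):

| grouping | IT term | coefficients (6 families) |
|---|---|---|
| family | common slope | 7 |
| family | group slopes | 12 |
| family | absent | 6 |
| tongue group | common slope | 3 |
| tongue group | group slopes | 4 |
| tongue group | absent | 2 |
| none | common slope | 2 |

Conventions:

* **AIC** uses the Gaussian maximum-likelihood log-likelihood with the
  residual variance counted as an estimated parameter:
  `loglik = −(n/2)(ln 2π + ln(rss/n) + 1)`, `AIC = −2·loglik + 2(k+1)`.
  This matches the convention of the mainstream statistical environments
  for `lm`-style fits. A perfect fit (rss = 0) is reported with AIC = −∞
  and a warning rather than an error.
* **Dummy coding** is treatment coding against the alphabetically first
  group present (Andrenidae; "long" for tongue group). The choice is
  internal: reported power-function parameters are always absolute
  per-family values (reference intercept plus offset), and per-family
  slopes likewise under an interaction model.
* **Selection** is argmin AIC; exact ties (possible only on degenerate
  data) break toward fewer coefficients, then a fixed candidate order.
* **Sexes are pooled by default.** A specimen-level F test
  (`test_common_slope_by_sex`) compares the additive model
  `ln L ~ sex + ln IT (+ species intercepts)` against one adding
  `sex × ln IT`; its type-I error is calibrated in the test suite. The
  `sex_filter` option supports male-only reruns.

The proboscis is fitted directly as its own response (not constrained to
the glossa+prementum sum); the three responses get independent model
selections.

## Trait and foraging-distance prediction

`predict_length` evaluates `exp(a_f + b_f ln IT)` exactly; identities
(`predict(1) = exp(a_f)`, `predict(c·IT) = c^b · predict(IT)`) hold to
floating-point precision and are asserted in the acceptance suite.

Foraging distance uses `10^(c0 + c1 · log10 IT)` with the IT unit declared
in the config (`mm` or `cm`) because the body-size literature mixes units;
output is km. The published foraging-regression constants are deliberately
not bundled — transcribe them into a config; every config in this
repository is synthetic and labelled so. With coefficients unset the API
raises an instructive error rather than inventing values.

Region summaries are **multi-membership**: a species contributes to every
rainfall region it occurs in, so per-region species counts can sum to more
than the species total (the bundled 56-species pattern sums to 89:
winter 44, aseasonal 13, early summer 12, late summer 20). Species with no
region are reported under `unassigned`. For *modeling* (PGLS/LMM) each
species gets the single region holding most of its specimen records, ties
breaking by the fixed order winter < aseasonal < early summer < late
summer.

## Phylogenetic comparison

* **Pruning** takes the induced subtree on the kept tips, summing branch
  lengths through collapsed degree-2 nodes. The path from the original
  root to the subtree's MRCA survives as a root stem edge, and depths and
  Brownian covariances **count the root stem** as history shared by all
  tips; root-to-tip distances are therefore invariant under pruning.
* **Polytomy grafting** replaces a genus tip whose terminal edge has
  length ℓ by a stem of ℓ/2 ending in a polytomy whose species tips each
  subtend ℓ/2. The published description of the construction ("equal
  branch length relative to the genus branch length") is ambiguous; the
  midpoint split is adopted because it preserves tip depths and
  ultrametricity, which any reasonable reading requires. A single-species
  genus keeps the same split with the species label replacing the genus.
* **Brownian covariance**: `V_ii` = root-to-tip depth, `V_ij` =
  root-to-MRCA shared path (computed from depths and patristic distances).
  Numerically singular V gets a documented, logged 1e-10 diagonal jitter.
* **PGLS** solves the whitened least-squares problem (Cholesky of V), which
  equals `β = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y`; the log-likelihood profiles the scale σ².
  The region ANOVA is the F test on whitened residuals with conventional
  degrees of freedom `(g−1, n−g)` for a g-level factor. (A published
  analysis of this design reports F(1, 3) with a 4-level factor and 56
  species; that df pair is inconsistent with standard ANOVA bookkeeping
  and is not reproduced.) On a star tree the whole stack reduces exactly
  to OLS/classical ANOVA, which the tests assert.
* **LMM**: `ln IT ~ region (or 1) + (1|subfamily) + (1|tribe) + (1|genus)`,
  nested, fitted by **ML** (not REML) because models are compared by AIC
  and likelihood ratio. The implementation profiles out the fixed effects
  and residual variance and maximises over the three variance *ratios*
  with a derivative-free optimiser, always also evaluating the exact
  zero-boundary candidate — so degenerate data collapse cleanly to the OLS
  likelihood (to machine precision, asserted to 1e-6). The fit agrees with
  statsmodels' MixedLM (ML) to ~1e-4 in log-likelihood on test data.
  `AIC = −2·loglik + 2·npar` with npar = fixed effects + 3 variance
  components + residual variance.

## Synthetic data: what it emulates, and what it does not

Generator defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| species mean IT | log-uniform on 0.99–4.42 mm | the measured regional IT range; log-uniform conditions the ln-ln slope well |
| species per family | 19/19/18/18/18/18 (=110) | the interspecific sample size |
| specimens per species | 10 | unit-tray sampling depth |
| ln-scale noise sd | 0.1 | species-level scatter around the family line |
| generating coefficients | bundled published set | proboscis/glossa common slopes 0.96/1.04; prementum per-family slopes |
| backbone | 7 genera, pure-birth, rate 1 | the regional genus count |
| Brownian rate σ² | 0.05 (root ln 2.58) | gives between-species ln-IT spread ≈ the observed range |

Noise is applied to glossa and prementum independently and the proboscis is
recomputed as their sum — so the generated proboscis is only approximately
a power law, exactly as the measurement definition implies. All specimens
of a species share the species IT. The pure-birth simulator extends the
tree past the n-th split by the waiting time to the next (unrealised)
split, so pendant edges are strictly positive and no two tips coincide —
without this the youngest cherry has zero-length edges and the Brownian
covariance is singular.

Not emulated: within-species IT variation, measurement error on IT,
unbalanced specimen counts correlated with body size, museum digitisation
artifacts, and any phylogenetic signal in the *allometric* residuals
(species are exchangeable within family in the morphometric generator).
Passing tests therefore validate the estimators under the model's own
assumptions, not robustness to these real-data complications.

Recovery simulations use one specimen per species so the species-level
noise is exactly the nominal sd (with k specimens the species-mean noise
would shrink by √k).

## Numerical choices

* OLS via `numpy.linalg.lstsq` with an explicit rank check; singular
  designs raise instead of silently pseudo-inverting.
* Whitening via triangular solves with the Cholesky factor, never explicit
  inverses.
* Region factors are dummy-coded against the first region present in the
  fixed order.
* LMM optimiser: Nelder-Mead on the square-root scale of the variance
  ratios, two starts (0.5, 0.05), tiny components clipped to the boundary
  and re-evaluated; the best of all candidates (including exact zero) is
  reported.

## Known limitations

* AIC selection between the additive and interaction models has an
  irreducible ~7.5% false-interaction rate (P(χ²₅ > 10)) when the additive
  model is true; this is a property of AIC itself, independent of noise
  level, so the additive model "wins" in ~92–93% of replicates, not more.
* ML variance components estimated from m groups carry sampling CVs of
  roughly √(2/m). With taxonomically realistic group counts (tens of
  subfamilies at best for n = 500 observations), per-replicate recovery of
  an outer variance component to better than ±25% is not achievable; the
  estimator is validated instead by its agreement with an independent
  implementation and by its boundary behaviour.
* The PGLS assumes the supplied tree and pure Brownian errors; no Pagel's
  λ or OU relaxation is provided.
* Foraging-distance output is only as meaningful as the user-supplied
  coefficients; the bundled examples are synthetic.
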