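# Methods

## The estimation problem

A litter-addition incubation mixes dry plant litter into soil in closed
jars and asks, at the end of the run, how much of the carbon that
disappeared came from the litter and how much from the native soil
organic carbon (SOC). When the litter comes from C3 plants
(δ¹³C ≈ −28‰) and the soil developed under a C4 crop
(δ¹³C ≈ −16.5‰), the isotopic contrast acts as a natural tracer and no
labelling is required.

## Two-pool mixing model

At the end of incubation the soil–litter mixture's total organic carbon
is the sum of the two pools, and its bulk isotopic signature is their
carbon-weighted mixture:

    TOC_final              = SOC_final + C_litter
    δ¹³C_final · TOC_final = δ¹³C_native · SOC_final + δ¹³C_litter · C_litter

Solving for the litter-derived pool,

    C_litter = TOC_final · (δ¹³C_native − δ¹³C_final) / (δ¹³C_native − δ¹³C_litter)

Everything else is bookkeeping: `SOC_final = TOC_final − C_litter`,
SOC mineralization `= SOC_initial − SOC_final`, litter-released C
`= litter C added − C_litter`. The priming effect (PE) of a treatment is
the treatment-minus-control contrast of SOC mineralization, and priming
efficiency is PE per unit litter added, `PE · soil_mass / litter_mass`.

Assumptions inherited from the design, all enforced or surfaced by the
code:

* the litter's δ¹³C does not change during incubation (no decomposition
  fractionation correction is applied);
* the two end-members differ — identical end-member signatures raise a
  degenerate-mixing error;
* for litter mixtures the *measured* mixture δ¹³C and chemistry are
  used, never the equal-proportion expectation (which is provided only
  as a diagnostic, including a C-mass-weighted mixture δ¹³C);
* a δ¹³C_final outside the closed interval spanned by the end-members
  is physically impossible under the model and indicates measurement
  error; the estimate is returned **unclamped** with a flag, because
  clamping would bias the priming contrast. Negative derived pools are
  likewise flagged, never truncated.

## Priming contrasts and uncertainty

Each treatment jar is contrasted against the mean of all control jars
(the design gives no 1:1 pairing); the treatment PE is the mean of the
per-jar contrasts and its SE comes from their spread. Folding the
control-mean uncertainty into that SE (in quadrature) is available as an
option and off by default, since published mean ± SE values of this kind
rarely include it. Per-jar uncertainty for all derived pools is
propagated by seeded Monte Carlo: each measured input is perturbed by
independent normal errors with its stated SE, the partition is
recomputed per draw, and empirical SEs and 95% intervals are reported.
Non-finite draws are excluded and counted.

Priming efficiency carries a unit subtlety: PE (μg C g⁻¹ soil) times
soil/litter mass ratio has magnitude ~10⁴–10⁵ μg C g⁻¹ litter, while the
quantity is conventionally printed at tens of units. Both scales are
implemented behind a flag; the default (`milli`) divides the raw value
by 1000 so reported numbers sit on the conventional printed magnitude.

## Synthetic incubation generator

The generator emulates the study design end to end: 3 litter species
(`Ah`, `Cm`, `Ps`) and their 4 equal-proportion mixtures, plus a
no-litter control, 5 replicate jars each (40 jars), 2 g litter on 200 g
soil, 111 days, with the packaged measured chemistry as the litter
traits. Defaults, with why:

| parameter | default | rationale |
|---|---|---|
| `SOC_initial` | 8000 μg C g⁻¹ soil | sandy cropland topsoil, ~0.8% SOC |
| `d13C_native` | −16.54 ‰ | C4-maize soil signature |
| `base_mineralization` | 321 μg C g⁻¹ soil | unprimed control loss over the run |
| decay `k = k₀·exp(k_N·N + k_L·L)` | k₀ = 0.0015 d⁻¹, k_N = +0.02, k_L = −0.002 per mg g⁻¹ | single-pool decay; N accelerates, lignin retards; yields 12–23% litter C released over 111 d |
| priming `PE = β₀ + β_N·N + β_Ce·Ce` | β₀ = 150, β_N = −10, β_Ce = +2.5 μg C g⁻¹ soil per mg g⁻¹ | injects the expected sign structure (N suppresses, cellulose fuels priming); treatment PEs span ≈124–525, so priming is ≈28–62% of SOC mineralization and efficiencies ≈12–53 on the reporting scale |
| jar noise | `priming_jar_sd` = 10, `base_jar_sd` = 10 μg C g⁻¹ soil | see below |
| measurement noise | `toc_meas_sd` = 5 μg C g⁻¹ soil, `d13c_meas_sd` = 0.01 ‰ | see below |
| community | 8 bacterial phyla + 6 fungal classes, Dirichlet concentration 200, library 10⁴ | baselines at typical agricultural-soil composition; designated taxa respond log-linearly to soluble sugar, phenols and condensed tannin |

Observations are assembled by running the mixing identity *forward*
exactly (TOC_final as the pool sum, δ¹³C_final as the exact C-weighted
mixture) before adding measurement noise, which gives the generator its
central guarantee: at zero noise every jar inverts through the
partitioning to its ground truth at machine precision. Because the
noise is additive, independent and zero-mean on TOC_final and
δ¹³C_final, the recovered PE is exactly unbiased — verified empirically
over 1000 simulated jars.

All randomness flows from one root seed through four named substreams
(decay, priming, measurement, community), so any stage can be re-run
independently and datasets are byte-reproducible.

### What the noise defaults mean — and do not mean

The default noise regime is deliberately *clean*: δ¹³C to 0.01‰ and TOC
to 5 μg g⁻¹ correspond to a best-case analytical setting, and the
jar-level biological spread (sd 10 μg C g⁻¹ soil) is well below what
field-collected soils show. The defaults are set so that the generator
fulfils its stated role — providing a regime in which the chemistry
drivers of priming are *recoverable*, so that the estimation and
selection machinery can be verified against known truth (≥90% correct
sign selection and ≥90% CI coverage over repeated experiments).

Passing these tests therefore demonstrates correctness of the
estimators, not field-scale statistical power. At realistic incubation
noise (per-jar SOC-mineralization sd of 40–100 μg C g⁻¹ soil, the level
implied by published treatment SEs), driver *selection* from only 7
distinct litter chemistry profiles is unreliable: several trait subsets
predict the 7 treatment-level priming values to within ~16 μg C g⁻¹
soil of each other, which such noise cannot distinguish. The pipeline
still estimates pools and priming correctly there — only the
identification of *which* traits drive priming degrades.

## Community statistics

Observed richness and bias-corrected Chao1
(`S_obs + F1(F1−1)/(2(F2+1))`) come from scikit-bio; Bray–Curtis
dissimilarity (`1 − 2Σmin(a,b)/Σ(a+b)`) from scipy; both wrapped with
count-integrality and degenerate-input checks. Taxon aggregation keeps,
at a chosen rank, taxa whose treatment-mean relative abundance exceeds a
display threshold (default 1%) in at least one treatment and pools the
rest into an explicit `other` bucket, conserving total abundance
exactly. The Spearman screen correlates every soil-process response
(SOC mineralization, litter-released C, priming effect, priming
efficiency) with every chemistry trait or taxon abundance across jars,
using midrank ties and the two-sided t-approximation p-value (a
permutation p is available for very small n). Raw p-values are reported
by default; Benjamini–Hochberg adjustment is provided and off by
default, and clearly labelled when on.

## Driver selection

Ordinary least squares with intercept over candidate predictor subsets,
arbitrated by the small-sample AICc

    AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n − k − 1)

with k counting the coefficients, the intercept *and* the residual
variance (conventions differ; this one is stated explicitly and used
consistently). Search is exhaustive for ≤12 candidates (the 8 chemistry
traits) and stepwise (forward/backward/bidirectional) beyond (the 14
taxa); exhaustive search doubles as the oracle for the stepwise
strategies in tests. Ties break deterministically to fewer predictors,
then lexicographic names. Subsets the design cannot identify (singular,
or n ≤ k) are skipped as ineligible rather than raising — with 7
distinct chemistry profiles, any subset of ≥7 traits is rank-deficient
across treatments. RSS = 0 maps to −∞ (a perfect fit wins);
n − k − 1 ≤ 0 maps to +∞.

The driver-recovery study selects on the **7 treatment means**, not the
35 jars: chemistry varies only between treatments, so jar-level
selection pseudo-replicates the predictors and lets AICc interpolate
the profiles with overparameterized subsets; at n = 7 the small-sample
correction makes those subsets ineligible. The pipeline's driver stage,
by contrast, reports jar-level models — the unit a reader of
per-sample regression tables expects — and always reports n alongside,
so the two conventions cannot be confused.

Known property, demonstrated in the tests: AIC-family criteria keep a
roughly constant per-candidate overfit probability (~15%), so on pure
noise the intercept-only model is the modal but not near-certain
selection. This is inherent to AICc, not a defect of the search.

## Numerical choices and degenerate inputs

* Mass balance `SOC_final + C_litter = TOC_final` holds to 1e-9
  relative tolerance by construction and is property-tested against an
  independent 2×2 linear-system solve.
* Partitioning is invariant to adding a constant to all three δ values
  (only differences enter), also property-tested.
* Trait-ratio printing uses round-half-away-from-zero to integer
  percent; unrounded values are retained internally. One published
  soluble-sugar ratio (Ah/Ps) computes to 67.7% against its printed 67;
  the package reports the unrounded value rather than matching the
  print.
* "mean ± SE" chemistry cells are accepted both as two-column
  (value, se) and as `v ± s` text.
* Control jars bypass the mixing model entirely (litter pool is zero by
  definition), so the degenerate equal-end-member check does not apply
  to them.

## Problem sizes used in verification

The oracle-equivalence check uses 10,000 random valid inputs; the
round trip uses the full 40-jar design; the recovery study uses 100
simulated experiments (each 40 jars, exhaustive AICc over 8 traits);
the bias study uses 1,000 simulated jars. These sizes give Monte-Carlo
errors comfortably below the effects being checked.

## Limitations

* End-point partitioning only: no CO₂ flux time series, no ¹³CO₂
  Keeling analysis, no microbial-biomass or temperature modelling.
* The community generator is a statistical stand-in for sequencing
  (log-linear trait responses + Dirichlet-multinomial sampling), not an
  ecological model; it supports verifying the statistics downstream of
  an abundance table, nothing upstream of it.
* Single-exponential litter decay with linear trait modifiers on the
  rate; no multi-pool lignocellulose kinetics.
* Driver regressions are associative; no mediation or structural
  equation analysis.
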