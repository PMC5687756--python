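# Methods

This note documents the statistical models, the synthetic-data generators,
the numerical choices and the limitations of `oystervid`.

## The survey and its observation model

A towed-video survey is hierarchical: *sites* contain *transects* (20 m
strips, 0.8 m wide in the reference layout), each transect is divided into
*b* contiguous *sections* (4 m × 0.8 m = 3.2 m², the observation unit),
each section's footage is scored independently by *c* observers, and each
observer scores it *n* times. Counts are kept in three scoring categories —
"probably living", "possibly living" and "dead" — and the two living
categories are merged for analysis (`merge_categories`), reflecting that the
cautious category alone recovers only a fraction of the living animals.

The reference layout is 3 sites with (5, 3, 5) transects, b = 5, c = 2,
n = 2: 65 sections and 260 readings.

## Classification agreement

For individually matched oysters, field status (truth) versus video status
is cross-tabulated with *living* as the positive class. Reported statistics:
correct classification rate (p_o), sensitivity n_ll/(n_ll+n_ld), specificity
n_dd/(n_dl+n_dd), and Cohen's kappa (p_o − p_e)/(1 − p_e) with p_e the
product-of-marginals chance agreement. Statistics whose marginal is empty
are reported as undefined individually, so a degenerate matrix still yields
the defined subset. Display rounds shares to whole percents; stored values
keep full precision. No kappa confidence interval is provided.

## The mixed linear model

Reading-level counts are modelled as

y_ijklm = μ + Si_i + Tr_j(i) + Se_k(ij) + Ob_l + (SiOb)_il + (TrOb)_jl(i) +
(SeOb)_kl(ij) + e_m(ijkl)

with Site fixed (sites are chosen deliberately where oysters occur) and all
other terms independent zero-mean Gaussians. The residual is the
within-observer repeat-reading variability. The model is Gaussian on counts;
this is an approximation for count data, adopted because it is the model
under which variance components are interpretable and additive on the count
scale (see *Limitations*).

### ANOVA

Sums of squares are computed from cell and marginal means with cell-size
weights. Layouts may be unbalanced **only** in transects per site; because
everything below the transect level is balanced, cell frequencies are
proportional and the decomposition remains orthogonal (asserted to 1e-8 in
tests). Degrees of freedom follow the standard nested rules; for the
reference layout they are (Ob 1, Si 2, Tr(Si) 10, Se(Tr,Si) 52, Ob×Si 2,
Tr(Si)×Ob 10, Se(Tr,Si)×Ob 52, Residual 130).

### Expected mean squares and F-tests

EMS coefficients come from the Cornfield–Tukey table algorithm over the
term lattice. Two conventions are implemented:

- **restricted** (default for F-tests): interactions involving the fixed
  Site factor sum to zero over sites and drop out of the random main
  effect's EMS — the convention of the classical mixed-model ANOVA
  literature. Under it, Observer is tested over Tr(Si)×Ob.
- **unrestricted**: all random terms are iid — the convention of
  REML software (and of this package's own REML model). Under it,
  Observer is tested over Ob×Si.

Each term's denominator is found by solving for the linear combination of
other mean squares whose EMS equals the numerator EMS minus the tested
component. Single mean squares result where possible; Site and Tr(Si) need
quasi-F denominators (e.g. MS_Tr + MS_ObSi − MS_TrOb for Site), with
Satterthwaite degrees of freedom. A negative quasi-F denominator is
reported as untestable rather than forced.

For layouts unbalanced in transects per site the EMS coefficients that
involve the transect count use the **arithmetic mean** count and the table
is flagged approximate. (The arithmetic mean makes main-effect
coefficients exact under proportional cell frequencies — e.g. the Observer
coefficient is exactly N/c — whereas a harmonic-mean rule would not; only
interaction-row coefficients remain approximate.) REML is the authoritative
estimator in the unbalanced case.

### Variance-component estimation

**Method of moments** inverts the triangular EMS system MS = A·σ² over the
seven random sources. Negative solutions are truncated to zero in the
returned components but the raw values are preserved — they are unbiased
and are what the balanced-design REML equivalence refers to.

**REML** maximises the restricted likelihood of the unrestricted Gaussian
model. The residual variance is profiled out analytically; the six variance
ratios γ_r = σ²_r/σ²_e are optimised by L-BFGS-B with analytic gradients
(∂/∂γ_r of −2ℓ_R is tr(P·G_r) − (N−p)·y'PG_rPy / y'Py) under bounds
γ_r ≥ 0, so boundary estimates are exactly zero. Optimisation starts from
the truncated MoM solution (falling back to ones), with optimizer
tolerances ftol 1e-14 / gtol 1e-9; convergence is accepted when the
optimizer reports success or the projected gradient norm is below 1e-4,
and a hard failure raises a diagnostic error carrying the optimizer state.
Covariance matrices are built densely (N × N); with the reference layout's
N = 260 a fit takes ~0.3 s, and the dense route handles the crossed
Observer factor and transect imbalance exactly. A constant response is
detected up front and returns all-zero components.

On balanced designs with all raw MoM estimates positive, REML coincides
with MoM under the unrestricted convention; the tests assert agreement to
1e-3 (observed agreement is ~1e-12 when started at MoM and ~1e-5 from a
neutral start).

Estimator bias: raw MoM is unbiased for every component. REML's
non-negativity constraint necessarily biases *small* components upward in
the mean at this design size — e.g. the transect component (10 df, with a
dominating section component) has a per-replicate sampling sd of ~3 around
a true value of ~1, so a substantial fraction of replicates would be
negative and are pushed to the boundary. Simulation at the reference design
shows mean REML recovery of the section and residual components within a
few percent, while the transect and observer components are overestimated
by tens of percent in the mean. This is a property of constrained
estimation, not of the implementation; users comparing small components
should look at the raw MoM values alongside REML.

## Error propagation and design planning

The variance of the mean count per section over a design (a, b, c, n) is

V[ȳ] = σ²_Tr/a + σ²_Se/(a·b) + σ²_Ob/c + σ²_e/(a·b·c·n).

The two observer-by-space interaction components are omitted by default;
`include_interactions=True` adds σ²_TrOb/(a·c) + σ²_SeOb/(a·b·c), the full
balanced-design variance. SE = √V; per-m² figures divide SE by the section
area (3.2 m²) at the reporting boundary only — all components are carried
in (counts per section)².

Consequences exploited by the planning tools:

- V is strictly decreasing in each knob whose component is positive; the
  observer term does not shrink with area, so √(σ²_Ob/c)/area is an
  asymptotic precision floor (`observer_floor`, checked by
  `required_area`).
- For a fixed number of sections m = a·b, the best split is a = m, b = 1
  (both spatial terms then scale as 1/m), so the best-split SE is monotone
  in total area and `required_area` can binary-search it. The min/max
  envelope over all factorizations (`se_vs_area`) shows how little the
  split matters when the section component dominates — with the reference
  components the envelope is narrow, i.e. precision is essentially a
  function of total area sampled.
- Site-to-site variance is **excluded**: predictions hold within a spatial
  unit comparable to one site. Extrapolating a mean across sites needs an
  additional between-site component that this model cannot supply.

With the reference components, the model predicts SE ≈ 1 oyster m⁻² when
~10 m² are sampled and SE ≈ 0.3 m⁻² at ~100 m² — i.e. a relative error of
30% at a mean density of 1 m⁻².

## Synthetic data

Two generator modes share one root seed (all draws descend from it through
fixed sub-streams, so a config + seed pins the dataset bitwise).

**gaussian-vc** draws readings from the mixed model exactly — the right
mode for validating the ANOVA/REML estimators (parameter recovery) and the
propagation formula (simulated survey-mean variance matches V[ȳ] within
Monte-Carlo error). Values are real-valued and can be negative when the
mean is small relative to the variances; recovery experiments therefore use
means large enough to keep that harmless.

**mechanistic** builds integer truth and an imperfect observation of it:

1. Per-section latent mean = grand mean + site offset + N(0, σ²_Tr) +
   N(0, σ²_Se), clipped at zero; the per-section count is the **rounded**
   latent mean by default. Rounding (rather than a Poisson draw with the
   latent mean as rate) keeps zero-variance configurations exactly
   constant and keeps the configured between-section variance equal to the
   realized one up to rounding noise; `count_model="poisson"` is available
   when overdispersed integer counts are wanted, at the cost of adding the
   mean to the between-section variance. The dead-oyster process is
   parameterized independently.
2. Every oyster is detected per (observer, reading) pass with a
   status-conditional probability (optionally reduced for oysters flagged
   as covered by algae/sediment); detected oysters are misclassified with
   configurable probabilities; video-living oysters split into
   "probably"/"possibly" categories. Matched oyster records take observer
   1, reading 1 — an individual is matchable once, not per reading.

The bundled preset (`reference_generator_config`,
`presets/reference_survey.yaml`) reproduces the validation study's
behavioural anchors: "probably living" alone recovers ~40% of living
oysters (0.8 detection × 0.5 split), merged living recovery sits in the
70–80% band, about half of dead oysters are found, and the
confusion-matrix off-diagonal rates are ~18%/20%.

What the mechanistic generator does **not** emulate: spatial
autocorrelation beyond the nested hierarchy, oyster clustering as a
detection mechanism (cluster membership is carried as a flag only),
size-dependent detectability, and the heavy right tail of real section
counts. One visible consequence: zero-clipping at a realistic mean (~4 per
section) plus imperfect detection shrinks the realized video-count
variance well below the configured latent σ²_Se, so a mixed-model fit to
preset data yields a smaller section component than the latent value —
passing recovery tests on gaussian-vc data says nothing about this
truncation distortion, which is why the two modes exist separately.

## Numerical and interface choices

- Degenerate inputs: empty confusion matrices, zero marginals, zero-variance
  responses, unmatched section keys and incomplete reading structures all
  raise typed errors naming the offending statistic/key/row; relative
  errors at field-zero sections are flagged undefined, not infinite.
- Section-level video means average over all c·n replicates by default
  (single-observer means are available via a flag).
- p-values display to 2 decimals, stored at full precision.
- Tables interchange as tidy CSV with fixed headers; statuses are the
  literal strings `living`/`dead`. Spreadsheet ingestion requires an
  explicit column mapping (no layout is assumed) and then passes through
  the same validators.
- Only layouts of the reference shape are supported (one fixed crossed
  factor, one random crossed factor, a two-level nested random chain,
  imbalance only in transects per site); this is a survey-analysis tool,
  not a general mixed-model engine.

## Problem sizes used in validation

The test-suite simulations use: 10,000 replicate surveys per design (three
designs) for the propagation check; 500 replicate reference-design datasets
for REML recovery; 1,000 null datasets for F-test calibration; section
counts of 10,000–20,000 for generator moment checks. The acceptance script
reports the same quantities at 4,000 / 120 / 8 replicates respectively.
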