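# Methods

## Model

The core model is the classical suicide-substrate scheme for a flavin
amine oxidase:

```
E + I ⇌ E·I → E·I* → E + P   (release, k_rel)
              E·I* → E–I     (covalent adduct, k_chem)
```

with mass-action kinetics in µM and minutes throughout (association
k_on in µM⁻¹min⁻¹, all other constants min⁻¹).  Tracked species:
free oxidized enzyme, the reversible complex E·I, the oxidized-product
complex E·I* (enzyme reduced, product still bound), the covalent adduct
(dead), free reduced enzyme (anaerobic mode only), free inactivator and
released product.  Two exact conservation laws (total enzyme, total
inactivator) hold along every trajectory and are asserted to 1e-8
relative in the tests.

Assumptions baked into the scheme:

- **Aerobic reoxidation is instantaneous.**  Air-saturated assays keep
  O₂ far from limiting, so enzyme released from E·I* re-enters the free
  oxidized pool immediately; O₂ and H₂O₂ are not modelled as species.
- **Anaerobic mode** sends released enzyme to an inert reduced pool and
  released product never rebinds: a pre-reduced enzyme neither oxidizes
  the propargylamine nor forms the adduct, so single-turnover spectral
  experiments see each site reduce exactly once.
- **Product release is irreversible.**  The released allenyl product is
  assumed not to rebind and resume adduct formation.
- **Substrate competition is algebraic.**  Assays are initial-rate and
  preincubations contain no substrate, so substrate protection enters
  only as the competitive factor (1 + S/K_M) in k_obs, never as an
  explicit E·S species.

Integration uses `scipy.integrate.solve_ivp` with LSODA (switches to BDF
on stiffness) at rtol 1e-10; integration failures raise an error naming
the rate constants.

## Derived parameters

Under rapid equilibrium (k_off ≫ k_ox) with the E·I* pool at quasi-steady
state, the scheme gives closed forms

```
Ki       = k_off / k_on
k_inact  = k_ox·k_chem / (k_ox + k_rel + k_chem)
K_I      = Ki·(k_rel + k_chem) / (k_ox + k_rel + k_chem)
r        = k_rel / k_chem
k_obs(I) = k_inact·I / (K_I·(1 + S/K_M) + I)
```

and the useful identity `k_inact/K_I = k_ox/((r+1)·Ki)`: the specificity
constant depends only on the oxidation rate, the partition ratio and the
reversible affinity.  Two regimes degrade the closed forms and are
handled explicitly:

- `k_off < 20·k_ox`: binding no longer pre-equilibrates; the derived
  parameters carry a `rapid_equilibrium=False` flag and a warning rather
  than an error.
- `(k_rel + k_chem) ≲ k_ox`: E·I* is no longer a fast intermediate and
  the true slow eigenvalue of the network deviates from k_obs (we
  measured >10% at `exit ≈ k_ox·f`).  The closed forms are still
  reported — they are the field's standard definitions — but property
  tests that assert 2% agreement with the ODE restrict themselves to
  exit-dominated rate sets, and the preset library places anchored
  compounds in that regime (below).

k_chem = 0 is a plain substrate: k_inact = 0 and the partition ratio is
reported as NaN ("not inactivating") rather than infinity.

## Estimators

- **IC50**: least squares of `v/v0 = top/(1 + I/IC50)` with bottom fixed
  at 0 and Hill slope fixed at 1 (the functional form of competitive
  inhibition); IC50 is initialized at the tested concentration nearest
  half the control response — deterministic and derivative-free.  Data
  that never cross 50% of control raise a range error naming the
  bracketing concentrations.
- **Global Ki**: one shared (Vmax, K_M, Ki) over the full substrate ×
  inhibitor grid, Levenberg–Marquardt via lmfit.  A control (I = 0)
  column is required; a Ki standard error exceeding the estimate
  triggers a poorly-determined warning instead of failure.
- **k_obs**: unweighted OLS on ln(activity) vs preincubation time
  (matching how plate data are reduced in practice); activities below 1%
  are excluded with a warning because their log-noise diverges, and
  fewer than 3 usable points is an error.
- **Kitz–Wilson**: lmfit fit of the rectangular hyperbola with
  half-saturation initialization; non-saturating designs (max I below
  the fitted K_I/5) warn about wide confidence intervals.
- **Partition ratio**: the titration endpoint is linear in the load
  ratio x = I₀/E₀, `activity% = 100·max(0, 1 − x/(r+1))`, because each
  consumed inactivator kills a site with probability exactly 1/(r+1);
  the estimator fits an OLS line through the points with 10–90% residual
  activity (window configurable — the toe and the saturation shoulder
  curve away from the asymptote) and returns the zero-activity intercept
  minus one, with a delta-method standard error.  Grids whose completed
  points never reach low activity are reported as censored (one-sided).
- **Exponential fits** (stopped-flow): variable-projection
  initialization — amplitudes and offset are solved linearly on a
  log-spaced grid of candidate rates, the best grid point seeds
  Levenberg–Marquardt.  This is deterministic, seed-free, and robust for
  traces that decay only a few percent inside the acquisition window.
  Flat traces return zero amplitude, NaN rate and a `"flat"` flag.
  Two-exponential fits report rates sorted descending.
- **Mechanism classification**: rates at 410 nm (adduct) and 495 nm
  (reduction) are called equal — concerted adduct formation or
  rate-limiting oxidation — when they agree within twice their combined
  standard error; otherwise sequential.  The 2-SE rule is a declared
  convention; without standard errors a 15% relative threshold is used
  with a warning.

## Preincubation–dilution protocol

For each (preincubation time, concentration) cell the preincubation is
simulated without substrate; on dilution, free concentrations scale and
the non-covalent complexes are counted as recoverable activity
(E_ox + E·I + E·I*), since excess substrate (5×K_M) re-equilibrates them
into turnover.  Reversible occupancy during the assay read itself is the
competitive factor at the diluted inhibitor concentration; the stored
activity divides this factor back out (the "reversible-binding
correction"), so the t = 0 column is ≈1 and each trace is normalized to
the inhibitor-free control — which also cancels any enzyme-instability
term if one were present.

Two small systematics are inherent to this protocol and visible in the
noiseless round trip: the E·I* pool starts empty (a positive intercept
offset of order k_obs/(k_ox·f + k_rel + k_chem) in the log-linear fit)
and rapid equilibrium is only 100-fold (k_off = 100·k_ox in the
presets).  Together they bias the recovered specificity constant about
1% low — well inside the 3% round-trip tolerance, and quoted here so the
number is not mistaken for estimator error.

## Long-incubation titrations

Each titration point is integrated in doubling windows until the
activity change over a whole window falls below 0.1% (the operational
"no further inactivation" criterion), with a 10-day default cap
mirroring the wet protocol; points that cannot finish are flagged
incomplete but retained.  Points whose estimated completion horizon
exceeds 10⁴ minutes use the analytic complete-consumption endpoint
instead of a multi-week stiff integration; the analytic line is
cross-validated against fully integrated endpoints (to 0.5% of full
scale) in the tests.  The grid design helper places 10 log-spaced load
ratios between 0.2·(r+1) and 2·(r+1).  Active-site titration runs the
same estimator with a low-r (< 5) inactivator and divides the intercept
by (r+1).

## Spectral model

Absorbance is a linear projection of the trajectory:
`A(λ,t) = Σ ε(λ, species)·c(t)/1000·path` with pooling oxidized =
E_ox + E·I (bound flavin still oxidized), reduced = E·I* + E_red,
adduct = E–I.  The default extinction coefficients (mM⁻¹cm⁻¹) are
**synthetic placeholders** chosen only to satisfy the qualitative
orderings of flavoprotein spectra — the adduct peaks at 410 nm, oxidized
flavin dominates 456/495 nm, reduction bleaches both — and are
config-overridable; measured coefficients should be substituted when
available.  Generated stopped-flow fixtures reproduce the two-phase
acquisition (1000 Hz for 0–0.5 s, 4 Hz for 0.5–1000 s); fits weight all
points equally.  The 456 nm channel is generated and stored but
classification uses the 410/495 pair.  The 600 nm charge-transfer band
seen with F2MPA is outside the model (no species absorbs there).

## Compound presets and the back-solve

Macroscopic anchors per compound/enzyme pair — the saturating anaerobic
reduction rate (= k_ox), the partition ratio, and either Ki or the
specificity constant (which fixes the other through the identity above)
— are back-solved to microscopic rates with a fixed convention that
makes presets unique and keeps the closed forms valid:

- `k_off = 100·k_ox`, but never below 60 min⁻¹ (1 s⁻¹): binding and
  dissociation are fast molecular events even for compounds oxidized
  slowly, and an artificially slow binding transient would leak into
  simulated stopped-flow traces;
- `k_on = k_off/Ki`;
- `k_chem` chosen per compound: much faster than k_ox where the 410 and
  495 nm rates are reported equal (clorgyline, pargyline — concerted
  behavior, and the deep quasi-steady state keeps the Kitz–Wilson round
  trip faithful), slower than k_ox for ASS234, whose reduction is
  reported to precede adduct formation (sequential).

Individual k_inact/K_I entries that exist only in published tables are
documented placeholders consistent with the anchored ratios and the
stated qualitative constraints (inactivation rates in the 0.1–1 min⁻¹
band for the classical compounds, clorgyline several-fold faster);
every numeric field of every preset carries a provenance note, and the
library self-check asserts the derived parameters match the closed forms
to 1%.  One anchored tension is resolved in favor of the scheme's
algebra: with selegiline/MAO-A's measured reduction rate (0.019 min⁻¹)
and partition ratio (360), k_inact cannot exceed k_ox/(r+1) ≈ 5×10⁻⁵
min⁻¹, so that preset's k_inact is set accordingly; its partition
titration — the quantity the preset anchors — is unaffected.

## Synthetic data and what it does not emulate

The generator reproduces the statistical structure the estimators
assume: multiplicative Gaussian noise on rates and activities (default
2%, typical plate precision) and additive Gaussian noise on absorbance
(default 0.002 AU, typical stopped-flow precision), with a single seeded
RNG per dataset so identical seed + configuration gives byte-identical
files.  It does **not** emulate enzyme instability over multi-day
incubations, inhibitor chemical decay, O₂ depletion, coupling-assay
(peroxidase/Ampliflu Red) artifacts, pipetting covariance across a
plate, or full-spectrum wavelength continua.  Passing round trips
therefore demonstrate estimator correctness under the model's own
assumptions, not robustness to every wet-lab systematic.

## Problem sizes

Default protocol sizes are those of the emulated assays: 6 substrate × 5
inhibitor points for the global Ki grid, 6 inhibitor concentrations × 8
preincubation times for Kitz–Wilson, 10 load ratios per titration, ~4000
points per stopped-flow trace, and 50 replicates for the Monte-Carlo
bias checks — enough for the noiseless recoveries to sit well inside
their tolerances while the whole suite runs in well under a minute.

## Known limitations

- The Kitz–Wilson closed forms are definitions, not eigenvalues: away
  from the exit-dominated regime they can differ from the observed decay
  rate by far more than fitting error (see above).
- The partition estimator assumes complete consumption; compounds whose
  completion horizon exceeds the incubation cap are flagged, not
  extrapolated.
- Preset k_chem values (and spectral extinction coefficients) are
  placeholders constrained only by qualitative behavior; quantities that
  depend on them beyond the anchored ratios should not be over-read.
- Double-exponential fitting uses a coarse 2-D grid seed; strongly
  overlapping rates (ratio < ~3) may resolve poorly, as with any
  unweighted biexponential fit.
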