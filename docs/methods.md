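# Methods

This note documents the models behind `specphyto`, the choices made where
the design was genuinely open, and what the synthetic campaigns do and do
not demonstrate.

## Underwater light climate

A vertical PAR profile is summarised by the diffuse attenuation coefficient
Kd(PAR) (m⁻¹), fitted as the negative least-squares slope of ln(PAR) on
depth.  With exactly two depths this reduces to the two-point form
Kd = [ln(I₀) − ln(I_z)]/Z.  The euphotic depth is the 1 % light level,
Zeu = 4.6/Kd.  Vertically averaged irradiance in the mixed layer is
Eavg = I₀(1 − e^(−Kd·Zumixl))/(Kd·Zumixl), computed with `expm1` so the
optically thin limit Eavg → I₀ is exact.

A column counts as stratified when the bottom density exceeds the 0–1.5 m
surface-layer mean by strictly more than 0.086 kg m⁻³; the boundary value
counts as mixed.  For mixed columns the mixed-layer depth Zumixl is the
bottom depth.  For stratified columns the criterion locates only the fact of
stratification, not a depth, so the package uses a stated convention: Zumixl
is the shallowest depth at which the density excess over the surface mean
first exceeds the threshold.

Spectral quality is summarised by quantum band integrals (trapezoid rule on
the instrument grid) over blue 410–490 nm, green 480–580 nm and red
600–700 nm — the blue and green bands overlap deliberately — giving the
ratios R/B, G/B and G/R, averaged over replicate casts per depth and then
over depths down to 2.5 m.  The integrals are exact band widths only when
the spectral grid contains the band edges; on the 3 nm instrument grid the
nearest grid points are used as-is.

## Fluorescence-derived parameters

All fluorescence quantities are in relative units with the dark maximal
fluorescence Fm ≈ 1 (the instrument gain is adjusted to this working
point).  Per rapid-light-curve step:

    Y(II) = (Fm′ − F)/Fm′           effective PSII quantum yield
    Fv/Fm = (Fm − F0)/Fm            dark-acclimated maximum yield (step 0)
    r.ETR = Y(II) · PAR · 0.5       µmol electrons m⁻² s⁻¹
    NPQ   = Fm/Fm′ − 1              Stern–Volmer quenching

The functional absorption cross section of PSII is estimated from the O–I₁
fluorescence rise during a 1 ms actinic pulse.  The rise is modelled as a
single saturating exponential F(t) = F₀ + (F_I1 − F₀)(1 − e^(−t/τ)),
the standard reading of single-hit Q_A-reduction kinetics; τ is the fitted
time constant, averaged over three consecutive repeats, and per-sample τ is
the mean over six subsamples (the subsample variance is retained for QC but
does not propagate).  Then

    Sigma(II) = 1/(τ · L · PAR)     L = 6.02214076×10²³ mol⁻¹,

with PAR converted to mol quanta m⁻² s⁻¹ and the result reported in nm²
(unit constants are centralised in `constants.py`).  Absolute rates follow:
PAR(II) = Sigma(II)·L·PAR (quanta PSII⁻¹ s⁻¹) and
ETR(II) = PAR(II)·Y(II)/(Fv/Fm).

### Photosynthesis–irradiance fitting

The PE model is the Eilers–Peeters rational function
P(E) = E/(aE² + bE + c), with derived parameters α = 1/c,
ETRmax = 1/(b + 2√(ac)), Eop = √(c/a) and Ek = ETRmax/α.  The three
replicate curves are pooled as points into one fit per unit system
(r.ETR vs PAR; ETR(II) vs PAR(II)).

The fit minimises residual sum of squares by bounded trust-region least
squares from a data-driven start (initial slope, observed maximum, position
of the maximum) plus seeded perturbed restarts, in the parameterisation
(log c, log b, log Eop) with a = c/Eop².  This keeps all coefficients
positive and lets Eop be box-bounded at ten times the largest observed
irradiance: when a curve does not turn over inside the measured range, Eop
is not identifiable and would otherwise diverge, which is also why Eop
estimates from noisy absolute-unit curves remain highly scattered.
Acceptance of a fit is defined purely by residual SS, not by the optimiser
trajectory.

### NPQ light response

Two candidate models are fitted to NPQ vs PAR: Michaelis–Menten
NPQ(E) = NPQmax·E/(Khalf + E) and a linear regression forced through the
origin.  The qualitative published criterion ("use the linear model when
the kinetics differ from Michaelis–Menten") is made operational as a
corrected-AIC (AICc) comparison, with the MM candidate disqualified when
its fit fails or returns non-positive parameters.  NPQ₃₀₀ and NPQ₁₂₀₀ are
the selected model evaluated at 300 and 1 200 µmol quanta m⁻² s⁻¹.  If all
NPQ ≤ 0 an identically-zero model is returned with a warning.

## Stage 1 — population trends (LMEM)

Each of the eight K-table parameters (ETRmax(II), Ek, α(II), Eop(II),
Sigma(II), Fv/Fm, NPQ₃₀₀, NPQ₁₂₀₀) is modelled independently as

    value ~ 1 + wl_t + (1 + wl_t | station),    wl_t = wavelength − 440 nm,

so the intercept is the population value at 440 nm.  Fixed effects and
their standard errors come from the REML fit; fixed-effect p-values are
two-sided t-tests with residual-based degrees of freedom (N − stations − 2).
Likelihood-ratio tests for the random terms compare ML fits of nested
models: full vs random-intercept-only (χ², df = 2: slope variance +
covariance) and random-intercept vs OLS (df = 1).  The plain χ² reference is
conservative for variance components on the boundary; p-values near a
threshold should be read accordingly.

Numerical choices worth knowing:

* Internally the fits run on wl_t/185 (span 0–1).  In per-nm units the
  random-slope variance is ~10⁻⁸ × the intercept variance, which defeats
  the likelihood optimisers; coefficients are converted back to per-nm on
  report.  With the rescaling, simulated 95 % Wald intervals for both fixed
  effects cover the truth at the nominal rate.
* A sequence of optimisers (lbfgs → powell → bfgs → nm → cg) is tried
  because the observed information is singular when a variance component
  estimates to exactly zero.
* A singular random-effect covariance (correlation pinned at ±1 or
  non-convergence) triggers a refit with independent intercept and slope
  components; the fit is flagged `singular`.
* Exactly degenerate inputs (zero residual around the OLS line) are
  reported from OLS with all random terms at zero: the profiled mixed-model
  likelihood is undefined at zero residual variance.

Detrending subtracts only the fixed-effect population line — not the
station-level predictions — so the detrended values retain each station's
full departure (random effects plus residual), which is what the
multivariate stages analyse.

## Stage 2 — partial triadic analysis

The detrended tables (one per wavelength; stations × the eight parameters)
are standardised globally: each column's mean and scale are computed over
the stacked rows of all tables.  "Scale" defaults to the standard deviation
(population convention, ddof = 0); a `range` (max − min) option is provided.
Stations missing any wavelength × parameter cell are dropped (logged).

* Interstructure: RV coefficients
  RV(X_k, X_l) = tr(W_k W_l)/√(tr W_k² · tr W_l²) with W = XXᵀ;
  eigendecomposition of the RV matrix; the table weights are the first
  eigenvector oriented positive (unit norm, so the squared weights sum
  to 1); cos²_k is the share of table k's squared coordinate carried by
  axis 1.
* Compromise: the convex combination Σ_k (w_k/Σw)·X_k; its SVD gives axis
  inertias (singular values squared), variable coordinates V·diag(s) and
  row coordinates U·diag(s).  Axis signs are fixed by making each axis's
  largest-magnitude variable loading positive; per-cent inertias are
  invariant to rescaling the weights.
* Intrastructure: each table's rows project as X_k·V and its variables as
  X_kᵀ·U.  The weight-averaged per-table projections reproduce the
  compromise coordinates exactly (a linear identity, asserted in tests).
  Per-station "polygons" collect the K wavelength positions of a station;
  their shoelace areas measure how wavelength-dependent a station is.

All outputs are checked against an independent brute-force implementation
that follows these definitions with explicit loops; the cos² convention is
declared here rather than inherited from any reference software.

## Stage 3 — ordination

PCA is the eigendecomposition of the correlation (default) or covariance
matrix, axes signed like the compromise axes.  Missing explanatory values
are completed beforehand by single-imputation EM under a multivariate
normal model (column-mean initialisation, conditional-mean updates to
convergence at 10⁻¹⁰); the procedure is deterministic for given data.

RDA centres and scales both matrices, takes fitted values Ŷ = X(XᵀX)⁻¹XᵀY,
and defines R² = ‖Ŷ‖²/‖Y‖² with the Ezekiel adjustment
adjR² = 1 − (1 − R²)(n − 1)/(n − m − 1).  Constrained plus residual
variance equals the total by construction.

Forward selection adds, at each step, the candidate with the largest gain
in adjusted R², with three stopping rules:

1. a global pre-test — selection starts only if the all-candidates model is
   significant under free row permutation of the response (this is what
   keeps the selection-wide type-I error near α; measured 3.6 % at
   α = 0.05 on null data, versus 9 % without it);
2. the marginal permutation test of the entering candidate, permuting rows
   of the response residualised on the already-selected variables,
   p = (1 + #{perm ≥ obs})/(1 + nperm), nperm = 199 by default (so the
   smallest attainable p is 0.005);
3. the adjusted-R² ceiling — the cumulative adjusted R² may not exceed the
   all-candidates model's.

When the candidate pool is rank-deficient or larger than n − 2, the global
model is a greedy full-rank subset capped at n − 2 predictors.  Ties in
gain are broken by candidate column order.  Abiotic and biotic pools are
selected separately by default (a combined-pool flag exists); the per-pool
global adjusted R² and permutation p are reported alongside the selection
path.  The global pre-test is conservative: with one genuinely active
variable diluted by many inert candidates and a modest effect size, the
marginal test may be significant while the gate blocks selection.  The
synthetic campaigns sit near this regime, so their per-wavelength
selections are often empty even though the single-variable euphotic-depth
association is detectable.

## Synthetic campaigns

The generator draws, per station × wavelength, the true parameter roster
from linear wavelength trends (intercept at 440 nm, slope per nm) plus
Gaussian per-station intercept/slope departures, then projects into the
jointly feasible region (2α ≤ Fv/Fm so yields never exceed Fv/Fm;
Ek ≤ 0.45·Eop so the EP coefficient b stays positive).  Defaults are the
field-campaign scale: Fv/Fm 0.61 − 0.00012/nm, Sigma(II) 6.08 − 0.0241/nm
(≈6 → 1.6 nm² across 440–625 nm), r.α 0.21 + 0.00029/nm,
r.Ek 200.94 + 1.39/nm, r.Eop ≈ 2000, and an NPQ response driven by a
Michaelis–Menten curve with Khalf = 751.8 µmol quanta m⁻² s⁻¹ and
NPQmax 3.155 − 0.01402/nm, which reproduces the blue-light pair
NPQ₃₀₀ = 0.90, NPQ₁₂₀₀ = 1.94.  A single Michaelis–Menten response cannot
produce NPQ₁₂₀₀/NPQ₃₀₀ > 4, so at the red end the generated NPQ pair is
the MM evaluation rather than an extrapolated table value.

From the truth, the measured streams are constructed exactly through the
forward model (RLC steps via Fm′ = Fm/(1+NPQ), Y from the EP curve;
induction rises from τ; exponential PAR and band-structured spectral
profiles; two-layer density profiles) with additive Gaussian fluorescence
noise truncated at zero (default sd 0.003 in Fm ≈ 1 units — the measuring
protocol tunes gain for signal-to-noise, and at saturating light the yield
itself is only ~0.05) and multiplicative lognormal light noise (sd 0.03).
τ is tied to Sigma(II) through the induction actinic intensity
(1 000 µmol quanta m⁻² s⁻¹), giving τ ≈ 0.27–1.0 ms, inside the plausible
(10 µs, 5 ms) window.  The 14-step actinic ladder spans 0–2 000
µmol quanta m⁻² s⁻¹ (dark step first); per-wavelength instrument PAR lists
are not published, so the ladder is a tunable default.

Station Ek departures are coupled to euphotic depth (two intercept-SDs per
SD of Zeu), so clearer water pushes a station's light-saturation parameter
above the population line.  The strength was chosen once so that a
single-predictor RDA of the eight-parameter table on Zeu has adjusted
R² ≈ 0.15–0.2, the scale reported for field abiotic models of this kind.

What the generator does **not** emulate: taxonomic composition effects
(biomasses are plain lognormal draws uncorrelated with photophysiology),
nutrient or temperature dependence, vertical mixing dynamics, spectrally
realistic water-type absorption (the spectrum is a smooth band-level
interpolation), package-effect or photoinhibition mechanisms, and any
dependence between NPQ and the light field.  Passing tests on synthetic
campaigns therefore demonstrate that the *computational chain* recovers
known truth under realistic noise — not that the chain would reach the same
ecological conclusions on real water masses.

## Problem sizes used in the test suite

The suite favours exact tiny-problem oracles (3×2 K-tables against the
brute-force PTA; closed-form PE and NPQ curves) plus moderate simulation
studies chosen for statistical resolution: 200 replicates for the PE noise
study and the mixed-model coverage check (binomial SE ≈ 1.5 % at 95 %
coverage), 500 replicates for the null selection rate (SE ≈ 1 %), and
5–19-station campaigns for round trips.  The end-to-end zero-noise round
trip tolerates 10⁻⁶ relative error; the binding term is the τ fit
(~3×10⁻⁸ relative).

## Known limitations

* Eop (both unit systems) is weakly identified whenever curves saturate
  without turning over; its estimates are scattered by construction and are
  best treated qualitatively, as the source study also concluded.
* LRT p-values for variance components use the plain χ² reference and are
  conservative near the boundary.
* The EM imputer assumes joint normality and reports no imputation
  uncertainty (single imputation).
* The raw-table reader sniffs delimiter and decimal comma from the header
  and first rows; exotic instrument dialects may need explicit
  pre-formatting.
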