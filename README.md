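# specphyto

Wavelength-dependent photophysiology of natural phytoplankton, from raw
multi-color PAM fluorescence to statistically analysed photosynthetic
parameters.

Multi-color pulse-amplitude-modulation (PAM) fluorometry measures, at
several actinic wavelengths (440, 480, 540, 590, 625 nm), the variable
chlorophyll-*a* fluorescence of a water sample: rapid light curves (RLCs)
of F and Fm′ over a 14-step irradiance ladder, and the fast O–I₁
fluorescence rise during a ~1 ms pulse.  From these, ecologists derive how
light harvesting and photoprotection depend on light colour — which is what
decides how well a community photosynthesises in the blue-green light of
coastal seas.  `specphyto` implements the full computational chain for such
a campaign:

1. **Light climate** — diffuse attenuation Kd(PAR) from vertical PAR
   profiles, euphotic depth Zeu = 4.6/Kd, mixed-layer depth and
   stratification from density profiles (0.086 kg m⁻³ criterion),
   vertically averaged irradiance Eavg, and spectral quality ratios R/B,
   G/B, G/R from hyperspectral profiles.
2. **Photophysiology** — per step: Y(II) = (Fm′−F)/Fm′,
   r.ETR = Y(II)·PAR·0.5, NPQ = Fm/Fm′−1; the PSII functional absorption
   cross section Sigma(II) = 1/(τ·L·PAR) from the O–I₁ time constant τ;
   absolute rates PAR(II) = Sigma(II)·L·PAR and
   ETR(II) = PAR(II)·Y(II)/(Fv/Fm).  PE curves are fitted with the
   Eilers–Peeters model P(E) = E/(aE²+bE+c) (α = 1/c,
   ETRmax = 1/(b+2√(ac)), Eop = √(c/a), Ek = ETRmax/α); NPQ light responses
   with a Michaelis–Menten/linear-through-origin model pair selected by
   AICc, evaluated at 300 and 1 200 µmol quanta m⁻² s⁻¹.
3. **Statistics** — per parameter, a linear mixed-effects model
   `value ~ wl_t + (wl_t | station)` (wl_t = wavelength − 440 nm) separates
   the population wavelength trend from station departures; detrended
   values feed a partial triadic analysis (RV-coefficient interstructure,
   weighted compromise, per-wavelength intrastructure) and a redundancy
   analysis with adjusted-R²/permutation forward selection of abiotic and
   biotic explanatory variables (199 permutations), plus photoacclimation
   indices such as Ek,440/Eavg and Ek(625/440) against the matching light
   ratios.

A synthetic-campaign generator (`specphyto.synth`) produces all four raw
data streams with known ground truth, so every stage is testable end to
end; with noise at zero the pipeline recovers the truth to ≤10⁻⁶ relative.

## Worked example

```python
import specphyto as sp

cfg = sp.PipelineConfig(seed=1, n_stations=19)   # fully synthetic campaign
res = sp.run_pipeline(cfg)

print(res.trend_table[["parameter", "beta0", "beta1"]])
print("interstructure axes 1+2: %.2f%%" % res.pta_result.inter_pct_inertia[:2].sum())
print("table weights:", res.pta_result.weights.round(3))
```

prints (abridged) the per-parameter population trends — intercept at 440 nm
and slope per nm —

```
parameter       beta0      beta1
sigma_nm2     6.07548   -0.02410
     fvfm     0.60964   -0.00012
   npq300     0.89340   -0.00400
  npq1200     1.92454   -0.00862
       ek   890.16605   -2.07968
```

i.e. the dark-acclimated quantum yield sits near 0.61 and barely changes
with wavelength, the PSII cross section falls from ~6 nm² in bright blue
towards ~1.6 nm² in light red (cells harvest blue light far better), and
non-photochemical quenching weakens toward the red — while the absolute
light-saturation parameter Ek(II) declines; and

```
interstructure axes 1+2: 83.69%
table weights: [0.357 0.436 0.46  0.501 0.468]
```

the five wavelength tables contribute nearly equally to the PTA compromise
(weights whose squares sum to 1) and the interstructure is essentially
two-dimensional.  `res.rda_results` holds the per-wavelength forward
selections (abiotic and biotic pools separately, with per-pool global
adjusted R² and permutation p), and `res.indices`/`res.regressions` the
spectral photoacclimation indices and their regressions.

The same run is available from the shell, stage by stage or end to end:

```
specphyto run --seed 1 --out runs/demo
specphyto simulate --seed 1 --out runs/raw
```

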