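# pulsetrack

Do carnivores actively *search* for ungulate neonates during the birth
pulse, or do they meet them incidentally? `pulsetrack` is a Python package
for movement ecologists working with dual-species GPS telemetry (collared
carnivores and collared adult female elk / mule deer) who want to answer
that question with an auditable, fully testable inference chain:

1. **Parturition detection** — the rolling minimum-convex-polygon method:
   a birth is declared at the first time the 24-h MCP area of a female's
   fixes stays ≤ 30 ha (elk; ≤ 15 ha deer) for ≥ 120 h.
2. **Step-selection functions (SSF)** — each observed predator step is
   matched with K = 20 random steps drawn from fitted Gamma (step length)
   and von Mises (turning angle) kernels, and a conditional logistic
   regression estimates

   `w(x) ~ exp(β₁·enc + β₂·canopy + β₃·veg + β₄·ruggedness +
   β₅·ln dist road + β₆·ln dist water + β₇·ln step length + β₈·cos turn)`

   where `enc` indicates the endpoint lies within 200 m of a
   contemporaneous fix of a female within 30 days post-partum. β₁ > 0 is
   evidence of active search beyond habitat preference.
3. **Parturition-habitat RSF** — logistic regression of 7-day post-partum
   elk fixes against 10× uniform availability over the elk range, projected
   as a per-30-m-cell selection surface w(x) = exp(β'x).
4. **Phenology tracking** — weekly mean RSF scores at carnivore fixes
   (15 Apr–31 Jul) in a random-intercept mixed model; a likelihood-ratio
   test of quadratic vs linear Julian-week effects asks whether use of
   parturition habitat peaks with the birth pulse.

A first-class synthetic-telemetry module (`pulsetrack.synth`) generates
landscapes, birth-pulse prey, and predators whose steps follow a known
exponential selection rule, so every stage is validated against generative
ground truth. See `docs/methods.md` for models, conventions and the
simulator's scope.

## Worked example

```python
from pulsetrack import scenarios

out = scenarios.run_pipeline(11, n_prey=10, n_predators=8,
                             beta_enc=0.9, duration_d=75.0)

print(out["detection_score"])
fit = out["ssf_fit"]
print(fit.coef("enc"), fit.se_of("enc"), fit.p_of("enc"), fit.n_strata)
print(out["phenology_lrt"].p)
```

prints (seed 11):

```
{'sensitivity': 1.0, 'n_true': 10, 'n_detected': 10,
 'false_positives': 0, 'mean_abs_offset_h': 20.1}
0.880  0.076  9.2e-31  4792
0.0098
```

Ten of ten simulated births are recovered by the rolling-MCP detector with
a mean timing error of ~20 h. Feeding those *detected* (not true) events
into the SSF, the encounter coefficient comes back 0.88 ± 0.08 against a
generative value of 0.90 — the predators' preference for ending steps near
parturient females is cleanly separated from their landscape preferences.
The phenology LRT (p ≈ 0.01) detects that these searching predators used
parturition habitat most around the birth pulse.

Each stage is also a standalone function (`parturition.detect_all`,
`ssf.build_strata` + `ssf.fit_conditional_logistic`, `rsf.fit_rsf` +
`rsf.predict_surface`, `phenology.weekly_use` + `phenology.lrt`) operating
on fix tables (CSV: `animal_id,species,sex,timestamp_iso8601,x,y`) and
raster stacks (ESRI ASCII grids + JSON sidecar), and a thin CLI wraps the
chain for shell use:

```bash
pulsetrack simulate --config sim.yaml --out-dir data/
pulsetrack detect --fixes data/prey_fixes.csv --out events.csv
pulsetrack ssf --predator-fixes data/predator_fixes.csv \
    --prey-fixes data/prey_fixes.csv --events events.csv \
    --rasters data/rasters --seed 1 --out ssf.json
pulsetrack rsf --prey-fixes data/prey_fixes.csv --events events.csv \
    --rasters data/rasters --out rsf.json --surface surface/
pulsetrack phenology --predator-fixes data/predator_fixes.csv \
    --surface surface/ --out phenology.json
```

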