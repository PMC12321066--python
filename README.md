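# cmrselect

Detecting phenotypic viability selection in **open populations with imperfect
detection**, while accounting for **intraindividual trait variation**.

Capture-mark-recapture (CMR) studies of selection usually assume each
individual's morphology is fixed and measure it once. When traits are instead
measured at *every* capture, the analyst must choose which measurement
instance — the first, the last, or the median of all of them — enters the
survival model, and that choice can change the conclusion whenever a trait
varies substantially within individuals. `cmrselect` implements the full
workflow for this problem:

1. **Cormack–Jolly–Seber (CJS) survival models.** Conditioning on first
   capture, with detection probability *p* constant over time and individuals
   and apparent survival constant over time but logit-linear in one
   per-individual covariate, `logit(φᵢ) = β₀ + β₁xᵢ`. A history first caught
   at occasion *f* and last seen at *l* contributes
   `Σ_{t=f+1..l} [log φᵢ + hₜ log p + (1−hₜ) log(1−p)] + log χ_l`, where
   `χ_T = 1`, `χ_t = (1−φ) + φ(1−p)χ_{t+1}` is the probability of never being
   seen after *t*. Fitting is by maximum likelihood with analytic gradients;
   SEs come from the observed information.
2. **AIC model scan.** For every trait × instance selector (first / median /
   last), the univariate trait model is compared by ΔAIC against an
   intercept-only null refit on exactly the same individuals.
3. **Variance partition.** One-way ANOVA of each trait on individual
   identity (individuals with ≥ 2 measurements) gives F = MS_among/MS_within,
   R² = SS_among/SS_total, and the intraclass correlation (repeatability).
4. **Contingency verdict.** F/R² (is among-individual variation dominant?)
   crossed with the ΔAIC triplet (do all three selectors favor the trait
   model?) places each trait in one of four cells: *under selection*,
   *not under selection*, *obscured by intraindividual variation*, or
   *possibly spurious*.

Because suitable field data are rarely public, the package ships a seeded
**open-population simulator** (births, deaths, imperfect detection, traits
split into a stable latent component plus within-individual noise, optional
selection on the latent or realized value) with presets mirroring two desert
lizard species at a dune ecotone, and the whole pipeline is exercised
end-to-end on it.

## Worked example

`example.yaml`:

```yaml
seed: 7
simulate:
  preset: cowlesi            # phi = 0.45, p = 0.55, 5 occasions
  selection: {dorsal_a: 1.0} # viability selection on one color trait
  n_initial: 250
  recruits_per_occasion: 40
```

```bash
cmrselect run-all --config example.yaml --out out/
```

prints

```
cmrselect 0.1.0 | config b85184697f84 | seed 7

species: cowlesi_like
  [Evidence trait is currently under selection]
    dorsal_a (positive)
  [Evidence trait is not currently under selection]
    dorsal_L (none)
  [High intraindividual variation obscures or inhibits inference of selection]
    pelvic_width (mixed)
  [High intraindividual variation: possibly spurious evidence of selection]
    (none)
```

Reading the outputs: `dorsal_a` was simulated with selection gradient 1.0 per
latent SD and low measurement noise — the scan finds ΔAIC ≈ −44 for all three
selectors with β̂₁ ≈ 1.03 ± 0.18, and its variance partition (F ≈ 9.5,
R² ≈ 0.87) puts it in the low-intraindividual-variation column: *under
selection, positive*. `dorsal_L` has no selection and low noise → all ΔAIC
positive: *not under selection*. `pelvic_width` has within-individual noise
exceeding its among-individual spread (F ≈ 1.7 < 4): whatever the scan says
about it is unreliable, so it lands in the *obscured* cell. Full numbers are
in `out/model_scan.csv`, `out/variance_partition.csv`, `out/verdicts.csv`.

The same pipeline runs on real data via an `input:` section (CSV with
`individual_id`, `species`, `occasion`, plus trait columns; see
`cmrselect.pipeline.run` for `adjust_svl` / `condition` options that
residualize anatomical traits on snout-vent length).

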