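# ednadetect

Bayesian detection-probability analysis and survey design for
environmental-DNA (eDNA) monitoring data.

Species can be detected in water bodies from the trace DNA they shed, but a
single 1-L water sample often misses a species that is present, and field
or laboratory contamination can produce positives where it is absent.
`ednadetect` is for ecologists and invasive-species managers who need to
turn binary eDNA detection/non-detection records into statements about
*detectability*: how the per-sample detection probability depends on fish
density, water temperature and sampling depth, how likely false positives
are, and how many litres of water a survey must filter to reach a target
certainty of detection.

The package bundles (reconstructed at sample level from its published
per-cell counts) the dataset of a controlled mesocosm experiment: four
earthen ponds stocked with African jewelfish (*Hemichromis letourneuxi*) at
0, 0.32, 1.75 and 5.24 fish/m³, each sampled with 27 one-litre grabs
(9 transects × 3 water-column positions) on days 1, 5 and 10 — 324 samples,
28 qPCR detections, none in the fishless control pond.

## The model

For sample *i* the detection indicator is Bernoulli(*p*ᵢ) with

```
logit(p_i) = β₀ + β_density · z(density_i) + β_temperature · z(temperature_i)
             + β_middle · [position_i = middle] + β_bottom · [position_i = bottom]
             + u_section(i) + u_transect(i)
```

where z(·) standardizes the continuous covariates (density by the distinct
pond densities, SD 2.53 fish/m³), surface is the baseline position, and the
optional section/transect random intercepts are Normal(0, σ²) with their
own SDs. Fitting is by MCMC (componentwise adaptive random-walk Metropolis,
3 chains × 200,000 iterations with a 50,000 burn-in by default) under
diffuse Normal(0, 10) priors on the fixed effects and Uniform(0, 10) priors
on random-effect SDs. Candidate models (all 2⁴ subsets of the predictors ×
four random-intercept structures) are compared by DIC with Link–Barker DIC
weights; adequacy is checked with posterior-predictive Bayesian p-values;
the fishless control pond gives a (prior-sensitive) false-positive rate;
and fitted models feed survey-design curves 1 − (1 − p)ⁿ.

## Worked example

```python
import ednadetect as ed

study = ed.builtin_pond_study()                       # 324 samples, 28 detections
stocked = ed.subset(study, predicate=lambda d: d["density_fish_per_m3"] > 0)
std = ed.study_standardization(study)

spec = ed.ModelSpec(fixed_terms=("density", "temperature", "middle"))
fit = ed.fit(stocked, spec, std, ed.TEST_PROFILE)     # desk-scale chains
print(ed.summarize(fit, round_to=2))
```

```
             Mean    SD  Lower95  Upper95    OR
intercept   -3.01  0.47    -4.04    -2.21  0.05
density      2.16  0.43     1.39     3.08  8.66
temperature -0.53  0.24    -1.00    -0.07  0.59
middle      -0.90  0.55    -2.02     0.15  0.41
```

Detection odds rise sharply with fish density (OR 8.7 per 2.53 fish/m³)
and fall with water temperature (OR 0.59 per 1.02 °C — warm water degrades
eDNA faster); mid-column samples detect least. Converting the fit into
survey advice:

```python
coefs = dict(zip(fit.names, fit.flat.mean(axis=0)))
ed.detection_curve(coefs, std, densities=[0.32, 1.75, 5.24], temperature=28.0)
```

```
density 0.32 fish/m3: per-sample p = 0.018, samples for 95% certainty = 164
density 1.75 fish/m3: per-sample p = 0.059, samples for 95% certainty = 50
density 5.24 fish/m3: per-sample p = 0.552, samples for 95% certainty = 4
```

At high density a handful of 1-L samples suffices; at low density a 95%
certainty demands on the order of a hundred litres. The `examples/`
directory holds one short script per capability (data, fitting, model
selection, posterior checks, false positives, survey design, simulation
and parameter recovery), and the same stages are scriptable from a shell:

```
ednadetect select --data builtin --predictors density,temperature,middle,bottom
ednadetect design --p 0.07 --target 0.95      # -> 42
```

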