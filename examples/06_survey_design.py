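"""How many 1-L water samples does a survey need?

Converts fitted coefficients into per-sample detection probabilities at
chosen covariate settings, cumulative detection curves 1 - (1 - p)^n, and
the smallest n reaching a target certainty.
"""

import ednadetect as ed

study = ed.builtin_pond_study()
stocked = ed.subset(study, predicate=lambda d: d["density_fish_per_m3"] > 0)
std = ed.study_standardization(study)

spec = ed.ModelSpec(fixed_terms=("density", "temperature", "middle"))
fit = ed.fit(stocked, spec, std, ed.TEST_PROFILE)
coefs = dict(zip(fit.names, fit.flat.mean(axis=0)))

curves = ed.detection_curve(
    coefs, std, densities=[0.32, 1.75, 5.24], temperature=28.0, position="surface"
)
for c in curves:
    print(f"density {c.density:4.2f} fish/m3: per-sample p = {c.per_sample_p:.3f}, "
          f"samples for 95% certainty = {c.n_required}")

# A fixed per-sample probability can also be used directly:
print("\nat p = 0.07 a 95% certainty needs", ed.samples_required(0.07, 0.95), "samples")
print("at p = 0.55, five samples give a cumulative probability of",
      round(ed.cumulative_detection(0.55, 5), 4))
# Detection is cheap at high fish density (a handful of litres) but the
# required volume grows roughly like 3/p as density falls.
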