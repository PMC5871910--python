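"""Molecular-mass calibration and truncated-HER2 isoform classification.

Fits the log-linear standard curve log10(mass) ~ migration distance on a
four-protein ladder consistent with the BT474-like migration model, then
estimates the mass of a band migrating to 188.2 um with its 90%
prediction interval and classifies the isoform (p95-like < 100 kDa,
p110-like >= 100 kDa).
"""

import numpy as np

import scwb

model = scwb.bt474_migration_model()
rng = np.random.default_rng(0)

# ladder proteins with known masses; distances carry 2 um of measurement noise
ladder = [(name, mass, model.distance(mass) + rng.normal(0, 2.0))
          for name, mass in [("p185HER2", 185.0), ("actinin", 100.0),
                             ("beta-tubulin", 50.0), ("GAPDH", 36.0)]]
print("ladder (protein, kDa, um):")
for name, mass, dist in ladder:
    print(f"  {name:<12} {mass:7.1f}  {dist:7.1f}")

cal = scwb.fit_mass_calibration([(m, d) for _, m, d in ladder])
est = scwb.estimate_mass(cal, 188.2)
print(f"\nband at 188.2 um -> {est.mass_kda:.1f} kDa "
      f"(90% CI {est.ci90_low:.0f}-{est.ci90_high:.0f} kDa)")
print(f"isoform class: {scwb.classify_form(est)}")
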