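"""Logistic regression of conservation concern on precision and accuracy.

Fits concern ~ precision + accuracy + precision:accuracy by IRLS on the
finfish fixture (precision: 1 = ambiguous name; accuracy: 1 = conservative
mislabeling; response: 1 = IUCN Vulnerable or higher), compares the
interaction model against main effects by AICc, and prints Wald inference
with |z| importance - the survey's model-comparison report.
"""

import seafood_audit as sa
from seafood_audit.stats import compare_models, fit_logistic, logistic_design

bundle = sa.load_fixture("finfish")
frame = sa.classify_all(bundle.records, bundle.authority,
                        bundle.status_registry)
usable = frame[(frame.precision != "excluded")
               & (frame.concern != "excluded")]
print(f"usable records: {len(usable)} "
      f"({int((usable.concern == 'concern').sum())} of concern)")

precision = (usable.precision == "ambiguous").to_numpy(float)
accuracy = usable.conservative_mislabeled.to_numpy(float)
y = (usable.concern == "concern").to_numpy(float)

fits = []
for interaction in (True, False):
    X, names = logistic_design(precision, accuracy, interaction)
    fits.append(fit_logistic(X, y, names))

for fit, delta in compare_models(fits):
    print(f"\nmodel: {' + '.join(fit.term_names[1:])}"
          f"  AICc={fit.aicc:.1f} (delta {delta:.1f})"
          f"  McFadden R2={fit.mcfadden_r2:.2f}")
    print(f"{'term':20}{'beta':>8}{'SE':>7}{'z':>7}{'p':>10}"
          f"{'OR':>8}{'importance':>11}")
    for i, name in enumerate(fit.term_names):
        print(f"{name:20}{fit.coefficients[i]:8.2f}"
              f"{fit.standard_errors[i]:7.2f}{fit.z_values[i]:7.2f}"
              f"{fit.p_values[i]:10.2g}{fit.odds_ratios[i]:8.2f}"
              f"{fit.importance[name]:11.2f}")
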