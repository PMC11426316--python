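"""Audit the packaged market survey and print its headline rates.

Loads the transcribed Calgary survey (109 invertebrate, 347 finfish
products), classifies every record against the authority-list snapshot and
prints the year-style summary plus per-taxon rates.  The percentages are
the survey's two headline numbers per cohort: total mislabeling (semantic +
invalid + substitution) and the conservative estimate (invalid +
substitution only).
"""

import seafood_audit as sa
from seafood_audit.report import render_group_rates, summaries_frame

for name in ("invertebrates", "finfish"):
    bundle = sa.load_fixture(name)
    classified = sa.classify_all(
        bundle.records, bundle.authority, bundle.status_registry
    )
    overall = sa.summarize(classified)[0]
    print(f"== {name}: n={overall.n}")
    print(f"   semantic={overall.counts['semantic']}"
          f" invalid={overall.counts['invalid_name']}"
          f" substitution={overall.counts['product_substitution']}")
    print(f"   total mislabeling     {overall.pct_total_mislabeled:5.1f}%")
    print(f"   conservative estimate {overall.pct_conservative_mislabeled:5.1f}%")
    print(summaries_frame(sa.summarize(classified, by="year"), "year")
          .to_string(index=False))
    print(render_group_rates(classified).head(5).to_string(index=False))
    print()
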