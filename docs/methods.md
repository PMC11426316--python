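# Methods

This note documents the models, rules and numerical choices behind
`seafood-audit`, and what the packaged fixture and synthetic generators do
and do not establish about real survey data.

## The classification procedure

A sample is a pair *(market name, barcode candidate set)*. The authority
list is a snapshot table with four kinds of entry:

* **on_list** — a regulated name with a non-empty acceptable-species set.
  Species are stored as Latin binomials or intensionally as whole genera
  (`genus:Sebastes`); a genus entry accepts any binomial of that genus.
* **alias** — an off-list name a consumer would read as one particular
  on-list name ("unagi" → "eel"). Aliases resolve transitively and must
  terminate in exactly one on-list entry; cycles are a configuration error.
* **invalid** — an off-list name too unusual for any appeal to the list.
  The entry may carry an *expectation set*: the species the odd name
  conceivably hinted at.
* **unregulated** — legally outside the list (mixed products).

The classifier is a pure function of the pair and these tables:

1. unregulated name → `unregulated` (kept in denominators as
   not-mislabeled, excluded from precision analyses);
2. on-list name: any overlap between candidates and the acceptable set →
   `properly_labeled`, else `product_substitution`. Overlap on a
   multi-species barcode deliberately passes: the barcode lacked the
   resolution to prove mislabeling, so the audit stays conservative;
3. alias: overlap with the *resolved* entry's set → `semantic` (the name
   is wrong but the content is what the buyer expected), no overlap →
   `product_substitution`;
4. invalid name: candidates inside the expectation set → `invalid_name`
   (the *name* is the defect), outside it → `product_substitution` (the
   content is the defect too). An empty expectation set always yields
   `invalid_name`.

Rule 4's expectation set is the one place this implementation refines the
simpler "off-list and un-aliased ⇒ invalid" rule: survey adjudications can
split records under the same invalid name into invalid-name and
substitution calls depending on the content (an "Alaskan salmon" that is
sockeye versus one that is rockfish), and the expectation set is exactly
the information needed to reproduce that as a function of the record.

Conservative mislabeling = invalid names + substitutions; total adds
semantic cases. Percentages are computed at full precision and rendered at
one decimal, matching survey reporting conventions.

## Precision (ambiguity) of market names

A regulated or adjudicated name is *precise* iff exactly one species may
be sold under it, judged on the resolved entry: genus-wide entries and
names carrying a multi-referent flag (off-list names that could denote
several species, e.g. "Pacific rockfish", "red tuna") are ambiguous.
Unregulated names have no precision and raise a dedicated signal so
downstream tables exclude them explicitly rather than silently.

## Worst-case conservation status

IUCN categories are ordered NA < DD < LC < NT < VU < EN < CR and a product
takes the maximum over its barcode candidates, so any assessed (data-based)
category dominates Not-Applicable and Data-Deficient. Species absent from
the status table are imputed NA. The concern dichotomy is VU-or-higher
versus LC/NT, with NA/DD records excluded from conservation analyses. The
assignment is order- and duplication-invariant, and the severity of a
union of candidate sets is at least the severity of each part.

## Statistical layer

All tests consume explicit 2×2 `ContingencyTable`s that record how many
records each exclusion dropped; degenerate tables (an empty margin) refuse
to run rather than returning NaN.

* **Chi-square**: X² = Σ(|O−E|−c)²/E with Yates correction c = ½ (capped
  at |O−E|) on by default, df = 1, upper-tail p. The correction default
  matches the convention under which the survey's printed statistics
  (33.5 / 0.04 / 0.01) arise.
* **Fisher's exact test**: full enumeration of the hypergeometric support;
  the two-sided p sums all tables no more probable than the observed one
  (with a 1 + 1e−7 slack against ties in floating point). The odds ratio is
  the conditional MLE under the noncentral hypergeometric likelihood,
  found by bracketing + Brent root-finding on the mean equation in
  log-odds; zero-margin counts give OR 0 or ∞ exactly. Confidence
  intervals invert the exact test (two-sided: α/2 in each tail, the R
  convention; one-sided alternatives give half-open intervals).
* **Logistic regression**: IRLS with step-halving (the log-likelihood is
  non-decreasing by construction), convergence at relative log-likelihood
  change < 1e−10 within 50 iterations, standard errors from the inverse
  Fisher information. AIC = 2k − 2ℓ; AICc adds 2k(k+1)/(n−k−1) and drives
  model ranking (both are reported, selection uses the small-sample
  corrected form). McFadden pseudo-R² = 1 − ℓ/ℓ₀ with the intercept-only
  ℓ₀ in closed form. Variable importance is |z| per term; VIFs come from
  the inverse correlation matrix of the non-intercept columns with the
  conventional warn threshold of 5. Quasi-separation (any |β| > 15 on the
  logit scale) is flagged, never silently accepted; Wald (not profile)
  intervals are used for odds ratios — closed-form, deterministic, and
  adequate at the audit's sample sizes.

## Barcode identification stand-in

Real surveys delegate identification to an online engine; this package
ships a transparent local substitute so the pipeline is self-contained and
auditable. Needleman–Wunsch global alignment with match +1, mismatch −1,
linear gap −2; `N` matches nothing and scores as a mismatch. Identity is
100 × matched columns / alignment columns of one optimal alignment, with
DP ties broken deterministically (diagonal over up over left) so values
are reproducible and symmetric. Candidates are the species of all
references within a 0.5-point tie window of the best identity, subject to
a 97% floor; queries under 200 nt return no candidates and a `too_short`
flag (short fragments are how contaminant matches slip through), and >5%
`N` content flags a suspect sequence. The thresholds are exposed
parameters, and no equivalence to any online identification service is
claimed — fixture candidate sets are transcribed, never recomputed.

## The packaged fixture

The fixture transcribes a published Calgary market survey: per-market-name
mislabeling tables (33 invertebrate and 78 finfish names), year-by-year
tallies, an authority-list snapshot covering every name, and an IUCN
status snapshot covering every barcoded species. Expansion to per-record
rows is deterministic (`scripts/build_fixtures.py`) and the files are
content-addressed: `load_fixture` verifies sha256 checksums before parsing.

Two kinds of completion were unavoidable and are flagged in the data:

* The survey prints barcode identities only for mislabeled records;
  correctly-labeled records receive an acceptable species and carry
  `imputed=1`.
* Sampling year is printed only as per-year totals; records are assigned
  to years by a deterministic fill that reproduces every per-year count.

The authority snapshot records, per name, only what the survey itself
fixes (which names are ambiguous because of genus-wide or multi-species
allowances, which aliases exist, which names are invalid and what they
hinted at); the remaining precision flags are snapshot metadata chosen
once to match the survey's cohort-level ambiguity tallies. Two printed
percentages (32.2 where the underlying counts give 32.258) reflect
truncation in the source; the package reports the exactly-rounded 32.3 and
the tests compare counts exactly and percentages at printed precision.

Reproducing the fixture therefore shows the *rules* are the survey's rules
— every per-name semantic/invalid/substitution cell, every year row, the
cohort ambiguity tallies and the conservation composition follow from the
snapshot tables. It does not validate the snapshot against the live
regulatory list or Red List, both of which move over time.

## Synthetic surveys

`generate_survey` draws each record independently: a market name (its own
entry per record; ambiguous with probability `ambiguous_fraction`), a
latent mislabeling type from (semantic, invalid, substitution, proper)
rates, a barcoded species constructed to *be* that type under the emitted
authority table, and a conservation status (VU vs LC) drawn from the
(precision, accuracy) cell probability. Default cell probabilities follow
the fitted finfish model's cell log-odds (−2.11, +3.39, +3.21, −3.39).
One `numpy` generator seeded from the config is threaded through every
draw; identical configs reproduce identical surveys.

Because names are not shared across records, the generator cannot emulate
name-level clustering (many samples of one popular name) or species-level
status correlation across records — features real surveys have. What
passing recovery tests show is that the classifier and the estimators are
correct under the generating model, not that real markets satisfy it.

`generate_refdb` mutates a common ancestor at the requested divergence per
species and at divergence/20 within species, keeping identification
well-posed; divergences under 1% are refused because clades would sink
into within-species noise.

## Problem sizes in the default test run

The suite exercises the full 456-record fixture everywhere; GLM parameter
recovery simulates n = 10,000 once and Wald-interval coverage uses 200
replicates of n = 400; synthetic rate recovery uses n = 1,000 surveys; the
alignment oracle enumerates all alignments for sequences up to 8 nt. These
sizes make the statistical assertions sharp (3 SE bounds, exact binomial
intervals) while keeping the whole suite around ten seconds.

## Known limitations

* The authority and status tables are snapshots; the pipeline performs no
  live lookups and no taxonomy synonym resolution beyond the explicit
  alias rows.
* Semantic-versus-invalid adjudication is data-driven by design: a name is
  semantic only if the alias table says how a consumer would read it.
  Auditing a new survey therefore requires curating that table.
* The identification stand-in is not a re-implementation of any online
  engine and should not be used to re-identify published records.
* Wald intervals undercover slightly at small n with separated cells; the
  separation flag marks fits whose intervals should not be trusted.
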