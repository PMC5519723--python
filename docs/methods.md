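# Methods

## Problem setting

The package infers a bipartite directed graph from diseases to the symptoms
they cause, using only co-occurrence patterns in binary per-visit indicator
data.  Each record is one patient visit; a concept indicator is 1 when the
visit carries at least one non-negated text mention of the concept or a
mapped diagnosis code.  Associations in such data are statistical, not
declarative: comorbidity, age structure and charting practice all induce
correlations that are not causal, which is why three models with different
assumptions are fitted and compared.

## Models

**L1 logistic regression** (one model per disease *j*): the disease
indicator is regressed on all symptom indicators.  Because all features are
binary, weights are comparable across symptoms, and `max(b_ij, 0)` is used
as the edge importance — only symptoms whose presence raises the disease
probability suggest edges.  An intercept is always included but never enters
the importance.  The regularization path is `10^-4 … 10` (6 log-spaced
points), selected per disease by mean held-out log-loss over 3 stratified
folds; ties go to the stronger penalty, matching the prior belief that each
disease causes few symptoms.

**Naive Bayes** (one model per disease): the smoothed conditionals are the
closed-form counts
`p(x_i=1|y_j=1) = (n_i1 + α)/(n_1 + 2α)` and likewise for the
disease-absent arm.  The importance is the log relative risk
`log p(x_i=1|y_j=1) − log p(x_i=1|y_j=0)`: a rare symptom made three times
more likely by a disease scores identically to a common one made three
times more likely, which is the desired behaviour for surfacing rare but
diagnostic symptoms.  The pseudocount grid is {0.1, 0.5, 1, 2, 5}, selected
by held-out predictive log-likelihood of the symptoms given the label over
the same folds; ties go to the heavier smoothing.

**Noisy OR**: the two-layer network
`P(x_i=1|y) = 1 − (1 − l_i) ∏_j f_ij^{y_j}` with failure probabilities
`f_ij` and leak `l_i`.  All parameters are estimated jointly by maximum
likelihood; no prior over the disease vector is assumed, which is what
distinguishes the model from the per-disease classifiers (those implicitly
treat diseases as independent).  The importance is `1 − f_ij`.

### Noisy-OR optimization

With fully observed disease columns the log-likelihood separates exactly
across symptoms, so the joint MLE decomposes into one concave-like
(d+1)-parameter problem per symptom.  Each is solved by L-BFGS on
log-odds-transformed parameters with analytic gradients; records are grouped
by unique disease pattern first, so cost scales with the number of distinct
patterns (at most `2^d`), not with n.  Initialization is moment-based:
`l_i` = symptom rate among disease-free records, and
`f_ij = 1 − max(0, p̂(x_i|y_j=1) − p̂(x_i|y_j=0))`, both clipped to
`[10^-3, 1 − 10^-3]` before the transform.  Iterates that fail to improve
the likelihood are rejected from the recorded trace and the best accepted
iterate is returned, so the reported final log-likelihood is never below the
initial one.  Termination: relative improvement below `tol` (default
`10^-8`) or `max_iter` (default 500).  All output probabilities are clamped
to `[ε, 1 − ε]` with `ε = 10^-6`; boundary solutions (deterministic edges,
never-co-occurring pairs) therefore report importances of `1 − ε` / `ε`
rather than exact 0/1.  The fit is deterministic; the `seed` parameter
exists for interface uniformity across fitting routines.

### Cross-validation determinism

Fold assignment deals record ids — sorted, then permuted by the seed —
round-robin within each label stratum.  This makes model selection invariant
to the order in which patients appear in the matrix, given the same seed.
Grid points whose folds lack both classes are skipped with a warning; if no
grid point is usable the strongest regularization/smoothing is used.

## Extraction conventions

Negation scopes open after each trigger (default set: denies, denied, no,
not, without, negative for, free of, ruled out) and run to the earliest of a
termination token (but, however, except), clause or sentence punctuation
(`, . ; : ! ?`), or 6 tokens; overlapping scopes merge.  Commas terminate
scopes so that consecutive denials ("no chest pain, no nausea") produce one
scope per trigger rather than one merged scope.  Matching is
case-insensitive at word boundaries with no stemming; longer aliases win
overlaps, then leftmost position.  Spans are 0-based half-open character
intervals.  Diagnosis codes match exactly (no prefix matching).  Alias
collisions across concepts resolve to the disease-role concept, then the
smallest concept id, and are logged.

Support filtering keeps disease columns with ≥ 100 positives and symptom
columns with ≥ 10; the 5-co-occurrence de-noising floor applies to the
pairwise models only (the noisy-OR likelihood already discounts
unsupported pairs), with a flag to extend it.  Filtered pairs are removed,
not zeroed, so a 0 threshold cannot resurrect them.

## Evaluation conventions

PR curves sweep every distinct score as a threshold and micro-average over
all pairs (one pooled contingency table per threshold), so
precision × retrieved is always an integer count.  The recall denominator
for the automatic evaluation defaults to reference edges whose concepts
survive support filtering (`restrict_to_scored=False` gives the
unrestricted denominator).  The symptom "pain" is excluded by default as
over-general.  A static reference source evaluated through its two
frequency buckets yields exactly two PR points, not a curve.

The Wilcoxon signed-rank comparison drops zero differences (Pratt handling
available), uses average ranks for ties, and computes the exact sign-flip
null by dynamic programming over doubled ranks for up to 25 nonzero pairs;
beyond that, the normal approximation with tie-corrected variance
(`Σ r_k² / 4`) without continuity correction.  Spearman ρ confidence
intervals are percentile bootstrap over edges (default 1000 replicates);
replicates with a constant resampled vector are skipped.

## Synthetic generator

The generator emulates the features of emergency-department data that
matter for this methodology and nothing more:

* **age-bracket confounding** — a categorical bracket (child / young adult /
  adult / senior) is the single latent cause: diseases are independent given
  the bracket but marginally correlated through it, and confounders can
  activate symptoms directly per bracket.  This is the minimal structure
  that reproduces the failure mode where pairwise models promote non-causal,
  age-associated symptoms;
* **noisy-OR symptom generation** with known failure/leak parameters, so
  recovery can be measured exactly;
* **missing-not-at-random omission** — present symptoms are masked with a
  configurable probability (applied to symptoms only; disease codes are
  assumed reliably coded);
* **text rendering** with per-concept alias sampling, sentence-terminated
  templates and explicit denial insertion, exercising the negation and
  matching rules end-to-end.

It does **not** model realistic clinical language, longitudinal visit
structure, symptom–symptom causation, or richer comorbidity than the single
latent bracket; passing tests therefore demonstrate correctness of the
machinery and the qualitative model contrasts, not performance on real
records.  An optional per-patient disease-count cap emulates the "patients
present with few diseases" effect; it is off by default.

The demo corpus (6 diseases, 12 symptoms, failures 0.25–0.85, leaks
0.002–0.06, senior-bracket confusion confounder at 0.08, omission 0.05,
denial insertion 0.25) was chosen once as a plausible acute-care profile
and is fixed.

## Verified properties and problem sizes

The test suite checks, at fixed seeds: boundary behaviour of the noisy-OR
MLE (deterministic pair → importance ≈ 1; never-co-occurring pair →
importance ≈ 0; n = 10,000, tolerance 0.01); parameter recovery (single
pair, n = 50,000, |f̂ − f| ≤ 0.02, |l̂ − l| ≤ 0.01; and a 6-disease,
12-symptom network where the max-abs parameter error decreases across
n = 10³, 10⁴, 10⁵ with matched seeds — sizes chosen to keep the full suite
in seconds while staying in the regime where sampling error dominates);
agreement of the fit with an independent 200 × 200 grid search on
single-pair instances within 10⁻³ log-likelihood; exact equality of naive
Bayes conditionals with hand counts; equality of the Wilcoxon p-value with
brute-force sign-flip enumeration for n ≤ 12; hand-enumerated PR points on
6-edge toys; exact extraction round-trip of rendered corpora
(collision-free aliases, omission 0); the 100/10/5 support and
co-occurrence boundaries; the confounding contrast (the bracket-activated
symptom ranks strictly better under the naive-Bayes importance than under
noisy OR in ≥ 8 of 10 seeded corpora — it held in 10 of 10 at the shipped
configuration); and structural invariants (monotonicity of the noisy-OR
conditional in its parents, monotone fit likelihood traces, PR nesting
under threshold tightening, byte-stable serialization round-trips).

## Known limitations

* The negation rule set is a deliberately simple NegEx-style convention
  (fixed trigger list, 6-token scope); it is a stand-in, not a validated
  clinical NLP component.
* Concept matching has no spelling or punctuation normalization, so
  variant-heavy symptoms would be under-counted on real text.
* The noisy-OR decomposition relies on diseases being fully observed;
  latent-disease inference is out of scope.
* Importances near the probability clamp (`ε = 10⁻⁶`) are reported at the
  clamp, not at the exact boundary.
* The logistic model's liblinear solver is deterministic but its weight
  signs on near-collinear symptom sets can be sensitive to regularization;
  interpretation should stay at the level of the clipped importance.
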