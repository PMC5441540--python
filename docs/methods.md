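# Methods

## Word-trajectory graphs

A report's tokens are mapped to a directed multigraph: nodes are the
distinct words, and each consecutive token pair contributes one edge, so
E equals token count − 1 for a contiguous report and is a direct verbosity
measure. Connectedness is summarized by E, LCC (largest weakly connected
component, "linked by some path" ignoring direction) and LSC (largest
strongly connected component, mutual reachability). The trajectory of a
contiguous report is always weakly connected, so for whole reports LCC
equals the distinct-word count; LCC becomes informative only for windowed
sub-graphs or externally supplied edge lists.

Conventions, fixed and configurable:

* **Tokenization** — maximal non-whitespace runs; default lowercasing and
  stripping of leading/trailing punctuation, keeping intra-word hyphens
  and apostrophes. The structural method treats tokens as opaque symbols,
  so fillers and disfluencies are ordinary words. Both switches are
  exposed because transcription conventions vary between labs.
* **Self-loops** — a consecutively repeated word yields a self-loop edge
  by default (`keep_self_loops=False` drops the edge but keeps the node).
  Either way a single node is a strong component of size 1, so the choice
  does not affect LSC.
* **Windowed attributes** — for protocols without a time limit, attributes
  are averaged over sliding windows of 30 tokens advanced by 1 (maximal
  overlap; both window and step configurable). A report shorter than the
  window is an error directing the caller to whole-report attributes.

Internally, surrogate evaluation uses a compact iterative Tarjan
implementation on integer-coded sequences; it is cross-checked in the test
suite against networkx components and against a brute-force
transitive-closure reachability oracle on ~1000 random sequences.

## Surrogate null and the random-like call

Each report is compared with n = 1000 uniform random permutations of its
own token sequence, rebuilt into trajectory graphs. This null preserves
the word multiset — hence the node set and E — exactly, so verbosity is
controlled by construction and only ordering information is tested.
LSCz = (LSC − LSCmr)/LSCsdr uses the population standard deviation over
the surrogates (divisor n; immaterial at n = 1000 but fixed). A report is
random-like when its designated z-score (LSCz by default; LCCz or both
available) lies in the closed band [−2, +2].

Degenerate variance is legal and resolved explicitly: when every surrogate
has the same LSC (e.g. an all-distinct-word report) and the original
equals that value, z := 0 and the report is random-like — loop-free speech
is indistinguishable from its own shuffles; when the original differs, z
is a signed infinity, a warning is logged, and the report is never
random-like.

Two consequences of the sequence-permutation null are worth stating
plainly:

* **LCCz is degenerate.** Permuting a contiguous sequence never changes
  weak connectivity, so LCCsdr = 0 and LCCz resolves to 0 for every whole
  report. All discriminative signal under this null is carried by LSCz.
  An edge-rewiring null (random graphs with the same node and edge
  counts, not constrained to be trajectories) would make LCCz informative
  but would no longer conserve trajectory structure or calibrate the
  random-like band against the report's own orderings; this package
  implements the permutation null throughout.
* **Structured speech separates mostly downward.** Random orderings of a
  multiset are already nearly maximally strongly connected, so an
  ordering can exceed its shuffles' LSC by only about two standard
  deviations, while orderings whose recurrences cluster locally (as
  syntax clusters them) fall many standard deviations *below*. Distance
  from randomness is therefore best read as |LSCz|.

## Synthetic transcripts and cohorts

The generator is this package's own construction (the analysis itself
prescribes no generative model). Tokens are emitted sequentially; with
probability rho a step revisits an already-used word, otherwise a fresh
word enters from an unbounded vocabulary. Revisit targets are
recency-weighted by default (geometric with p = 0.5 over words ordered
most-recently-used first), clustering recurrences locally; a `uniform`
mode yields nearly exchangeable, structureless orderings at any rho and
serves as a null generator. Report lengths are uniform on 40–120 tokens,
emulating 30-second time-limited reports.

Under the permutation null this one parameter reproduces the clinically
observed spectrum: rho near 0 gives loop-free, random-like reports
(the schizophrenia-like regime); growing rho grows LSC monotonically and
pushes |LSCz| far beyond 2 (the structured, control-like regime). Default
per-subject rho ranges are U(0, 0.04) for schizophrenia-like, U(0.01,
0.08) for bipolar-like and U(0.08, 0.30) for control-like subjects
(cohort sizes 11/10/21), chosen once from a design scan over rho to
place the group random-like rates near the published 64%/30%/5% gradient;
pooled simulation gives ≈ 0.65/0.35/0.03.

Symptom scores are generated from attributes, not group labels, so the
index's anchoring assumption is true by construction:
score = 32 − 0.8·LSC + 0.9·LSCz + ε, ε ~ N(0, 3²), evaluated on the
negative-image report and clipped to the PANSS negative subscale's
feasible range [7, 49]; controls receive no score. The LCC coefficient
slot exists and defaults to 0: in this generator LCC tracks the
distinct-word count, which is strongly collinear with the intercept in
the unit-length-scaled sense (condition index ≈ 10 on cohorts of this
size), so a nonzero LCC effect would not survive the pruning step and
could not be recovered stably. At these defaults the patient-only fit
attains R² ≈ 0.5–0.6 — a deliberately moderate effect size; noise_sd is
the single dial for making the pipeline's task easier or harder.

What the generator does **not** emulate: natural-language semantics or
syntax, realistic (Zipfian) vocabulary frequencies, within-subject
report-type correlations beyond a shared rho, or rater noise in symptom
scoring. Passing tests therefore demonstrate correctness and calibration
of the *pipeline* under a controlled recurrence model, not clinical
validity on real speech.

## Disorganization Index

Candidates are regressed on the symptom total by OLS after Belsley-style
collinearity pruning: all columns (intercept included) are scaled to unit
length, the SVD gives condition indices s_max/s_j and per-variable
variance-decomposition proportions; while any condition index exceeds 10,
the variable with the largest proportion on an offending component is
dropped (ties: largest proportion summed over offending components, then
input order; the intercept is never droppable; dropping every candidate
raises an error that names the single best-correlated attribute).
Complete-case analysis per model handles missing reports (e.g.
unrecallable dreams); imputation is deliberately not offered. The
``negative_dream`` reference index's inputs name their report
(``LSC_negative``, ``LCC_dream``), and the pipeline falls back to the
negative-image-only reference index, with a logged notice, for subjects
missing a dream report.

Observed power of a fit is the post-hoc power of the overall F-test at
α = 0.05 with effect size f² = R²/(1 − R²) and noncentrality λ = f²·n
(the λ = f²·(n − k − 1) alternative differs negligibly at these sizes).
scipy's `stats.ncf.sf` is numerically unreliable at small noncentrality,
so the computation goes through `scipy.special.ncfdtr`, with the exact
central-F value (= α) at λ = 0; the implementation is verified against
Monte-Carlo simulation. The prevalence-based planning formula
N = Z²P(1 − P)/d² rounds up and floors at 1.

## Statistics battery

Rank-based group contrasts (tie-corrected Kruskal–Wallis; two-sided
Wilcoxon rank-sum, exact for small samples without ties), Pearson
chi-square on 2×2 tables (Yates correction off by default, flag
provided), Spearman correlations (exact p by full enumeration for n ≤ 9
without ties, t approximation otherwise), and partial Spearman defined as
Pearson correlation of rank-transformed variables residualized on the
rank covariates (df = n − 2 − #covariates) — several inequivalent
"partial Spearman" definitions exist; this is the one used throughout.
Multiplicity uses Bonferroni thresholds by comparing raw p to α/m
(thresholds reported with half-up rounding, e.g. 0.05/8 → 0.0063).
Distribution screening offers one-sample Kolmogorov–Smirnov against a
normal with estimated parameters (approximate; Lilliefors correction
optional) and the Levene test, mean-centered by default with a median
(Brown–Forsythe) option. All-identical inputs return the degenerate
H = 0 / W = 0 with p = 1 rather than an exception.

## Classification

Gaussian naive Bayes (per-class variances, sklearn's 1e-9 relative
variance floor) with stratified k-fold CV (k = 10 by default, reduced to
the minority-class size with a warning when necessary; the seed is always
explicit). Posteriors are pooled across folds into a single ROC: the AUC
is the Mann–Whitney statistic on pooled out-of-fold posteriors, and
confusion-matrix metrics use the 0.5 threshold. Specificity is the
standard true-negative rate; class-weighted averages of
sensitivity/specificity are also emitted because published tables differ
in convention. Pooled cross-validated scores are pessimistically biased
under the null (training folds anti-learn noise): at n = 200 with 10
folds the null AUC distribution centers near 0.48 rather than 0.50, an
O(1/n) effect the calibration tests account for.

## Problem sizes in the test and acceptance suites

Simulation studies are sized for single-CPU runs: null-band calibration
uses 600 structureless reports × 1000 surrogates; coefficient-recovery
coverage uses 200 cohorts of 21 patients at 150 surrogates per report;
the group-gradient check pools eight default cohorts (single cohorts of
11/10/21 leave ~±0.15 binomial noise on group rates; pooling makes the
ordering decisive); classifier calibration uses 500 null runs at n = 200.
These sizes are the package's standing choices and are encoded in the
tests and in `scripts/acceptance.py`.

## Known limitations

* The permutation null makes LCCz uninformative for whole reports (see
  above); analyses should rely on LSCz, as the random-like call does.
* Exact Spearman enumeration is O(n!) and is therefore capped at n ≤ 9.
* The reference index coefficients were estimated on small clinical
  cohorts; applying them to new populations, languages, or elicitation
  protocols is an extrapolation, and refitting is recommended whenever
  symptom scores are available.
* The synthetic generator controls connectedness structure only; no
  conclusion about real-speech semantics or about clinical performance
  follows from synthetic results.
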