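# speechdisorg

Graph-structural analysis of verbal reports for quantifying formal
thought disorder — the speech disorganization (poverty of speech,
derailment, loosened associations) that accompanies psychosis and tracks
negative-symptom severity.

The package is aimed at computational-psychiatry researchers working with
short transcribed speech samples (e.g. 30-second memory reports): it turns
each transcript into a word-trajectory graph, measures how far its
connectedness lies from randomly ordered speech, condenses the attributes
into a single symptom-anchored **Disorganization Index**, and evaluates how
well that index classifies diagnosis and negative-symptom severity.

## The method

**Word-trajectory graph.** Each unique word of a report is a node; every
pair of consecutive tokens contributes one directed edge (a multigraph, so
E = word count − 1 and directly measures verbosity). Three connectedness
attributes summarize the graph:

* **E** — number of word-to-word transitions;
* **LCC** — nodes in the largest component connected by some path,
  ignoring edge direction;
* **LSC** — nodes in the largest *strongly* connected component (all
  members mutually reachable along directed paths): the recurrent "loop"
  structure of speech.

Verbosity is controlled either by normalizing attributes by word rate, or
— for protocols without a time limit — by averaging attributes over
sliding 30-word windows.

**Similarity to random speech.** Each report is compared with 1000
surrogates obtained by uniformly shuffling its word sequence (identical
words and edge count, randomized order). With LSCmr/LSCsdr the surrogate
mean and standard deviation,

    LSCz = (LSC − LSCmr) / LSCsdr

locates the report inside its own null distribution. A report with
|LSCz| ≤ 2 is **random-like**: its loop structure is indistinguishable
from shuffled speech — the structural signature of disorganization.

**Disorganization Index.** Attributes that separate the clinical groups
are regressed (OLS) on the PANSS negative subscale total after a
Belsley-style collinearity pruning loop: columns scaled to unit length,
SVD condition indices computed, and while any condition index exceeds 10
the variable with the largest variance-decomposition proportion on an
offending component is dropped. The surviving affine combination

    Index = b0 + Σ b_k · attribute_k

is the Disorganization Index (higher = more disorganized). Four reference
coefficient sets estimated on clinical cohorts ship with the package, e.g.

    Index(negative) = 31.43 − 0.30·LCC + 0.08·LSC − 2.12·LSCz

**Classification.** Gaussian naive Bayes with seeded stratified 10-fold
cross-validation, pooled out-of-fold posteriors, AUC as the rank statistic
on the pooled posteriors; severity labels come from a median split of
patient PANSS negative totals (high = strictly above the median).

Because no clinical data ship with the package, a synthetic-cohort
generator (`speechdisorg.synthetic`) produces transcripts with a tunable
recurrence parameter and symptom scores generated *from the graph
attributes*, so every stage — including parameter recovery of the index
regression — is testable end to end.

## Worked example

```python
import speechdisorg as sd

text = ("I was walking in a garden and the garden was full of birds "
        "and I remember the birds singing while I was walking home")
t = sd.Transcript.from_text("s01", "image_negative", text, duration_s=30)
attrs = sd.sequence_attributes(t.tokens)
dist = sd.make_surrogates(t.tokens, n=1000, seed=7)
sc = sd.z_scores(attrs, dist)
score = sd.REFERENCE_INDICES["negative"].score(
    {"LCC": attrs.LCC, "LSC": attrs.LSC, "LSCz": sc.LSCz})
```

prints, step by step:

```
word rate: 24 E: 23 LCC: 15 LSC: 14
LSCmr=13.86 LSCsdr=1.37 LSCz=0.10 random_like=True
Disorganization Index (negative-image): 27.84
```

This little report repeats its words enough to build a 14-node strong
component, but its loops are no larger than its own shuffles produce
(LSCz = 0.10, inside the ±2 band), so it is classified random-like, and
the reference negative-image index scores it 27.84.

Fitting the index on a synthetic cohort (statsmodels-style model/results):

```python
cohort, truth = sd.generate_cohort(sd.GeneratorConfig(seed=42))
res = sd.DisorganizationIndex.from_cohort(
    cohort, ["LSC_negative", "LSCz_negative"]).fit()
print(res.summary())
```

```
Disorganization Index (fitted)
==============================================
n (complete cases)      21
candidates              ['LSC_negative', 'LSCz_negative']
dropped (collinearity)  none
final condition index   4.42
R-squared               0.5612
F-test p-value          0.000603
observed power          0.9927
----------------------------------------------
term                  coef        se         p
const              32.1007    1.6574    0.0000
LSC_negative       -0.8421    0.5235    0.1251
LSCz_negative       1.3148    0.3922    0.0035
```

Only the 21 patients enter the fit (controls carry no symptom score); the
design passes the collinearity screen, the regression explains 56% of the
symptom variance, and its post-hoc power is 0.99. On the same cohort the
random-like rates reproduce the expected clinical gradient
(schizophrenia-like 0.55, bipolar-like 0.30, control-like 0.00).

A command-line interface mirrors the library:

```bash
speechdisorg simulate --out sim/ --seed 2
speechdisorg run --transcripts sim/transcripts.tsv --metadata sim/metadata.tsv \
    --out results/ --index fit --seed 3
```

## Documentation

`docs/methods.md` documents the model and its assumptions, all tunable
parameters with defaults and rationale, what the synthetic generator does
and does not emulate, numerical conventions (tie-breaking, degenerate
variance, zero-noncentrality power), and known limitations.
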