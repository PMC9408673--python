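# Methods

`epiwatch` implements a two-stage surveillance method for online epidemic
information: (1) identification and removal of false messages, (2) daily
public-opinion early-warning indicators over the surviving ("effective")
messages. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic data generator does and does not
emulate.

## Stage 1 — identification of false epidemic information

### Reliable-source scoring

The link structure of the crawled pages is encoded as a column-stochastic
transfer matrix *M*: entry (i, j) = 1/outdegree(j) when page j links to
page i, zero otherwise; pages without out-links have an all-zero column.
Self-links and duplicate links are removed during construction (the matrix
models simple links); links to pages outside the crawl are dropped with a
warning.

Reliability is the stationary distribution of a damped random surfer
(PageRank): at each step the surfer follows a random out-link with
probability *d* and teleports uniformly with probability 1 − *d*; the mass
of dangling pages is redistributed uniformly. Defaults: damping *d* = 0.85
(the standard web-graph value), L1 tolerance 1e-10, max 1000 iterations.
The iteration conserves probability mass exactly, so scores sum to 1 at
every step.

Selection policy: by default a page is reliable when its score is at least
the uniform baseline 1/N (multiplier configurable); a top-fraction policy
is available as an alternative. The scorer is deliberately pluggable: the
propagation scheme behind source reliability is a modelling choice, and the
threshold policy is exposed because only the outcome of such a selection —
not its rule — is ever observable in practice.

### The nine-feature system

Eight classification features over four levels, plus one regulatory
feature. For message *i* with nouns N<sub>i</sub> and a fixed list of
epidemic subject feature words F:

| feature | definition | range |
|---|---|---|
| F1 subject relevance | mean over all (noun, feature-word) pairs of max(PMI, 0) | ≥ 0 |
| F2 feature words | count of noun/verb/adjective/adverb tokens W<sub>i</sub> | ≥ 0 |
| F3 clauses | clause count S<sub>i</sub> | ≥ 0 |
| F4 effective length | E<sub>i</sub>/T<sub>i</sub>, effective over raw characters | [0, 1] |
| F5 emotional intensity | P<sub>i</sub>/(P<sub>i</sub>+R<sub>i</sub>), positive over polarized clauses | [0, 1] |
| F6 publisher name | 1 if real name else 0 | {0, 1} |
| F7 publisher level | platform tier | {1, 2, 3} |
| F8 history amount | messages released historically H<sub>i</sub> | ≥ 0 |
| F9 false history (regulatory) | running false fraction among the publisher's classified messages | [0, 1] |

PMI(a, b) = log p(a, b) / (p(a) p(b)) with natural log; probabilities are
document frequencies (share of documents containing the word / both words)
with additive smoothing *s* on each probability (default 0 in unit tests
for exactness, 1e-9 in the pipeline to avoid log 0). Document-level
co-occurrence was chosen over window-level because messages are short and
the corpus — not the sentence — is the natural sampling unit here.

Design points where the definitions above were genuinely open:

* **F1 aggregation.** The m×k pair matrix is aggregated by the mean of
  *non-negative* PMI values. Negative PMI encodes topical irrelevance;
  clipping at zero keeps one irrelevant noun from cancelling a strongly
  relevant one, matching the reading that higher relevance means more
  likely true. A message without nouns scores 0.
* **F5 with no polarized clauses.** P + R = 0 returns 0.5 — maximally
  non-extreme, since extremes on either side are the falsity signal.
* **"Invalid characters" for F4.** Whitespace, punctuation and URL
  substrings by default, configurable as a regular-expression list;
  counting is in Unicode code points.
* **F9 update rule.** The "increase" of the publisher's false-history
  probability is the empirical false fraction among their classified
  messages (0 before anything is classified). Elimination at threshold
  θ (default 0.5) is a hard removal of all the publisher's messages —
  deterministic, idempotent, monotone in θ.
* **F9 as classifier input.** By default F9 only drives elimination (it is
  regulatory state, not content evidence, and feeding it back into the
  classifier that produced it risks a feedback loop); a flag
  (`use_f9_in_classifier`) includes it for experimentation.

Annotations (clause segmentation, POS tags, clause polarity) are input
data: production taggers differ by language and platform and are out of
scope. A naive lexicon-lookup annotator ships as an explicitly marked
baseline for raw text.

### Boosted-tree classifier

The classifier is an additive ensemble of regression trees fit to the
second-order expansion of the regularized logistic objective

    Obj = Σᵢ l(yᵢ, ŷᵢ) + Σₜ [ γ·Tₜ + (λ/2)·Σⱼ w²ₜⱼ ]

Each round computes per-sample gradient g = p − y and hessian h = p(1 − p)
at the current margin, grows one tree by exact greedy split search (gain
½[G²_L/(H_L+λ) + G²_R/(H_R+λ) − G²/(H+λ)] − γ over all features, with
thresholds at midpoints of consecutive distinct values, ties routing left),
and sets each leaf to the closed-form optimum −G/(H+λ), scaled by the
learning rate. Growth is depth-wise; there is no subsampling, histogram
approximation or multi-class support — the learner is the minimal faithful
form of the objective, which is the point.

Defaults mirror common gradient-boosting practice: learning rate 0.3,
depth 3, 50 rounds, λ = 1, γ = 0, minimum child hessian 0. The initial
margin is the log-odds of the training base rate (configurable; a fixed
margin of 0 reproduces a reference implementation's base_score = 0.5).
The regularized objective is recorded per round; it is non-increasing on
every seeded fixture in the suite. In tests the ensemble's margins agree
with xgboost's exact-greedy trees to within the reference's float32 leaf
precision.

Classification: a message is false when its falsity probability is ≥ 0.5
(threshold configurable, open interval; the tie goes to false — the
conservative direction for filtering).

### Pipeline

`run_identification` chains: reliable-source selection → co-occurrence
statistics → feature extraction → stratified train/test split (seeded;
default 80% train) → training → held-out accuracy and confusion counts →
classification of the full corpus → publisher false-history update →
θ elimination. The *effective corpus* is what remains: messages classified
true whose publisher stayed below θ. Every run can write the filtered
corpus, the model (versioned JSON), an importance table (all nine features,
zero gain for unused ones) and a manifest (config hash + seed) for
auditability.

The ablation harness retrains the model across training fractions
(default 10%–80%) with and without {F1, F9}, optionally adding naive
Bayes / KNN / SVM reference classifiers from scikit-learn (comparison
oracles, not part of the method).

## Stage 2 — early-warning indicators

Per calendar day (the unit time), over the effective messages:

* **I1 volume change rate** Qr = (l₂ − l₁)/l₁ against the previous day's
  count; undefined (NaN + flag) on the first day or after an empty day.
* **I2 regional coverage** Ac = p_l/P: distinct provinces reached by the
  day's place mentions through a gazetteer, over P provincial regions
  (default 34); unmapped places are ignored with a warning.
* **I3 emotional tendency** Et: the arithmetic mean of the per-message
  emotional intensities (F5), so Et ∈ (0, 1) whenever intensities are.
  The mean — not a sum scaled by n — is the only reading consistent with
  a bounded tendency value.
* **I4 subject concentration** Tc = n/c, messages per topic cluster.
* **I5 new subjects** Nt: current clusters with low relevance to every
  cluster of the previous day.

### Adaptive topic clustering

Each message's subject list is its nouns. Pairwise message relevance is
the mean non-negative PMI over the cross product of two noun lists
(computed over distinct nouns weighted by multiplicity — identical to the
full cross-product mean, far cheaper on repetitive lists). The pairwise
matrix is scaled onto [0, 1] by its largest off-diagonal value, then
average-linkage agglomerative merging continues while linkage similarity
is ≥ τ (default 0.5), i.e. the dendrogram is cut at distance 1 − τ. The
cluster count *c* therefore emerges from the data.

Scaling by the maximum — rather than full min–max rescaling — is a
deliberate choice: min–max normalization of a window dominated by a single
topic stretches its internal sampling noise across the whole [0, 1] range,
so roughly half the pairs always fall below any mid-range τ and the window
shatters into artificial clusters, destroying the concentration signal.
Max-scaling preserves the *ratios* between pair relevances: a homogeneous
window stays one cluster, genuinely unrelated messages (no positive PMI)
stay apart, and a window with no positive relevance at all maps to
all-zero. Duplicate messages always merge at any τ ≤ 1.

New-subject detection compares cluster noun multisets across consecutive
windows with the same mean-positive-PMI relevance, normalized by the
largest cross-window value (identical windows score 1). A current cluster
is new when its best relevance to the previous window is < τ_new (default:
same as τ). On the first window every cluster counts as new.

Degenerate inputs: an empty window yields NaN concentration and zero new
subjects; windows must be strictly chronologically ordered; results are
invariant to message order within a window (messages are canonically
sorted before clustering).

## Synthetic data generator

Real crawled message corpora cannot be redistributed, so the generator
plants the statistical structure the method assumes, with symbolic tokens:

* **Corpus** (default 1000 messages, 30% false, 60 publishers, 9 days):
  true messages draw ~80% of their nouns from the epidemic vocabulary,
  carry a subject feature word with probability 0.7, average 7 clauses,
  effective-length ratio centred on 0.8 with overlapping Beta noise, and
  balanced clause polarity; false messages are shifted on every axis
  (45% epidemic nouns, feature word with probability 0.25, ~4.5 clauses,
  ratio centred on 0.6, polarity pulled 80% toward one pole) and come
  mostly from pseudonymous tier-1 publishers with thin history. The
  shifts overlap deliberately: the classes are separable at roughly the
  0.9 accuracy level, not trivially, so classifier comparisons have room
  to differ.
* **Link graph** (default 500 pages): sequential preferential attachment
  (targets chosen ∝ in-degree + 1, no self-links), giving hub pages
  above-uniform reliability.
* **Timeline** (default 20 days, 30 messages/day): one persistent topic is
  active every day; a novelty schedule (default alternating 0/4) injects
  brand-new topic vocabularies; a burst schedule multiplies daily counts.
  Each message draws nouns from its topic's vocabulary plus a small
  *common* background vocabulary — common words have near-zero PMI with
  everything, so they cannot fake topical relevance. Day-level sentiment
  means are controllable. This plants I1 spikes on burst days, I5 bursts
  on novelty days, and a strong negative I4/I5 rank correlation.

Everything is deterministic under the configured seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: natural language (tokens are symbolic, so there
is no segmentation or tagging noise), adversarial behaviour (misinformation
that mimics reliable style), platform dynamics (reposts, deletion,
publisher turnover), or realistic place-name ambiguity. Results on the
synthetic corpus demonstrate that the machinery recovers structure it is
told to expect, not field performance.

## Problem sizes and runtime choices

The test suite and the reproduction script run the full method at the
generator's default scales — 1000-message corpora, 500-page graphs,
20-day timelines — which exercise every code path in seconds on one CPU;
oracle comparisons (dense eigenvectors, brute-force split enumeration,
reference boosting) use ≤ 50-sample fixtures where exhaustive computation
is exact.

## Known limitations

* Source reliability assumes the link graph is honest; link farms defeat
  PageRank-style scoring.
* F9 elimination is irreversible within a run; a publisher wrongly flagged
  early loses all messages (θ trades this against speed of containment).
* PMI estimates are unstable for very rare words; the smoothing default
  only prevents infinities, it does not shrink estimates.
* Clustering is O(n²) in window size; daily windows beyond a few thousand
  messages need sampling.
* The annotator baseline is intentionally naive; feature quality on raw
  text is bounded by the annotations supplied.
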