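# Methods

## Problem and pipeline

Semi-structured interviews with older adults contain linguistic traces of
social isolation and loneliness (SI/L): lonelier speakers tend to use fewer
first-person-plural pronouns, more negative language, shorter responses, and
to mention fewer relationships. This package turns a directory of
interview transcripts plus a table of validated scale scores (UCLA-3
loneliness; MacArthur emotional support ESS-E, instrumental support ESS-I,
negative interactions ESS-NI; social support index SSI) into:

1. located responses to six template relationship questions (TF-IDF
   retrieval within each transcript),
2. a participant × feature table (POS profile, vocabulary richness, filled
   pauses, Yngve syntactic complexity, sentence similarity, sentiment
   aggregates, response length, pronoun densities, relationship and
   communication counts, sociodemographics),
3. a Gini-impurity feature ranking with incremental top-k selection, and
4. leave-one-subject-out (LOOCV) binary classification metrics
   (confusion matrix, sensitivity, specificity, support-weighted F1, ROC
   AUC) for a binarized target.

## Transcript dialect and localization

Transcripts are plain UTF-8 text: interviewer lines start with `Q`,
participant lines with `A` (also tolerating `Q:`/`Q.` transcriptionist
variants); unmarked lines continue the current turn. The continuation rule
and marker grammar are this package's conventions.

Within one transcript, each interviewer turn is a retrieval document.
Documents and the query template are vectorized with raw term frequency ×
smoothed inverse document frequency, idf(t) = ln((1+N)/(1+df(t))) + 1
(scikit-learn's smoothed variant), unnormalized; cosine similarity
normalizes at match time and a zero vector is assigned similarity 0.
Retrieval tokenization lowercases and strips punctuation but keeps stop
words — the templates are short and function words carry signal. Ties break
toward the earliest turn; matches below similarity 0.2 are flagged
low-confidence. The participant response is recovered positionally: all
participant turns strictly between the matched interviewer turn and the
next interviewer turn.

## Linguistic features

All linguistic features except pronoun densities are computed from the
concatenated responses to the six relationship questions; pronoun densities
are computed over the participant's speech in the *entire* interview (the
default modeling scope) and, additionally, over the relationship section.
Interviewer speech is never counted.

* **POS profile.** A deterministic dictionary tagger with suffix-rule
  fallbacks maps tokens onto 8 coarse classes (noun, verb, adjective,
  adverb, pronoun, interjection, filler, other); external taggers can plug
  in through a tagset-mapping adapter (a Penn-Treebank mapping ships with
  the package). Per tag we emit `freq_<tag>` = count/total tokens and
  `ratio_<tag>` = count/open-class tokens (non-"other") — the two
  normalizations are this package's convention — plus the pronoun:noun
  ratio.
* **Vocabulary richness.** TTR = V/N; Brunét W = N^(V^−0.165) (lower =
  richer); Honoré R = 100·ln N / (1 − V1/V) with V1 the hapax count. When
  V1 = V the denominator is floored at 1e-3 and the value flagged rather
  than raised — short responses make all-hapax spans routine.
* **Filled pauses.** Token (and token-n-gram, for multiword entries like
  "you know") matches against an editable filler lexicon, divided by total
  tokens.
* **Syntactic complexity.** Yngve depth: children of each constituent are
  indexed right-to-left from 0 and a word's depth is the sum of indices on
  its root-to-leaf path. Without a constituency parser configured, a
  deterministic right-branching binary tree is used, giving per-sentence
  depths [1,…,1,0]; this flattens absolute levels but preserves the
  length-driven component of the statistics. Aggregation: `yngve_mean` =
  mean over sentences of per-sentence mean depth, `yngve_total` = sum of
  per-sentence totals, `yngve_median` = median of per-sentence means.
* **Sentence similarity.** Cosine of raw term-count vectors over all
  unordered sentence pairs, aggregated as mean/median/SD/max. (A
  "frequency" aggregation sometimes listed for this family has no standard
  definition; only the four above are exposed.)
* **Sentiment.** An additive valence lexicon scorer: s = Σ valences maps to
  compound = s/√(s²+15); pos/neg/neu are normalized proportions of
  positive, negative and zero-valence token mass. Capitalization,
  punctuation and negation heuristics of full VADER-style scorers are
  deliberately out of scope. A compact conversational valence lexicon
  ships with the package and is replaceable by file path.
* **Response length.** Total/mean/minimum words and total/median characters
  over the six located responses.

Population (not sample) SD is used in every aggregate. Degenerate inputs
(no tokens, one sentence, empty responses) yield zeros plus an explicit
flag instead of errors.

## Social extraction

Pronoun densities count class members (first-singular I/me/my/mine,
first-plural we/our/us/ours, third he/she/they/them/their) divided by total
tokens; second person is excluded as interviewer-directed. Relationship
counts are pure dictionary lookups (word → category, e.g. husband→spouse)
with s-stripping plural folding and **no anaphora resolution** — "I have
children. A son and a daughter." counts 3 mentions in `children`, an
acknowledged overestimate that is part of the method's semantics.
Communication frequency takes the *maximum* contacts-per-month over matched
phrases ("every day"→30, "once a week"→4.33, …); modes are the union of
matched mode phrases; an unmatched frequency is reported missing (NaN, later
median-imputed), not zero. "Understood by no one" is detected when a
negation pattern ("no one", "nobody", "not really") matches a response
containing no relationship word.

## Modeling

Targets are binarized as score **strictly greater than** the cutoff: UCLA-3
uses the fixed cutoff 40 ("lonely"); support scales use the empirical
median (or 75th percentile) of the observed scores. Participants missing a
scale score are dropped for that target only.

Model families (scikit-learn): single-hidden-layer MLPs of 200 units
(logistic, tanh) or 100 units (ReLU) trained with Adam (max 1000 epochs,
tolerance 1e-4, fixed seed); RBF-kernel SVM (C=1, tol=0.001); kNN (k=9,
Chebyshev metric, distance weighting); decision tree (max depth 100, min
leaf 1); random forest (8 trees, 4 features per split, depth 7).

LOOCV fits on all-but-one participant with features z-scored using
training-fold statistics only (no leakage), predicts the held-out label and
decision score, aggregates one confusion matrix over folds and computes a
single AUC from the pooled decision scores. F1 is the support-weighted mean
of the two per-class F1 scores; sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP); AUC follows the all-pairs definition P(s⁺>s⁻) + ½P(tie),
implemented via midranks.

**Known biases, measured and documented.** Pooling raw decision scores
across LOOCV folds is pessimistic on null data (the held-out subject's
class is underrepresented in its training fold), by roughly 0.02–0.14 AUC
depending on the model family — smallest for the decision tree, largest for
the SVM. Score calibration against training-fold score distributions was
evaluated and rejected: with memorizing models it converts the same
imbalance into anti-conservative AUC. Conversely, ranking features by Gini
gain on the full table and then evaluating subsets of that frozen ranking
by LOOCV is *optimistic* on null data (selection bias of order +0.2 AUC at
n=40 with ~80 candidate features). Null-calibration checks therefore run
LOOCV without any selection step, with the tree family.

Gini ranking: gain = parent impurity (1 − p₀² − p₁²) minus the minimum
support-weighted child impurity over all single-threshold splits,
descending, ties alphabetical. (For a binary target the impurity maximum is
0.5.) Incremental selection evaluates top-1…top-k subsets and returns the
AUC-maximizing k, smaller k on ties.

## Cohort statistics

Cohen's d and the two-sample t operate on summary statistics (n, mean,
sample SD) with pooled variance, df = n₁+n₂−2 (not Welch); group 1 = women
by reporting convention. Mann-Whitney U (midrank ties, asymptotic p),
Spearman ρ and the 2×2 chi-square (continuity correction off) delegate to
scipy.

## Synthetic cohort generator

The generator emulates the study conditions so every stage is testable:
latent loneliness z ~ N(0,1) per participant; four response characteristics
set as base + scale·(β·z + noise_sd·ε), clipped; β defaults −0.5 (first-
person-plural rate), +0.5 (negative-sentence rate), −0.5 (words per
response), −0.5 (relationship mentions); noise_sd 0.5. UCLA =
round(40 + 10z + ε·4) clipped to [20,80], so the >40 cutoff splits default
cohorts roughly in half; ESS-E/ESS-I/SSI couple negatively and ESS-NI
positively to z. Default cohort size 97 with 65% women, mirroring the
target-study scale.

Realization in text (slotted sentence pools): the first-person-plural rate
is realized token-exactly by a whole-transcript quota over pronoun slots;
the negative rate by per-sentence Bernoulli choice among
negative/positive/neutral pools; response length with per-response
lognormal jitter (σ=0.45 — interview responses genuinely vary widely);
relationship mentions exactly, one lexicon word per relationship sentence.
Women draw higher Q4 communication-frequency phrases (design means ≈ 23.6
vs 8.0 contacts/month) and a slightly higher none-understood rate
(0.46 vs 0.352). The six template questions are embedded verbatim, in
order, among distractor questions.

What the generator does **not** emulate: real discourse structure, topic
drift, disfluent syntax, transcription errors, item-level scale responses,
or vocabulary differences beyond the configured effects. Passing tests
demonstrate that the pipeline recovers what the generator plants under its
linear-Gaussian couplings — not that the features detect loneliness in real
speech.

## Problem sizes used in the checks

Worked-example metrics are exact arithmetic on printed-style inputs.
Simulation suites use: 20 null cohorts of n=40 (tree LOOCV, no selection);
100 strong-signal cohorts of n=100 (|β|=1, noise 0.3) for Gini-rank
recovery and localization accuracy, with one ANN LOOCV run on the top-10
features; 10 default cohorts of n=97 pooled for the gendered
communication/none-understood rates. These sizes give sampling error well
inside the asserted bands while keeping the default suite quick.

## Limitations

* The packaged relationship/communication/filler/sentiment lexicons and the
  dictionary POS tagger are editable approximations, not validated
  clinical instruments; all are configuration, not ground truth.
* The right-branching fallback parse underestimates true syntactic
  complexity; plug in a constituency parser adapter for real analyses.
* LOOCV metrics on small cohorts carry the pooling and selection biases
  quantified above; the incremental-selection AUC curve is optimistic by
  construction.
* No anaphora resolution: relationship counts are mention counts, not
  distinct-person counts.
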