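# Methods

## Overview

`ftdsim` is a simulation framework for construct-validating NLP markers of
formal thought disorder (FTD). The logic is the reverse of the usual clinical
NLP study: instead of asking whether a metric correlates with diagnoses, we
*generate* narratives from a language model whose impairment is known —
because we injected it — and ask whether the metric recovers it. Two
theory-driven perturbations of autoregressive decoding stand in for two
candidate mechanisms of FTD:

* **temperature** *T* — next-token probabilities are flattened as
  *p'(w) ∝ p(w)^(1/T)*, modelling a generalized under-constraint of word
  selection (noisy retrieval from, or over-inclusive organization of,
  semantic memory);
* **memory span** *m* — only the last *m* tokens of the history are shown to
  the model at each step, modelling a specific impairment in maintaining
  global context.

The packaged metrics operationalize **derailment** as the cosine distance
(1 − cosine similarity) between embeddings of consecutive (or all pairs of)
words or sentences, and **tangentiality** as the ordinary-least-squares slope
of prompt-to-sentence distance over sentence index.

## Decoding model

One narrative is generated by iterating: truncate the history to the last
*m* tokens → propose `n_beams` candidate trajectories of `lookahead` tokens
each by ancestral sampling → commit the first token of the trajectory with
the highest joint probability under the processed per-step distributions.
Each per-step distribution is processed in the order **mask → temperature →
tail exclusion**:

1. tokens that would repeat an existing 2-gram, and tokens on the ban list
   (URL prefixes, newlines by default), are zeroed;
2. the remainder is flattened or sharpened by *T*;
3. the lowest-probability tokens whose cumulative mass is ≤ 1% are removed
   (nucleus rule with retained mass 0.99; a drop-lowest-fraction-by-count
   variant is available via `tail_mode="count"`), and the result is
   renormalized.

Masking first matches canonical decoder implementations (constraint logits
processors run before temperature/top-p warpers), keeps the ban absolute,
and gives the exact zero-temperature limit: as *T* → 0 generation coincides
with greedy argmax decoding of the constrained distribution. If the mask
removes every token, the step falls back to the unconstrained tempered
distribution and logs a warning — a deliberate totality escape that can, in
pathological vocabularies, emit a banned token rather than crash.

Randomness: each narrative has one seed; the generator for step *t* is
derived from `SeedSequence([seed, t])`, so narratives are bit-reproducible
and independent of the order in which a sweep generates them.

Defaults follow the simulated-narrative protocol: 200 tokens per narrative,
5 beams × 3-token lookahead, 1% tail exclusion, no-repeat-2-gram. Beams are
rebuilt from scratch each iteration and exactly one token is committed per
iteration (a literal reading of choosing "the next word" from the best
trajectory). Memory span counts backend tokens, not orthographic words,
because the truncated context is what the model actually consumes.

## Toy ground-truth backends

The pretrained-transformer adapter reproduces the original setting but is
optional; all tests and validation experiments run on two self-contained toy
backends whose ground truth is known by construction.

**Clustered bigram chain** (temperature ground truth). Word tokens are
partitioned into 4 clusters × 8 tokens. Conditional on emitting a word, a
fraction `within_mass` (default 0.9; the validation experiments use 0.95) of
the probability stays inside the current cluster; the full stop consumes a
fixed 0.08 per step and restarts the walk in a uniformly random cluster.
`within_mass` is defined *conditionally on emitting a word* so that sticky
clusters (`within_mass` up to 1) and a nonzero stop probability can coexist.
Raising *T* flattens each row toward uniform, mechanically increasing the
cross-cluster transition rate — and, under cluster-aligned embeddings, the
consecutive-word semantic distance. `within_mass ≤ 0.5` is rejected: without
sticky clusters the perturbation has no signal to recover.

**Topic-window model** (memory-span ground truth). Word tokens belong to 12
topics × 5 tokens arranged on a chain. At each step the model re-infers a
topic mixture from *only the visible window* (weights ∝ counts of visible
word tokens per topic), then samples from topic-conditional bigram tables
mixed by those weights. A `leakage` probability (0.25) draws instead from
the words of the *adjacent* topics on the chain, so off-topic material
enters locally rather than by teleport. Sentence stops occur at 0.05 per
step (mean sentence ≈ 20 tokens). Three design features produce the three
signature effects of bounded memory:

* *local drift:* with a short window a handful of leaked words flips the
  visible majority, so the topic random-walks along the chain — away from
  the prompt — at a rate that falls as the window grows;
* *chain geometry:* the fixture embedding centroids form a smooth chain
  (AR(1) on the sphere, lag-1 cosine ≈ 0.8), so the prompt distance grows
  gradually with the number of steps walked instead of saturating after one
  switch; this is what makes the tangentiality slope informative;
* *multi-topic prompts:* the canonical probe prompt contains 3 words from
  each of 4 topics. With full memory the window permanently retains this
  diverse topical core, so successive sentences keep sampling different
  facets of it (moderately distant from each other, but close to the prompt
  mean); with a window of roughly one sentence the model collapses onto
  paraphrasing the preceding sentence (minimal consecutive-sentence
  distance); with a 3–10-token window it loses even that and drifts.

The result is the characteristic dissociation: shrinking the span *lowers*
consecutive-word distance (word choice becomes hyper-local) while *raising*
tangentiality, and the consecutive-sentence distance is nonmonotone in span
(high at 3–10, lowest near 20, intermediate at 200).

Alternative drift mechanisms are available for experimentation
(`drift="uniform"`, a `drift_uniform_frac` blend, a count-based `novelty`
pressure, and `revisit` mass toward already-visited topics) but default off:
in our probes each of them traded one signature effect against another.

## Preprocessing

Narratives are split into sentences on full stops (runs of stops collapse to
one boundary; abbreviations are deliberately not protected — the rule is the
rule), contractions are expanded from a bundled ~50-entry table
(case-preserving on the first letter), and, for static-embedding analyses,
words are lowercased, stripped of punctuation, filtered (stop words from a
pinned ~130-word list, single letters, non-alphanumerics) and lemmatized.
The default lemmatizer is a bundled dictionary (~230 common English forms,
chains resolved to idempotence at load); a spaCy adapter exists behind the
optional `nlp` extra. The stop list and lemmatizer inventory are
configuration: results that depend on them are configuration-sensitive, which
is why both ship pinned.

Filters are re-applied after lemmatization so that no output word is ever a
stop word or single letter, keeping the pipeline idempotent.

## Embeddings and encoders

Static tables load from the word2vec text format (the export format shared
by published word2vec, GloVe and fastText vectors). Lookups are exact and
lowercase; out-of-vocabulary words are skipped silently but counted, and the
per-narrative OOV rate is reported alongside the metrics. No subword
composition is attempted.

Two deterministic constructions substitute for pretrained resources in
tests and validation: the cluster-aligned fixture table described above, and
a hashing sentence encoder that sums fixed pseudo-random directions for each
word and adjacent word pair (unit-normalized, derived from cryptographic
hashes, independent of the process hash seed). The encoder satisfies the
contextual-encoder contract — deterministic, fixed dimension, order-aware —
while its distances reflect lexical overlap; real contextualized encoders
are reachable through the optional `sentence-transformers` adapter.

## Metrics

All distances are cosine distances in [0, 2]. Word-level series come in
consecutive and all-pairs variants; because the all-pairs scope is ambiguous
in common usage, both the whole-narrative and within-sentence scopes are
implemented (`scope="narrative"` default, `"sentence"` optional) and
reported separately. Sentence-level series use three encodings: mean of
static word vectors, relaxed word mover's distance, and the contextual
encoder. The relaxed WMD is the nearest-neighbour formulation — for each
word in one sentence, the cosine distance to its closest word in the other,
averaged per direction and symmetrized by averaging the two directions. A
full optimal-transport WMD (uniform weights, solved as a transportation LP)
is provided as a cross-check; each relaxed direction lower-bounds it.

Shared-word exclusion (dropping words present in both members of a sentence
pair, per pair, before encoding) is on by default so the measures reflect
semantics rather than verbatim repetition. Degenerate pairs — empty after
exclusion, all-OOV, or with a zero mean vector — are skipped and counted,
never imputed. Each series is summarized by mean, minimum, maximum and
unbiased (n−1) sample variance; empty series and length-1 variances are
undefined markers, not zeros.

Tangentiality encodes the full prompt as one unit (it is the topic
referent), computes d_k to each sentence k, and fits the OLS slope of d_k on
k; skipped sentences keep their index so the regression is not distorted.
Both the static-mean and contextual variants are computed when both
resources are supplied.

## Sensitivity analyses

Sweeps follow the two-sweep protocol: temperature over its grid with span
fixed at 200, and span over {3, 5, 7, 10, 15, 20, 30, 50, 100, 200} with
temperature fixed at 1 (grid spacing within the stated ranges is otherwise
a free choice and is configurable). The headline R for each metric is the
unweighted mean of per-(prompt × encoding) Spearman correlations — matching
the convention of averaging effect sizes over prompts and models — with
per-prompt and per-encoder breakdowns retained for consistency inspection.
Memory span is sign-reversed before correlating so that FTD-consistent
effects are positive for both parameters; the reversal is exact
(R_reversed = −R_raw). Rp residualizes the *parameter* on mean words per
sentence by OLS and correlates the residuals with the metric; a
metric-residualizing variant was considered and rejected as the default
because the confound mechanically contaminates the metric, not the
parameter. Statistical significance is deliberately not computed: with
simulated data the p-value is a function of how many narratives one chooses
to generate.

`binned_profile` reports per-bin means with counts (empty bins are marked,
never interpolated) for nonmonotonicity inspection; `compare_aggregations`
reports |R| per aggregation method with the interquartile range across
(prompt × encoding × level) strata as the consistency band.

## Validation experiments and their problem sizes

`ftdsim.validation` packages the study conditions: temperature recovery
(clustered bigram, within-mass 0.95, temperatures {0.5, 1, 2, 3, 5}, 100
narratives × 200 tokens per cell) and memory-span recovery (topic-window
backend, spans {3, 10, 20, 50, 200}, 100 narratives per cell), each judged
over 20 replicates; the sentence-length confound (500 sentence pairs
sharing a 2-word topical core plus isotropic fillers, 5 vs 20 words); and a
residualization-attenuation check. These sizes keep a full validation run in
minutes on one CPU while leaving the stochastic directional effects many
standard errors wide. The experiments pin one canonical backend and fixture
table (as a study pins one pretrained model); replicate seeds drive only the
generation randomness. The validation sweeps commit one token per step
without beam lookahead — the beam machinery is validated separately by the
decoding invariants — because the recovery claims concern the perturbations,
not the beam heuristic.

Shared-word exclusion is disabled *within the toy validation sweeps*: with a
60-word closed vocabulary, adjacent sentences overlap structurally and
per-pair exclusion would mostly measure vocabulary size. On real text with
open vocabularies the default (exclusion on) stands.

## What the toy conditions do and do not show

Passing these experiments demonstrates that the pipeline — decoding,
preprocessing, embedding, metrics, correlation machinery — faithfully
transmits known perturbations into the metrics that theory says should
detect them, and reproduces the qualitative dissociations (word-level
distance rises with temperature but falls with truncated memory;
tangentiality responds to memory span specifically; the span effect on
sentence distance is nonmonotone). It does not show that the same effect
sizes hold for a pretrained transformer with published embeddings, nor
anything about clinical populations: toy vocabularies are tiny and closed,
the hashing encoder sees lexical overlap rather than meaning, and simulated
narratives contain no disfluencies, interviewer turns, or ASR noise. A
reduced pretrained-model replication is reachable with the optional extras
(`TransformerBackend`, `SentenceTransformerEncoder`) but requires weight
downloads and hours of CPU.

## Numerical choices

Temperature scaling runs in log space (stable down to T = 1e-6). Tail
exclusion sorts ascending with a stable sort, so ties are resolved by
vocabulary order, deterministically. Cosine distances are clipped to [0, 2]
against floating-point excursions; zero-norm vectors raise a dedicated
degenerate-input error, and callers decide whether a pair is skipped (series
construction) or the failure propagates (direct calls). Sampling uses
inverse-CDF on the cumulative sum, which keeps draws reproducible across
platforms for a fixed generator stream. Seeds derived from user seeds are
reduced modulo 2^31.
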