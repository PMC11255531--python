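# Methods

## Pipeline model

The unit of analysis is the **victim**, not the article. Corpus ingestion
applies a keyword inclusion filter and labelled exclusion rules (homicide-
suicide, bombings, attempts, euphemisms, fiction), then resolves annotated
articles into victim records: annotations sharing one gender collapse to a
single record carrying the union of circumstances and the full article text;
mixed-gender articles are split per annotation, each annotation contributing
its 0-based half-open character span as the record's text. An article is
excluded under the *first* matching rule in rule order, so the exclusion
report partitions the input exactly (|included| + Σ counts = |input|).

Each frame (stigma, glorification, isolation) is a lexicon: seed descriptors,
optionally expanded through a synonym source and pruned by coder decisions.
Seeds are never pruned; the default pruning policy is `unanimous_remove`
(every coder must vote remove), the conservative choice when the adjudication
rule between two coders is not otherwise specified; `any_remove` is
available. The synonym source is a protocol: a static table (dict or CSV) is
the deterministic default, and a WordNet adapter (optional `nltk` extra)
collects single- and multi-word lemmas across the noun, verb, adjective and
adverb synsets, with underscore-joined lemmas normalised to spaced phrases.
Expansion order is deterministic (seeds in input order, then each seed's
synonyms lexicographically) so lexicon builds are reproducible.

A frame vector is the unweighted arithmetic mean of the expanded terms'
embeddings; an article vector is the unweighted mean of its sentence
embeddings (rule-based splitter on terminal punctuation with abbreviation
and single-initial guards). Mean-over-sentences is our documented choice of
article pooling; terms are embedded as bare strings without a carrier
sentence. Vectors are *not* normalised before averaging — cosine scoring is
scale-invariant afterwards, and normalising term vectors first would
silently reweight short vs long phrases. Sentence vectors are summed in a
canonical (byte-sorted) order so the article vector is bitwise invariant to
sentence permutation despite float non-associativity.

The framing score is cosine similarity, clamped to [−1, 1] purely against
floating-point drift; zero vectors and dimension mismatches are errors, not
silent zeros. Scoring produces the complete victims × frames grid.

## Embedding backends

`HashEmbedder(dimension, seed)` maps each lowercase token through a keyed
BLAKE2 hash to a seeded Gaussian direction, normalised to unit length; a
string embeds as the mean of its token vectors. It is deterministic across
processes, needs no model download, and gives near-orthogonal embeddings to
disjoint vocabularies (E[cos] = 0, sd ≈ D^(−1/2)), which is what makes the
synthetic experiments interpretable: the injection rate of a frame's tokens
directly controls expected cosine alignment with that frame's centroid. It
is a *simulation* backend: it captures lexical overlap in expectation but no
semantics — synonyms are as orthogonal as unrelated words — so passing tests
with it validates the pipeline's statistics, not the linguistic quality of
any particular embedding model. `TransformerEmbedder` (optional extra) wraps
a sentence-transformers checkpoint with mean pooling behind the same
contract for real-text analyses; no single public checkpoint is canonical
for this task, so the name is configurable.

## Statistics

**Mann-Whitney U.** U is computed from midranks (U_a = R_a − n_a(n_a+1)/2),
so ties are handled; the two-sided p-value uses exact enumeration when the
samples are tie-free and n_a·n_b ≤ 400 (exhaustively checked against a
permutation oracle in the tests), otherwise the normal approximation with
tie correction and continuity correction. The p-value computation is
delegated to `scipy.stats.mannwhitneyu` with the method chosen by that rule.
No multiple-testing correction is applied; raw p-values are reported.

**Mutual information.** I(G;S) between the binary group label G and the
binned score S uses the plug-in estimator: both samples pooled, shared
equal-width bins over the pooled range (default 10; a Freedman–Diaconis
option exists), joint cell frequencies substituted into
Σ p(g,s) log₂[p(g,s)/(p(g)p(s))], zero cells skipped (0·log 0 = 0). Values
are in bits; for binary G, 0 ≤ I ≤ 1, with 0 iff the binned distributions
coincide and 1 for perfectly separated equal-size groups. **Directionality
convention:** in this package larger MI always means *more divergent*
gender-conditional score distributions. Some of the applied literature
describes MI verbally with the opposite polarity while still ranking low
values as "least similar"; we do not attempt to reproduce any such
estimator's exact values and state our convention in every output header.
Whether previously published circumstance-level MI tables are in bits or
nats is not stated in that literature; ours are bits. Constant pooled scores
(zero range) return MI = 0 with a warning rather than an error.

The plug-in estimator is biased upward in small samples by approximately
(K−1)/(2N ln 2) bits for K occupied bins and N pooled observations. This
matters when comparing MI *across* strata of different sizes: a small
stratum can out-score a genuinely divergent large one on bias alone. The
stratified matrix therefore reports each cell's group sizes, and the
replicated localisation experiment (below) equalises stratum sizes by
design.

**Cohen κ** = (p_o − p_e)/(1 − p_e) with p_e from the product of marginal
label frequencies; two constant, identical coders (p_e = 1 with perfect
agreement) define κ = 1. **Count table:** a victim with k circumstances
contributes k attribution counts; row totals sum the listed circumstances;
percentages are 100·count/total rounded half-up to one decimal (decimal
arithmetic, not banker's rounding).

Stratified MI assigns a multi-circumstance victim to every matching stratum,
since several circumstances can be attributed to a single death. The default
gender contrast is cisgender male vs cisgender female — other identities are
retained in score tables but excluded from the two-group tests, where they
are typically far too few to compare — and the pair is configurable.

## Synthetic corpus generator

The generator emulates an annotated news corpus with controllable framing
structure. Each victim receives a gender (default counts 153 male : 64
female, the observed mix in the annotated-corpus setting this generator
stands in for), one circumstance sampled from a per-gender distribution
(default proportional to the observed per-gender attribution counts), and
with probability 0.08 a second circumstance (matching the observed ~234
attributions over ~217 decedents). Article text is 4–10 sentences of 8–20
tokens from a 500-token synthetic background vocabulary ("tok0042"), with
frame-lexicon tokens injected i.i.d. per token at a rate keyed by
(gender, circumstance, frame), wildcard `*` for circumstance-independent
rates; for a multi-circumstance victim the maximum matching rate applies.
Background and frame vocabularies must be disjoint (enforced) so injection
is the only channel linking text to frames. Generation is deterministic per
seed, byte-identical across runs, and returns realized injection rates as
ground truth.

`synthetic_lexicons(n_terms=60)` provides the generator's companion frame
lexicons: 60 synthetic tokens per frame, emulating a scale of roughly 20
descriptors per dimension after synonym expansion. The size is load-bearing:
with a k-term frame vocabulary, tokens injected for one frame perturb
*another* frame's cosine score by ≈ Δr·√(T_eff/k) standard deviations of the
per-article noise (Δr the injection-rate contrast, T_eff the effective token
count per article), because a small lexicon's centroid has a non-negligible
random cosine to the other centroids. A degenerate 3-word lexicon therefore
produces spurious "significant" differences on uninjected frames; at k = 60
the leakage is well below detection at the default sample sizes.

What the generator deliberately does **not** model: real lexical semantics
(hash embeddings have none), publisher/date effects, non-English text,
discourse structure, or annotation noise. Passing the synthetic experiments
shows the estimators recover known effects through the full pipeline; it
does not validate any claim about real news language, which additionally
depends on the embedding model and lexicon quality.

## Replicated validation experiments

Two experiments (module `newsframing.experiments`) state the package's
recovery guarantees; both use the hash backend at D = 256 and 20 seeded
replicates, with every replicate's generator and backend seeded from the
replicate index.

1. *Gender contrast:* stigma injection 0.15 (male) vs 0.05 (female),
   n = 100 victims per gender, other frames uninjected. The stigma frame's
   Mann-Whitney p is < 0.01 in ≥ 19/20 replicates; each uninjected frame has
   p > 0.05 in ≥ 15/20.
2. *MI localisation:* the same contrast injected only for victims annotated
   with one target circumstance, uniform circumstance distribution and
   n = 200 per gender so that every stratum has ≈ 55 victims per gender and
   the plug-in bias (≈ 0.06 bits) is common across cells rather than
   favouring small strata. The target circumstance's MI cell is the column
   maximum in ≥ 18/20 replicates. Under the skewed default circumstance mix
   at n = 100 this localisation is *not* reliable — the smallest stratum
   (~11 pooled observations) carries ~0.6 bits of pure bias — which is
   precisely the cross-stratum comparability caveat documented above.

## Numerical and degenerate-input conventions

- Spans: 0-based, half-open, validated against text length; mixed-gender
  resolution without spans is an instructive error.
- Duplicate article ids, malformed JSONL lines (named by line number),
  missing coder decisions (named by term) and empty include-keyword lists
  are errors; an empty corpus file and unmatched annotations are warnings.
- Exact-vs-asymptotic rank-test switch at n_a·n_b = 400; documented, and the
  oracle agreement is tested on the exact side only (the asymptotic side is
  an approximation by construction).
- MI bins span the pooled min–max; scores identical across the pool short-
  circuit to MI 0. MI is invariant to affine rescaling of scores (bin
  assignments preserved), which is tested.
- All randomness flows from explicit integer seeds; derived seeds stay
  below 2³¹.

## Known limitations

- The shipped seed lexicons are the three published example descriptors per
  dimension, not the full 80-descriptor instrument; real analyses should
  supply the full list. The default keyword filter list is likewise a small
  illustrative set, not a curated public-health keyword inventory.
- The plug-in MI estimator is not debiased; cross-stratum comparisons of
  unequal-size strata conflate bias with divergence (reported group sizes
  allow readers to judge).
- Rule-based sentence splitting will occasionally split abbreviations it
  does not know; the splitter is injectable.
- p-values are reported uncorrected across the three frames.
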