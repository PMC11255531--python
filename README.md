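# newsframing

Tools for measuring how news reports of suicide are *framed* — with
stigmatizing, glorifying, or isolation/depression language — and whether that
framing differs by the decedent's gender and by the circumstance attributed to
the death.

Unsafe media reporting is a known suicide risk factor, and reporting
guidelines mostly target explicit content (method, location). Attitudinal
framing is subtler: the Stigma of Suicide Scale (SOSS) defines stigma
("shallow", "pathetic", "immoral"), glorification/normalization
("understandable", "brave", "motivated") and isolation/depression ("unhappy",
"depressed", "sad") as one-word descriptors of people who die by suicide.
This package operationalizes those dimensions as *frame lexicons*, embeds
them and the article text in a common vector space, and quantifies alignment
and group differences. It is aimed at public-health and computational social
science researchers analyzing news corpora with victim-level annotations
(gender, circumstance of death).

## Method

For each SOSS dimension *d* with expanded lexicon terms
*w*₁…*w*ₖ, the frame vector is the unweighted mean of term embeddings,
**f**_d = (1/k) Σᵢ **e**(wᵢ). Each article is split into sentences
*s*₁…*s*ₘ and represented as the mean sentence embedding
**a** = (1/m) Σⱼ **e**(sⱼ). The framing score of a victim's text against
dimension *d* is the cosine similarity

> score(a, d) = **a**·**f**_d / (‖**a**‖‖**f**_d‖) ∈ [−1, 1],

computed per *victim*: an article reporting several same-gender deaths is one
record with the full text; mixed-gender articles are split by annotated
character spans.

The statistical layer then compares score distributions:

- **Mann-Whitney U** (two-sided; exact when tie-free and n₁·n₂ ≤ 400,
  otherwise normal approximation with tie and continuity corrections) for the
  overall male/female contrast per frame;
- **Mutual information** I(G;S) in bits between gender G and the binned
  score S (plug-in estimator over 10 shared equal-width bins spanning the
  pooled range), computed per circumstance stratum to localize *where* the
  gender difference is concentrated. Higher MI = more divergent
  gender-conditional score distributions (see `docs/methods.md` for the
  directionality convention);
- **Cohen κ** for inter-rater reliability of annotations, and a
  gender × circumstance attribution count table with one-decimal
  percentages.

Embeddings are pluggable. The default `hash` backend maps each token to a
deterministic unit vector (seeded hash), so disjoint vocabularies are
near-orthogonal and the whole pipeline is testable offline with known ground
truth; a sentence-transformer adapter (`pip install newsframing[transformer]`)
provides contextual embeddings for real text. Lexicon expansion likewise
accepts any synonym source; a WordNet adapter is available via
`pip install newsframing[wordnet]`.

## Worked example

Generate a synthetic corpus in which male-victim articles contain
stigma-lexicon tokens at rate 0.15 vs 0.05 for female-victim articles
(the other frames uninjected), score it, and test for the contrast:

```python
from newsframing import (SyntheticSpec, generate_corpus, resolve_corpus,
                         make_backend, frame_vectors, score_corpus,
                         compare_by_gender, stratified_mi)
from newsframing.synthetic import synthetic_lexicons

spec = SyntheticSpec(n_victims={"cis_male": 100, "cis_female": 100}, seed=7)
lexicons = synthetic_lexicons()
articles, annotations, truth = generate_corpus(spec, lexicons)

backend = make_backend("hash", dimension=256, seed=7)
victims = resolve_corpus(articles, annotations)
scores = score_corpus(victims, frame_vectors(lexicons, backend), backend)

for c in compare_by_gender(scores, ["stigma", "glorification", "isolation"]):
    print(f"{c.frame:14s} mean M={c.mean_a:+.3f} F={c.mean_b:+.3f} "
          f"U={c.U:7.1f} p={c.p:.2e}")
```

prints

```
stigma         mean M=+0.174 F=+0.057 U= 8872.0 p=3.09e-21
glorification  mean M=+0.039 F=+0.051 U= 4392.0 p=1.38e-01
isolation      mean M=-0.009 F=+0.007 U= 4239.0 p=6.31e-02
```

The injected stigma contrast is recovered decisively (mean male score 0.174
vs 0.057, p ≈ 10⁻²¹) while the two uninjected frames show no significant
difference — the null frames stay null. `stratified_mi(scores, ...)` then
breaks the contrast down by circumstance, returning the circumstance × frame
MI matrix.

The same pipeline runs from the shell:

```bash
newsframing synth --seed 7 --out data/
newsframing score --corpus data/corpus.jsonl --annotations data/annotations.csv \
    --lexicons data/lexicons.csv --out scores.csv --seed 7
newsframing compare --scores scores.csv
newsframing mi --scores scores.csv --bins 10 --out mi_matrix.csv
newsframing table1 --annotations data/annotations.csv
newsframing run --config config.yaml   # all stages, five output files
```

For real corpora, supply the JSONL articles, the annotation CSV
(`article_id,victim_id,gender,circumstances,span_start,span_end`), a YAML
keyword filter rule set, and a lexicon CSV (`frame,term,role`) built from the
full SOSS word list — the package ships only the nine example seed words, not
the full 80-descriptor instrument.

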