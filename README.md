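# aluhsf

Heat shock factor (HSF) binding sites inside Alu repeats: a tested pipeline
for motif-model scanning, strand-aware site classification, density
statistics, repeat-consensus positional mapping, and antisense-transcript
proximity analysis.

## The problem

Alu elements — the ~300-bp primate SINE retrotransposons that make up over a
tenth of the human genome — carry transcription factor binding sites, among
them a 13-bp variant of the heat shock element with the degenerate consensus
`nCAGAAAGCTCCG`. Genome-wide, these Alu-internal HSF sites are distributed
non-randomly: they accumulate in heat-shock-responsive transcripts, they
cluster at preferred positions on the Alu consensus (221 in both
orientations, 175 only in sense copies, 91 only in antisense copies), and
they are strongly over-represented in Alus lying *antisense* to their host
transcript — roughly 4 % of sense Alus versus nearly 21 % of antisense Alus
harbor a site. Antisense-oriented sites in down-regulated genes sit close
(within 5 kb, typically ~2 kb) to antisense transcription signals,
suggesting HSF-driven antisense transcription as a down-regulation
mechanism under heat stress.

`aluhsf` implements the computational side of this analysis for anyone who
wants to reproduce, probe, or extend it: regulatory genomicists working on
transposable-element-derived binding sites, and method developers who need a
fully synthetic, truth-tabled test bed for strand-aware motif/repeat
pipelines.

## The model

A site is scored by a position weight matrix over the 13 columns: for a
window $w$, the score in bits is

$$S(w) = \sum_{j=1}^{13} \log_2 \frac{f_j(w_j)}{b(w_j)},$$

with column frequencies $f_j$ (pseudocount-smoothed) and background $b$
(uniform by default). Windows on both strands scoring at least **8.7 bits**
are reported — the working threshold sits just below the 8.9 bits of a
documented HSPA1A promoter site. Motif discovery is a classic Gibbs site
sampler (one site per sequence, leave-one-out resampling, phase-shift
moves). Each in-Alu hit is projected onto its subfamily consensus via
Smith–Waterman local alignment with affine gaps, giving the 1-based
consensus position. Densities are counts/kb (upstream 5 kb) or counts/10 kb
(genic), compared between expression classes with two-tailed Welch t-tests.
Antisense probe signals with detection p < 0.05 are related to the nearest
HSF site in an antisense-oriented Alu of the same gene, with a 5-kb
proximity rule and sides labelled in the antisense transcript's frame.

A seeded synthetic-data generator (`aluhsf.synthetic`) plants all of this
structure — class-dependent Alu rates, orientation-biased motif planting at
positions 221/175/91, probe signals 2 kb from planted antisense sites — and
records every planted site in a truth table, so the whole pipeline is
testable end to end without downloads.

## Worked example

The orientation-bias summary applied to the published genome-scale counts
(bundled as `REFERENCE_ORIENTATION_COUNTS`):

```bash
$ aluhsf summarize-orientation
expression_class region_kind  n_sense_alus  n_antisense_alus  n_hits_in_sense_alus  n_hits_in_antisense_alus sense_pct antisense_pct fold
              up upstream5kb          2301              2393                   112                       481      4.87         20.10 4.13
              up       genic         14580             17507                   632                      3629      4.33         20.73 4.78
            down upstream5kb          6244              7187                   268                      1512      4.29         21.04 4.90
            down       genic         47295             63323                  1961                     13092      4.15         20.67 4.99
aggregate: sense 4.22%  antisense 20.70%  fold 4.90
```

`sense_pct` is the site load — HSF site occurrences per 100 Alus of that
orientation. The aggregate row is the reported contrast: 4.22 % of sense-Alu
load versus 20.70 % antisense (the "approximately 4 %" vs "nearly 21 %"),
a 4.9-fold aggregate bias with per-row folds of 4.1–5.0.

An end-to-end run on self-generated synthetic data:

```bash
$ aluhsf run-all --synthetic --seed 0 --out-dir out/
genes: 240   hosted Alus: 2343   HSF site occurrences: 3379
site load: 8.47 per 100 sense Alus, 25.13 per 100 antisense Alus (fold 2.97)
antisense signals detected: 62; proximal (<= 5000 bp): 62 (54 upstream of the antisense transcript, 8 downstream)
```

`out/` then holds every stage table: classified hits, per-gene site
categories, orientation counts and bias, densities and Welch comparisons,
consensus-position mappings and their histogram (modes 175/221 sense and
91/221 antisense on the planted data), proximity records, and a
`manifest.json` recording the seed and parameters. Identical seeds give
byte-identical outputs.

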