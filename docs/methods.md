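# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices behind `aluhsf`, in enough detail to judge what a passing
test suite does and does not establish.

## Motif model and scanning

The HSF element is modelled as a 13-column position weight matrix.
Frequencies are `(count + q) / (n + 4q)` with pseudocount `q = 0.25` per
base (avoids minus-infinity log-odds on small site sets); scores are summed
`log2(frequency / background)` in bits against a uniform background
(0.25 each — scores then do not depend on the composition of the scanned
input; estimating the background from data is available but not the
default). The built-in model is constructed from the four first-base
variants of the degenerate consensus `nCAGAAAGCTCCG`: column 1 is flat
(contributes ~0 bits) and each of the twelve core columns contributes
+1.77 bits on match and −2.32 on mismatch, so a perfect core scores
21.2 bits and each mismatch costs ~4.1 bits.

The scanning threshold defaults to 8.7 bits, calibrated in the original
analysis so that a documented HSPA1A promoter site (8.9 bits) is retained.
Under the built-in matrix this admits words up to three core mismatches —
the divergence tolerance with which old Alu copies retain the element. The
exact matrix behind the original threshold was never published, so both the
matrix and the threshold are configurable; the defaults are honoured as
stated, not re-derived. Windows containing an ambiguous base are skipped by
default (`n_policy="skip"`): no score is fabricated for unsequenced bases.
Minus-strand hits are reported in plus-strand coordinates of the scanned
region with the matched word read on the hit strand, and overlapping hits
are all retained — the analysis counts site occurrences, and any pruning
would silently change the downstream count tables.

## Gibbs site sampler

Motif discovery is the classic one-site-per-sequence Gibbs sampler: hold
one sequence out, build the matrix from the other sites, resample the
held-out site with probability proportional to `2^score`. Two departures
from the textbook loop matter in practice. First, sequences are visited in
a deterministic sweep rather than at random, which guarantees coverage in
short runs. Second, after every sweep a greedy phase-shift move slides the
entire alignment by ±1–2 columns when that raises the information content;
without it the sampler frequently locks into an off-by-one register.
Restarts (default 25 × 500 iterations) are scored by information content
and the best alignment is returned. All randomness flows through one seeded
generator, so results are reproducible.

## Synthetic data

The generator builds one contig per gene — 5-kb pad, genic body, 5-kb pad —
which removes all inter-gene interval ambiguity from tests. Per region,
Alu insertion counts are Poisson at a per-kilobase class rate; each
insertion is a mutated copy of a bundled 300-base toy consensus placed
uniformly without overlaps (placements still colliding after 50 draws are
dropped; at the default rates occupancy is low and the loss is negligible,
as the rate-recovery test confirms).

Defaults encode the study conditions the analysis targets:

| parameter | default | rationale |
|---|---|---|
| genes per class | 60 each (up/down/unchanged/random) | desk-scale yet enough Alus for stable tables |
| gene length | 10–30 kb uniform | typical human gene bodies |
| Alu rate /kb | down 0.6, up 0.4, unchanged/random 0.3 | genome-wide Alu density is ~0.35/kb; down:up = 1.5 gives the enrichment direction of the published density table |
| plant probability | sense 0.04, antisense 0.21 | the reported per-Alu site fractions |
| plant positions | sense {221, 175}, antisense {221, 91} | the three preferred consensus positions |
| substitution / indel rate | 0.05 / 0.005 per base | Alu subfamily divergence scale |
| background GC | 0.41 | human genome average |
| antisense signal offset | 2 kb | observed enrichment distance of antisense signals |

The planted 13-mer is the degenerate consensus with its first base drawn
uniformly per instance, so a recovered model reproduces the `n` column.
Planted windows are protected from mutation by default, making
positional-recovery expectations deterministic; indels elsewhere shift the
motif's genomic offset, and the truth table records the *realised*
coordinates, orientation, and consensus position of every instance. For
down-regulated genes, each planted genic antisense site emits a 100-base
probe signal 2 kb away on the antisense transcript's downstream side
(lower coordinates for a `+` host), with detection p < 0.02; a fraction of
down genes (10 %) also emit a non-significant decoy probe to exercise the
detection filter. Signals that would fall outside the genic region are not
emitted.

The toy consensus is not a RepBase sequence. It is a fixed GC-rich
pseudo-random body with an A-box/B-box-like interior and poly-A tail,
constructed with two properties: (i) no window on either strand comes
within four substitutions of the motif, so unplanted copies are silent
under the default threshold; (ii) at positions 221, 175 and 91 the
consensus shares five scattered bases with the motif core. The second
property mirrors reality — the heat shock element derives from Alu sequence
itself — and is what anchors local alignments of planted copies in the
correct register; without it, the planted block is entirely foreign to the
consensus and optimal alignments jitter by a few columns around it.

What the generator does **not** emulate: truncated or partially deleted Alu
insertions (all copies are full-length), retrotransposition phylogeny and
subfamily structure (one toy subfamily), array probe-level noise and
normalisation, chromosome-scale linkage between genes, and non-uniform
background composition (no CpG islands, no repeats other than the planted
Alus). Passing tests therefore certify the *bookkeeping* — coordinates,
strands, orientation classes, density normalisations, alignment projection
— and the statistical power under idealised noise, not performance on real
genomes.

## Classification and counting

A hit belongs to an Alu iff its midpoint lies inside the Alu interval
(half-open), so a 13-mer straddling an edge receives one deterministic
label; among overlapping Alus containing the midpoint, the larger overlap
with the hit wins, ties to the smaller start. Alus are attached to the
gene region containing *their* midpoint, and an Alu whose midpoint falls in
regions of two genes is counted once per host — the counting frame is
per-transcript. Orientation tables count site occurrences (matching the
published table headers) and additionally report Alus-with-at-least-one-site,
since per-Alu phrasing ("4 % of sense Alus harbor a site") reads
differently from occurrence counts; on the published counts the occurrence
ratio reproduces the printed percentages, which is why the occurrence view
feeds the summary.

## Densities and tests

Densities are per gene region: counts/kb upstream, counts/10 kb genic (the
scaling that makes the much longer genic stretches comparable to the 5-kb
windows). The gene is the sampling unit; classes are compared with
two-tailed Welch t-tests — the unequal-variance form is the safer reading
of an unspecified two-sample t-test, and the pooled form is a flag away.
Raw p-values are reported (the original tables are uncorrected);
Benjamini–Hochberg is optional.

## Positional mapping

Alu copies are aligned to their subfamily consensus by Smith–Waterman with
affine gaps (match +2, mismatch −3, gap open −8, extend −1; the first gap
base costs the open score). The traceback is fully deterministic: among
equal-scoring end cells the smallest subject offset wins, then the smallest
query offset; at equal predecessor scores diagonal beats up beats left.
Minus-strand copies are reverse-complemented before alignment so every
alignment runs consensus-forward and both orientations share one coordinate
frame. A hit's first base is converted to a copy-local offset (measured
from the 3′ genomic end for minus-strand copies) and read off the alignment
columns, 1-based; if that base sits in a gapped stretch the nearest aligned
column to the right is used, with `mapped_fraction` recording coverage.
Hits that straddle an Alu edge have no complete consensus image and are
excluded from mapping. Modal positions are local maxima of the per-
orientation position histogram; the pipeline calls modes with a floor of
10 % of the orientation's mappings, which reports the planted preferred
positions and ignores isolated stray mappings from doubly-mutated
near-windows.

## Proximity

Gaps are edge-to-edge between half-open intervals, zero on overlap — the
natural reading of a "5-kb flanking region". Sides are labelled in the
antisense transcript's frame (it runs opposite the host gene): for a `+`
host, a site at higher coordinates than the signal is upstream of the
antisense transcript. The host-gene frame is available behind a flag, since
the original description never states the frame explicitly; the antisense
frame is the one in which the mechanistic model (HSF driving antisense
transcription toward the promoter) is coherent. Overlapping site/signal
pairs are sided by midpoint comparison, ties upstream. The detection filter
is strict (`p < alpha`, default 0.05).

## Acceptance sizes and determinism

The acceptance checks run at: 100 random kilobases for the
scanner-vs-enumeration identity; 50 seeded trials of 20 × 200-base
sequences for Gibbs recovery (5 % within-site divergence, Hamming ≤ 1);
the default 240-gene dataset at 2 % divergence for positional recovery;
100 seeded runs of 300 genes per class for the density-comparison power
(computed on the generator's annotation layer — gene lengths and Poisson
Alu counts — without materialising sequence, which is exactly the data the
density statistic consumes); and a 120-gene divergence-free dataset for
classification exactness, scanned at a stringent 18-bit threshold so the
hit set coincides with the planted set (planted words score 21.2 bits;
the classifier under test is threshold-agnostic). Every stage, including
the pipeline itself, is a pure function of (inputs, configuration, seed),
and identical seeds give byte-identical output files.

## Known limitations

* The original position weight matrix and its training sites are
  unpublished; the 8.7/8.9 values are honoured as defaults but cannot be
  re-derived, and scores from the built-in matrix are not numerically
  comparable to the original tool's.
* RepBase subfamily consensi are license-restricted and not bundled;
  positional mapping on real AluY/AluSx copies requires user-supplied
  consensus FASTA, and the canonical positions 221/175/91 are asserted only
  on planted synthetic data.
* Genome-scale published numbers (transcript counts, table p-values) depend
  on hg18, the original arrays, and RepeatMasker output, and are out of
  reach at desk scale; the pipeline reproduces the printed worked example
  and the structural/statistical properties instead.
* One transcript interval per gene: isoform selection must happen upstream.
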