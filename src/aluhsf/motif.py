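"""Position weight matrix model of the Alu-internal heat shock element.

The heat shock factor (HSF) site studied here is a 13-bp motif with the
degenerate consensus ``nCAGAAAGCTCCG``.  It is modelled as a position weight
matrix (PWM): per-column base frequencies turned into log-odds scores (base 2,
so scores are in bits) against a background composition.  A candidate window
scores the sum of its per-column log-odds; windows at or above a threshold
(default 8.7 bits, chosen so that a documented HSPA1A promoter site scoring
8.9 bits is retained) are reported as motif hits.

The module covers PWM construction from an aligned site set, single-window
scoring, two-strand region scanning, de-novo motif discovery with a classic
Gibbs site sampler, and degenerate consensus-string export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Default width of the Alu-internal HSF motif.
MOTIF_WIDTH = 13

#: Default log-odds score threshold (bits) for calling a site.
DEFAULT_THRESHOLD = 8.7

#: Score of the documented HSPA1A promoter HSF site under the original model
#: (informational; the threshold sits just below it).
HSPA1A_REFERENCE_SCORE = 8.9

#: Core of the degenerate 13-bp consensus: the first position is unconstrained.
HSF_CONSENSUS_CORE = "CAGAAAGCTCCG"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and any other letter (N, ...) as 4."""
    out = np.full(len(seq), 4, dtype=np.int8)
    for base, code in _CODE.items():
        idx = np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(base)
        out[idx] = code
    return out


@dataclass
class PWM:
    """Position weight matrix over {A,C,G,T}.

    ``counts`` is a 4 x width matrix of base tallies; ``frequencies`` applies
    the pseudocount; ``log_odds`` is log2(frequency / background).
    """

    counts: np.ndarray
    background: np.ndarray
    pseudocount: float
    frequencies: np.ndarray = field(init=False)
    log_odds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x width matrix")
        if self.counts.shape[1] < 1:
            raise ValueError("PWM width must be >= 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")
        n = self.counts.sum(axis=0)
        denom = n + 4.0 * self.pseudocount
        self.frequencies = (self.counts + self.pseudocount) / denom
        with np.errstate(divide="ignore"):
            self.log_odds = np.log2(self.frequencies / self.background[:, None])

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def max_score(self) -> float:
        """Sum of the column-wise log-odds maxima (upper bound on any word)."""
        return float(self.log_odds.max(axis=0).sum())

    def information_content(self) -> float:
        """Total information content in bits: sum over columns of 2 + H(col)."""
        f = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * np.log2(f), 0.0)
        return float((2.0 + terms.sum(axis=0)).sum())


@dataclass
class MotifScanConfig:
    """Scanning parameters.

    ``n_policy`` controls windows containing an ambiguous base: ``"skip"``
    excludes them (default — no score is fabricated for unsequenced bases);
    ``"min"`` scores the ambiguous column at the column's minimum log-odds.
    """

    threshold: float = DEFAULT_THRESHOLD
    reference_score: float = HSPA1A_REFERENCE_SCORE
    strands: str = "both"
    n_policy: str = "skip"

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.strands not in ("plus", "minus", "both"):
            raise ValueError(f"unknown strands setting {self.strands!r}")
        if self.n_policy not in ("skip", "min"):
            raise ValueError(f"unknown n_policy {self.n_policy!r}")


@dataclass
class MotifHit:
    """One scored motif occurrence, in region-relative plus-strand coordinates.

    ``matched_word`` is the motif as read 5'->3' on the hit strand.
    """

    region_id: str
    start: int
    end: int
    strand: str
    score: float
    matched_word: str


def build_pwm(
    sites: list[str],
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
) -> PWM:
    """Build a PWM from an aligned set of equal-length A/C/G/T sites.

    Frequencies are (count + pseudocount) / (n + 4 * pseudocount); log-odds
    are log2(frequency / background).  Background defaults to uniform.
    """
    if not sites:
        raise ValueError("site set must be non-empty")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("all sites must have equal length")
    counts = np.zeros((4, width))
    for s in sites:
        codes = encode(s)
        if (codes == 4).any():
            raise ValueError(f"site {s!r} contains a non-ACGT base")
        counts[codes, np.arange(width)] += 1
    if background is None:
        background = np.full(4, 0.25)
    return PWM(counts=counts, background=background, pseudocount=pseudocount)


def default_hsf_pwm(pseudocount: float = 0.25) -> PWM:
    """PWM for the 13-bp Alu-internal HSF element.

    Built from the four first-base variants of the degenerate consensus
    ``nCAGAAAGCTCCG``, so column 1 is uniform and the remaining twelve
    columns are sharply peaked.  A perfect match to the core scores about
    21.2 bits; each core mismatch costs about 4.1 bits, so words up to three
    substitutions away still clear the 8.7-bit default threshold — mirroring
    the tolerance with which diverged Alu copies retain the element.
    """
    sites = [b + HSF_CONSENSUS_CORE for b in ALPHABET]
    return build_pwm(sites, pseudocount=pseudocount)


def score_window(pwm: PWM, word: str) -> float:
    """Log-odds score (bits) of a single word of length ``pwm.width``.

    A base with zero frequency (possible at pseudocount 0) yields -inf.
    A word containing an ambiguous base also scores -inf; region scanning
    applies its ``n_policy`` before windows reach this point.
    """
    if len(word) != pwm.width:
        raise ValueError(
            f"word length {len(word)} does not match PWM width {pwm.width}"
        )
    codes = encode(word)
    if (codes == 4).any():
        return float("-inf")
    return float(pwm.log_odds[codes, np.arange(pwm.width)].sum())


def _strand_scores(pwm: PWM, codes: np.ndarray, n_policy: str) -> np.ndarray:
    """Scores of all windows of one encoded strand (vectorised)."""
    w = pwm.width
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return np.empty(0)
    if n_policy == "min":
        extra = pwm.log_odds.min(axis=0)[None, :]
    else:  # skip: -inf drops the window below any finite threshold
        extra = np.full((1, w), -np.inf)
    lo = np.vstack([pwm.log_odds, extra])
    scores = np.zeros(n_win)
    for j in range(w):
        scores += lo[codes[j : j + n_win], j]
    return scores


def scan_region(
    pwm: PWM,
    sequence: str,
    config: MotifScanConfig | None = None,
    region_id: str = "region",
) -> list[MotifHit]:
    """Scan a region on one or both strands for windows scoring >= threshold.

    Minus-strand hit coordinates are reported on the plus strand of the
    scanned region; ``matched_word`` is read on the hit strand.  Hits are
    sorted by start, then strand ('+' before '-').  Overlapping hits are all
    retained: the analysis counts site occurrences, not a pruned subset.
    """
    if config is None:
        config = MotifScanConfig()
    w = pwm.width
    seq = sequence.upper()
    L = len(seq)
    hits: list[MotifHit] = []
    if L < w:
        return hits

    if config.strands in ("plus", "both"):
        scores = _strand_scores(pwm, encode(seq), config.n_policy)
        for i in np.flatnonzero(scores >= config.threshold):
            i = int(i)
            hits.append(
                MotifHit(region_id, i, i + w, "+", float(scores[i]), seq[i : i + w])
            )
    if config.strands in ("minus", "both"):
        rc = revcomp(seq)
        scores = _strand_scores(pwm, encode(rc), config.n_policy)
        for i in np.flatnonzero(scores >= config.threshold):
            i = int(i)
            start = L - i - w  # mirror back to the plus-strand frame
            hits.append(
                MotifHit(region_id, start, start + w, "-", float(scores[i]), rc[i : i + w])
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def consensus_string(pwm: PWM, degeneracy_cutoff: float = 0.5) -> str:
    """Degenerate consensus: majority base where its frequency >= cutoff, else 'n'.

    With the default cutoff the model of the Alu-internal element renders as
    ``nCAGAAAGCTCCG``: twelve constrained columns behind an unconstrained one.
    """
    if not 0.25 < degeneracy_cutoff <= 1:
        raise ValueError("degeneracy_cutoff must be in (0.25, 1]")
    out = []
    for j in range(pwm.width):
        col = pwm.frequencies[:, j]
        k = int(col.argmax())
        out.append(ALPHABET[k] if col[k] >= degeneracy_cutoff else "n")
    return "".join(out)


def majority_consensus(pwm: PWM) -> str:
    """Plain majority-base consensus (no degeneracy), e.g. for recovery checks."""
    return "".join(ALPHABET[int(k)] for k in pwm.frequencies.argmax(axis=0))


def gibbs_sample_motif(
    sequences: list[str],
    width: int = MOTIF_WIDTH,
    n_iterations: int = 500,
    n_restarts: int = 25,
    seed: int | None = None,
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
) -> tuple[PWM, list[int]]:
    """Classic Gibbs site sampler: one motif occurrence per sequence.

    Each iteration holds out one sequence, builds a PWM from the remaining
    sites, and resamples the held-out site with probability proportional to
    2**(log-odds score).  The highest-information-content alignment seen
    across restarts is returned, together with per-sequence site offsets.

    Deterministic for a fixed seed.  No annealing; defaults (25 restarts x
    500 iterations) are sized for site sets of tens of sequences a few
    hundred bases long.  After each full sweep a phase-shift move slides the
    whole alignment by up to two columns when that raises the information
    content, which unlocks the off-by-one registers the plain sampler is
    prone to.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    if any(len(s) < width for s in sequences):
        raise ValueError(f"every sequence must be at least {width} bases long")
    if background is None:
        background = np.full(4, 0.25)
    rng = np.random.default_rng(seed)
    n = len(sequences)
    codes = [encode(s.upper()) for s in sequences]
    if any((c == 4).any() for c in codes):
        raise ValueError("sequences must be over {A,C,G,T}")
    n_windows = [len(c) - width + 1 for c in codes]
    cols = np.arange(width)
    log_bg = np.log2(background)

    def tally(offsets: np.ndarray) -> np.ndarray:
        counts = np.zeros((4, width))
        for c, o in zip(codes, offsets):
            counts[c[o : o + width], cols] += 1
        return counts

    def ic_of(offsets: np.ndarray) -> float:
        return PWM(tally(offsets), background, pseudocount).information_content()

    best_offsets: np.ndarray | None = None
    best_ic = -np.inf
    for _ in range(n_restarts):
        offsets = np.array([rng.integers(0, m) for m in n_windows])
        counts = tally(offsets)
        for it in range(n_iterations):
            z = it % n
            c = codes[z]
            counts[c[offsets[z] : offsets[z] + width], cols] -= 1
            freq = (counts + pseudocount) / (n - 1 + 4.0 * pseudocount)
            logratio = np.log2(freq) - log_bg[:, None]
            m = n_windows[z]
            scores = np.zeros(m)
            for j in range(width):
                scores += logratio[c[j : j + m], j]
            p = np.exp2(scores - scores.max())
            p /= p.sum()
            offsets[z] = rng.choice(m, p=p)
            counts[c[offsets[z] : offsets[z] + width], cols] += 1
            if z == n - 1:  # end of sweep: greedy phase-shift move
                current = ic_of(offsets)
                best_shift = 0
                for d in (-2, -1, 1, 2):
                    shifted = offsets + d
                    if any(not 0 <= o < nw for o, nw in zip(shifted, n_windows)):
                        continue
                    ic_s = ic_of(shifted)
                    if ic_s > current:
                        current, best_shift = ic_s, d
                if best_shift:
                    offsets = offsets + best_shift
                    counts = tally(offsets)
        ic = ic_of(offsets)
        if ic > best_ic:
            best_ic, best_offsets = ic, offsets.copy()

    assert best_offsets is not None
    pwm = PWM(tally(best_offsets), background, pseudocount)
    return pwm, [int(o) for o in best_offsets]


def write_pwm(pwm: PWM, path) -> None:
    """Serialise a PWM as a plain-text position-frequency table."""
    with open(path, "w") as fh:
        fh.write("# position frequency matrix; background "
                 + " ".join(f"{b:.6g}" for b in pwm.background)
                 + f"; pseudocount {pwm.pseudocount:g}\n")
        fh.write("pos\t" + "\t".join(ALPHABET) + "\n")
        for j in range(pwm.width):
            fh.write(
                f"{j + 1}\t" + "\t".join(f"{pwm.counts[i, j]:g}" for i in range(4)) + "\n"
            )


def read_pwm(path) -> PWM:
    """Read a PWM written by :func:`write_pwm`."""
    background = np.full(4, 0.25)
    pseudocount = 0.25
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "background" in line:
                    parts = line.split("background")[1].split(";")[0].split()
                    background = np.array([float(x) for x in parts])
                if "pseudocount" in line:
                    pseudocount = float(line.rsplit("pseudocount", 1)[1])
                continue
            if not line or line.startswith("pos"):
                continue
            rows.append([float(x) for x in line.split("\t")[1:5]])
    counts = np.array(rows).T
    return PWM(counts=counts, background=background, pseudocount=pseudocount)
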