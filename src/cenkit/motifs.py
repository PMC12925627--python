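"""Position weight matrices: construction, log-odds scoring, exact p-value
calibration, and strand-aware scanning.

A :class:`Pwm` is a per-position nucleotide probability model over the
alphabet A, C, G, T.  Sequences are scored by the log-likelihood ratio (in
bits) of the motif model against a 0-order :class:`Background`.  P-values
are calibrated *exactly* for a discretized version of the score by
per-position convolution of the score distribution under the background
model, so a fixed p-value threshold has the same meaning for every motif.

Coordinates are 0-based, half-open, on the forward strand throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ALPHABET = "ACGT"

#: IUPAC nucleotide codes accepted in input sequences.  Only A/C/G/T are
#: scored; windows containing any other code are skipped by the scanner.
IUPAC_CODES = set("ACGTRYSWKMBDHVN")

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMP_TABLE = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes and case."""
    return seq.translate(_COMP_TABLE)[::-1]


def at_percent(seq: str) -> float:
    """A+T percentage of a sequence; ambiguous bases are excluded from both
    numerator and denominator.  Returns 0.0 for an empty/all-ambiguous input."""
    codes = encode(seq)
    valid = int((codes < 4).sum())
    if valid == 0:
        return 0.0
    at = int(((codes == 0) | (codes == 3)).sum())
    return 100.0 * at / valid


def gc_percent(seq: str) -> float:
    """G+C percentage, ambiguous bases excluded (0.0 for empty input)."""
    codes = encode(seq)
    valid = int((codes < 4).sum())
    if valid == 0:
        return 0.0
    gc = int(((codes == 1) | (codes == 2)).sum())
    return 100.0 * gc / valid


@dataclass(frozen=True)
class Background:
    """0-order background model over A, C, G, T.

    ``source`` records provenance: ``uniform``, ``genome`` (estimated from the
    scanned assembly) or ``user``.
    """

    freqs: np.ndarray
    source: str = "uniform"

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=np.float64)
        if freqs.shape != (4,):
            raise ValueError("background must have exactly 4 frequencies (A,C,G,T)")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"background frequencies must sum to 1, got {freqs.sum()!r}")
        if (freqs <= 0).any():
            raise ValueError("background frequencies must all be > 0")
        object.__setattr__(self, "freqs", freqs)

    @classmethod
    def uniform(cls) -> "Background":
        return cls(np.full(4, 0.25), source="uniform")

    @classmethod
    def from_sequences(cls, seqs, floor: float = 1e-6) -> "Background":
        """Estimate 0-order frequencies from pooled sequences (ambiguous bases
        ignored).  ``floor`` guards against absent bases in tiny inputs."""
        counts = np.zeros(4, dtype=np.float64)
        for s in seqs:
            codes = encode(s)
            counts += np.bincount(codes[codes < 4], minlength=4)
        if counts.sum() == 0:
            return cls.uniform()
        freqs = np.maximum(counts / counts.sum(), floor)
        freqs = freqs / freqs.sum()
        return cls(freqs, source="genome")

    @classmethod
    def user(cls, freqs) -> "Background":
        return cls(np.asarray(freqs, dtype=np.float64), source="user")


@dataclass
class Pwm:
    """Per-position nucleotide probability matrix.

    ``probs`` is a width x 4 matrix whose rows sum to 1.  ``pseudocount`` and
    ``n_sites`` record how the matrix was built (``n_sites`` is 0 for matrices
    loaded from a motif file).
    """

    name: str
    probs: np.ndarray
    pseudocount: float = 0.0
    n_sites: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("probs must be a width x 4 matrix with width >= 1")
        if (probs < 0).any():
            raise ValueError("probabilities must be non-negative")
        rowsums = probs.sum(axis=1)
        if np.abs(rowsums - 1.0).max() > 1e-9:
            i = int(np.abs(rowsums - 1.0).argmax())
            raise ValueError(f"row {i} of motif {self.name!r} sums to {rowsums[i]!r}, not 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.pseudocount > 0 and (probs == 0).any():
            raise ValueError("entries must be strictly positive when pseudocount > 0")
        self.probs = probs

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.name + "_rc", self.probs[::-1, ::-1].copy(),
                   self.pseudocount, self.n_sites)

    def max_score(self, background: Background) -> float:
        """Highest achievable log-odds score (bits) against ``background``."""
        return float(log_odds(self, background).max(axis=1).sum())

    def min_score(self, background: Background) -> float:
        return float(log_odds(self, background).min(axis=1).sum())


def build_pwm(sites, pseudocount: float = 0.1, name: str = "motif") -> Pwm:
    """Build a :class:`Pwm` from aligned, equal-length example sites.

    ``N`` contributes 0.25 to each base count.  Probabilities follow the
    additive-smoothing convention::

        probs[i][b] = (count(b at i) + pseudocount * 0.25) / (n_sites + pseudocount)
    """
    sites = [s.upper() for s in sites]
    if not sites:
        raise ValueError("cannot build a PWM from an empty site list")
    width = len(sites[0])
    counts = np.zeros((width, 4), dtype=np.float64)
    for k, site in enumerate(sites):
        if len(site) != width:
            raise ValueError(
                f"sites must all have the same length: site {k} ({site!r}) "
                f"has length {len(site)}, expected {width}"
            )
        for i, ch in enumerate(site):
            if ch == "N":
                counts[i] += 0.25
            elif ch in ALPHABET:
                counts[i, ALPHABET.index(ch)] += 1.0
            else:
                raise ValueError(f"invalid character {ch!r} in site {k} ({site!r})")
    n = len(sites)
    probs = (counts + pseudocount * 0.25) / (n + pseudocount)
    return Pwm(name=name, probs=probs, pseudocount=pseudocount, n_sites=n)


def log_odds(pwm: Pwm, background: Background) -> np.ndarray:
    """width x 4 log2-odds matrix; the score of a word is the sum of its
    per-position entries."""
    if (pwm.probs <= 0).any():
        raise ValueError(
            "PWM contains zero probabilities; rebuild it with a pseudocount > 0 "
            "before computing log-odds"
        )
    return np.log2(pwm.probs / background.freqs[None, :])


@dataclass
class MotifHit:
    """One scored, strand-aware motif match.

    ``start``/``end`` are 0-based half-open forward-strand coordinates;
    ``matched_seq`` is given in motif orientation (reverse-complemented for
    minus-strand hits).
    """

    contig: str
    start: int
    end: int
    strand: str
    score: float
    p_value: float
    matched_seq: str


class MotifScanner:
    """Scores sequences against one PWM with exactly calibrated p-values.

    The log-odds matrix is discretized to integers (``granularity`` bins over
    the widest per-position score range) and the full distribution of the
    integer score of a background-random word is computed by per-position
    convolution.  P-values are reported at the discretized score floor, which
    is conservative; the discretization error of the score is bounded by
    width/scale bits.
    """

    def __init__(self, pwm: Pwm, background: Background, granularity: int = 1000):
        if granularity < 100:
            raise ValueError("granularity must be >= 100")
        self.pwm = pwm
        self.background = background
        self.granularity = granularity
        lo = log_odds(pwm, background)
        self.lo = lo
        row_min = lo.min(axis=1)
        max_range = float((lo.max(axis=1) - row_min).max())
        self.scale = granularity / max_range if max_range > 0 else 1.0
        self.int_matrix = np.floor((lo - row_min[:, None]) * self.scale + 1e-12).astype(np.int64)
        self.offset = float(row_min.sum())
        # complement columns (A<->T, C<->G) and reverse rows: scoring the
        # forward strand with this matrix equals scoring the reverse
        # complement of each window with the original matrix.
        self.int_matrix_rc = self.int_matrix[::-1, ::-1].copy()
        self.lo_rc = lo[::-1, ::-1].copy()

        dist = np.ones(1, dtype=np.float64)
        for i in range(pwm.width):
            row = self.int_matrix[i]
            new = np.zeros(len(dist) + int(row.max()), dtype=np.float64)
            for b in range(4):
                new[row[b]:row[b] + len(dist)] += dist * background.freqs[b]
            dist = new
        total = dist.sum()
        if abs(total - 1.0) > 1e-9:  # pragma: no cover - numerical safeguard
            dist = dist / total
        self.support = dist
        self.survival = np.minimum(np.cumsum(dist[::-1])[::-1], 1.0)

    # -- p-value table ------------------------------------------------------

    @property
    def score_grid(self) -> np.ndarray:
        """Real-score value of each discretized score level."""
        return self.offset + np.arange(len(self.survival)) / self.scale

    def pvalue_of_int(self, s: int) -> float:
        """P(discretized score >= s) for a background-random word."""
        if s <= 0:
            return 1.0
        s = min(int(s), len(self.survival) - 1)
        return float(self.survival[s])

    def pvalue(self, score: float) -> float:
        """P-value of a real log-odds score (floor-discretized, conservative)."""
        return self.pvalue_of_int(int(np.floor((score - self.offset) * self.scale + 1e-9)))

    def score_threshold_int(self, p_threshold: float) -> int:
        """Smallest discretized score whose p-value is <= ``p_threshold``."""
        idx = np.nonzero(self.survival <= p_threshold)[0]
        return int(idx[0]) if idx.size else len(self.survival)

    # -- word helpers -------------------------------------------------------

    def word_int_score(self, word: str) -> int:
        codes = encode(word.upper())
        if (codes >= 4).any() or len(codes) != self.pwm.width:
            raise ValueError("word must be ACGT-only and match the motif width")
        return int(self.int_matrix[np.arange(self.pwm.width), codes].sum())

    def word_score(self, word: str) -> float:
        codes = encode(word.upper())
        return float(self.lo[np.arange(self.pwm.width), codes].sum())

    def word_pvalue(self, word: str) -> float:
        return self.pvalue_of_int(self.word_int_score(word))

    # -- scanning -----------------------------------------------------------

    def scan(self, contig_seq: str, p_threshold: float,
             strands: str = "both", contig: str = "contig") -> list[MotifHit]:
        """All windows (both strands unless ``strands='forward'``) whose
        calibrated p-value is <= ``p_threshold``, sorted by start coordinate.
        Windows containing any non-ACGT character are skipped."""
        if not (0.0 < p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        if strands not in ("both", "forward"):
            raise ValueError("strands must be 'both' or 'forward'")
        w = self.pwm.width
        seq = contig_seq.upper()
        n = len(seq)
        if n < w:
            return []
        codes = encode(seq)
        amb = codes >= 4
        safe = np.where(amb, 0, codes).astype(np.intp)
        n_windows = n - w + 1
        cum = np.concatenate(([0], np.cumsum(amb)))
        bad = (cum[w:] - cum[:-w]) > 0
        smin = self.score_threshold_int(p_threshold)

        hits: list[MotifHit] = []
        strand_list = ["+"] if strands == "forward" else ["+", "-"]
        for strand in strand_list:
            mat = self.int_matrix if strand == "+" else self.int_matrix_rc
            lo = self.lo if strand == "+" else self.lo_rc
            scores = np.zeros(n_windows, dtype=np.int64)
            for i in range(w):
                scores += mat[i][safe[i:i + n_windows]]
            ok = np.nonzero((scores >= smin) & ~bad)[0]
            idx = np.arange(w)
            for j in ok:
                word = seq[j:j + w]
                real = float(lo[idx, safe[j:j + w]].sum())
                matched = word if strand == "+" else revcomp(word)
                hits.append(MotifHit(
                    contig=contig, start=int(j), end=int(j + w), strand=strand,
                    score=real, p_value=self.pvalue_of_int(int(scores[j])),
                    matched_seq=matched,
                ))
        hits.sort(key=lambda h: (h.start, h.strand))
        return hits


def score_pvalue_table(pwm: Pwm, background: Background,
                       granularity: int = 1000) -> MotifScanner:
    """Exact score -> p-value calibration (see :class:`MotifScanner`).

    The returned object maps scores to p-values via :meth:`MotifScanner.pvalue`
    and exposes the full discretized distribution (``support``/``survival``).
    """
    return MotifScanner(pwm, background, granularity=granularity)


def scan(contig_seq: str, pwm: Pwm, background: Background, p_threshold: float,
         strands: str = "both", contig: str = "contig",
         granularity: int = 1000) -> list[MotifHit]:
    """Convenience wrapper: build a scanner and scan one contig."""
    return MotifScanner(pwm, background, granularity).scan(
        contig_seq, p_threshold, strands=strands, contig=contig)
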