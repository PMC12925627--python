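"""Point-centromere annotation.

Point centromeres of Saccharomycetaceae-like genomes consist of a ~8-bp CDEI
motif, an AT-rich spacer (CDEII) whose length is the key evolving trait, and
a ~26-bp CDEIII motif.  Annotation proceeds in two sequential motif searches:

1. scan the assembly (both strands) with the CDEIII matrix and extract, for
   every hit, a fixed-size window consisting of the motif plus 224 bp of
   upstream sequence in centromere orientation;
2. rescan each window with the CDEI matrix at a permissive threshold and, for
   windows with a CDEI match, measure the intervening CDEII (length and AT%).

Candidates are ranked by a combined score and passed through a cascade of
filters (top-N, CDEII length coherence, AT content, duplicate removal, and a
joint length/AT outlier rule); the number of retained calls doubles as a
karyotype estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .motifs import (Background, MotifScanner, Pwm, at_percent, revcomp)

logger = logging.getLogger(__name__)

Records = Sequence[Tuple[str, str]]


@dataclass
class CandidateWindow:
    """A CDEIII hit plus its fixed upstream context, in centromere orientation
    (CDEIII occupies the window's 3' end)."""

    contig: str
    window_start: int
    window_end: int
    orientation: str
    window_seq: str
    cdeiii_hit: object


@dataclass
class CentromereCall:
    """One candidate or final point centromere (CDEI..CDEIII span)."""

    contig: str
    start: int
    end: int
    orientation: str
    full_seq: str
    cdei_seq: str
    cdeii_seq: str
    cdeiii_seq: str
    cdeii_length: int
    cdeii_at: float
    score_cdei: float
    score_cdeiii: float
    combined_score: Optional[float] = None
    status: str = "candidate"

    @property
    def retained(self) -> bool:
        return self.status == "retained"


def extract_windows(records: Records, cdeiii: Pwm, background: Background,
                    p_threshold: float, upstream: int = 224,
                    granularity: int = 1000) -> tuple[list[CandidateWindow], int]:
    """First-stage CDEIII scan.

    Returns one window per hit with at least ``upstream`` bp of upstream
    sequence available in centromere orientation, plus the count of hits
    dropped for sitting too close to a contig edge.  For minus-strand hits
    "upstream" lies downstream on the forward strand and the window is
    reverse-complemented.
    """
    scanner = MotifScanner(cdeiii, background, granularity=granularity)
    windows: list[CandidateWindow] = []
    edge_dropped = 0
    for name, seq in records:
        seq = seq.upper()
        for hit in scanner.scan(seq, p_threshold, strands="both", contig=name):
            if hit.strand == "+":
                ws, we = hit.start - upstream, hit.end
                if ws < 0:
                    edge_dropped += 1
                    continue
                window_seq = seq[ws:we]
            else:
                ws, we = hit.start, hit.end + upstream
                if we > len(seq):
                    edge_dropped += 1
                    continue
                window_seq = revcomp(seq[ws:we])
            windows.append(CandidateWindow(
                contig=name, window_start=ws, window_end=we,
                orientation=hit.strand, window_seq=window_seq, cdeiii_hit=hit))
    if edge_dropped:
        logger.warning("dropped %d CDEIII hit(s) too close to a contig edge", edge_dropped)
    return windows, edge_dropped


def attach_cdei(windows: Sequence[CandidateWindow], cdei: Pwm,
                background: Background, p_threshold: float = 1e-2,
                granularity: int = 1000) -> list[CentromereCall]:
    """Second-stage CDEI rescan of each window (forward orientation only).

    Windows without a CDEI match above threshold are dropped; with several
    matches the best-scoring one wins (ties resolved toward the window's
    5' end).  CDEII is the subsequence strictly between CDEI end and CDEIII
    start.
    """
    scanner = MotifScanner(cdei, background, granularity=granularity)
    calls: list[CentromereCall] = []
    for win in windows:
        cdeiii_w = win.cdeiii_hit.end - win.cdeiii_hit.start
        cdeiii_start = len(win.window_seq) - cdeiii_w
        hits = scanner.scan(win.window_seq, p_threshold, strands="forward",
                            contig=win.contig)
        hits = [h for h in hits if h.end <= cdeiii_start]
        if not hits:
            continue
        best = min(hits, key=lambda h: (-h.score, h.start))
        full_seq = win.window_seq[best.start:]
        cdei_seq = win.window_seq[best.start:best.end]
        cdeii_seq = win.window_seq[best.end:cdeiii_start]
        cdeiii_seq = win.window_seq[cdeiii_start:]
        if win.orientation == "+":
            start = win.window_start + best.start
            end = win.window_end
        else:
            start = win.window_start
            end = win.window_end - best.start
        calls.append(CentromereCall(
            contig=win.contig, start=start, end=end,
            orientation=win.orientation, full_seq=full_seq,
            cdei_seq=cdei_seq, cdeii_seq=cdeii_seq, cdeiii_seq=cdeiii_seq,
            cdeii_length=len(cdeii_seq), cdeii_at=at_percent(cdeii_seq),
            score_cdei=best.score, score_cdeiii=win.cdeiii_hit.score))
    return calls


def combined_score(call: CentromereCall, weights=(1.0, 1.0, 1.0), *,
                   max_cdei: float, max_cdeiii: float) -> float:
    """Weighted sum of max-normalized CDEIII score, CDEI score, and CDEII AT%.

    Strictly increasing in each component; equals ``sum(weights)`` for a
    perfect-consensus call with a 100% AT CDEII.
    """
    w1, w2, w3 = weights
    return (w1 * (call.score_cdeiii / max_cdeiii)
            + w2 * (call.score_cdei / max_cdei)
            + w3 * (call.cdeii_at / 100.0))


def score_calls(calls: Sequence[CentromereCall], cdei: Pwm, cdeiii: Pwm,
                background: Background, weights=(1.0, 1.0, 1.0)) -> None:
    """Assign ``combined_score`` to every call in place."""
    max_cdei = cdei.max_score(background)
    max_cdeiii = cdeiii.max_score(background)
    for call in calls:
        call.combined_score = combined_score(
            call, weights, max_cdei=max_cdei, max_cdeiii=max_cdeiii)


def _overlap_frac(a: CentromereCall, b: CentromereCall) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return ov / min(a.end - a.start, b.end - b.start)


def filter_cascade(calls: Sequence[CentromereCall], top_n: int = 50,
                   length_window: int = 30, min_at: float = 70.0,
                   joint_length: int = 10, joint_at: float = 7.0,
                   ) -> list[CentromereCall]:
    """Apply the five filtering rules sequentially, marking removals.

    1. keep only the ``top_n`` calls by combined score;
    2. remove calls whose CDEII length differs by more than ``length_window``
       nt from the median length of the top 5 (by score) survivors;
    3. remove calls with CDEII AT content < ``min_at``%;
    4. remove duplicates (identical full sequence, or >50% coordinate overlap
       on the same contig and strand), keeping the higher-scoring call;
    5. recompute the length and AT medians over survivors and remove calls in
       which *both* the length differs by more than ``joint_length`` nt and
       the AT content lies below median - ``joint_at``.

    All calls are returned with ``status`` set to ``retained`` or
    ``removed:<rule>``.
    """
    calls = list(calls)
    if not calls:
        return []
    if any(c.combined_score is None for c in calls):
        raise ValueError("combined_score must be set on every call (run score_calls)")

    ranked = sorted(calls, key=lambda c: (-c.combined_score, c.contig, c.start))
    survivors = ranked[:top_n]
    for c in ranked[top_n:]:
        c.status = "removed:top50"

    # rule 2: CDEII length coherence with the top-5 median (with fewer than 5
    # survivors the median of all available is used)
    m5 = median(c.cdeii_length for c in survivors[:5])
    kept = []
    for c in survivors:
        if abs(c.cdeii_length - m5) > length_window:
            c.status = "removed:length_outlier"
        else:
            kept.append(c)
    survivors = kept

    # rule 3: minimum CDEII AT content
    kept = []
    for c in survivors:
        if c.cdeii_at < min_at:
            c.status = "removed:at_content"
        else:
            kept.append(c)
    survivors = kept

    # rule 4: duplicates; survivors are in score order, so the first of a
    # duplicate group is the keeper (ties broken by (contig, start) in the
    # initial sort)
    kept = []
    for c in survivors:
        dup = False
        for k in kept:
            if c.full_seq == k.full_seq:
                dup = True
                break
            if (c.contig == k.contig and c.orientation == k.orientation
                    and _overlap_frac(c, k) > 0.5):
                dup = True
                break
        if dup:
            c.status = "removed:duplicate"
        else:
            kept.append(c)
    survivors = kept

    # rule 5: joint length/AT outlier rule (AND semantics: both must deviate)
    if survivors:
        med_len = median(c.cdeii_length for c in survivors)
        med_at = median(c.cdeii_at for c in survivors)
        kept = []
        for c in survivors:
            if (abs(c.cdeii_length - med_len) > joint_length
                    and c.cdeii_at < med_at - joint_at):
                c.status = "removed:length_at_joint"
            else:
                kept.append(c)
        survivors = kept

    for c in survivors:
        c.status = "retained"
    return calls


@dataclass
class AnnotateConfig:
    """Configuration for :func:`annotate_genome`.

    ``background`` is ``"genome"`` (0-order frequencies estimated from the
    scanned assembly, the default), ``"uniform"``, or a :class:`Background`.
    Thresholds default to the midpoint of the usual CDEIII range (1e-5) and
    the permissive CDEI threshold (1e-2); per-clade overrides go here.
    """

    cdei: Pwm
    cdeiii: Pwm
    p_cdeiii: float = 1e-5
    p_cdei: float = 1e-2
    upstream: int = 224
    background: Union[str, Background] = "genome"
    weights: tuple = (1.0, 1.0, 1.0)
    top_n: int = 50
    length_window: int = 30
    min_at: float = 70.0
    joint_length: int = 10
    joint_at: float = 7.0
    granularity: int = 1000
    species: str = "synthetic"
    assembly: str = "NA"

    def __post_init__(self) -> None:
        for p in (self.p_cdeiii, self.p_cdei):
            if not (0.0 < p < 1.0):
                raise ValueError("p-value thresholds must lie in (0, 1)")

    def resolve_background(self, records: Records) -> Background:
        if isinstance(self.background, Background):
            return self.background
        if self.background == "uniform":
            return Background.uniform()
        if self.background == "genome":
            return Background.from_sequences(seq for _, seq in records)
        raise ValueError(f"unknown background spec {self.background!r}")


#: Column order mirroring the published per-centromere table schema.
TABLE_COLUMNS = [
    "species", "assembly", "genome_size", "contig", "centromere_number",
    "full_sequence", "cdei_sequence", "cdeiii_sequence", "cdeii_sequence",
    "cdeii_length", "cdeii_at",
    "start", "end", "orientation", "score_cdei", "score_cdeiii",
    "combined_score", "status",
]


@dataclass
class AnnotationResult:
    calls: list
    table: pd.DataFrame
    karyotype: int
    removal_counts: dict
    n_edge_dropped: int
    config: AnnotateConfig


def build_table(calls: Sequence[CentromereCall], config: AnnotateConfig,
                genome_size: int, keep_removed: bool = False) -> pd.DataFrame:
    """Per-centromere table; retained calls are numbered by (contig, start)."""
    retained = sorted((c for c in calls if c.retained),
                      key=lambda c: (c.contig, c.start))
    numbers = {id(c): i + 1 for i, c in enumerate(retained)}
    rows = []
    ordered = retained + sorted((c for c in calls if not c.retained),
                                key=lambda c: (c.contig, c.start))
    for c in ordered:
        if not keep_removed and not c.retained:
            continue
        rows.append({
            "species": config.species, "assembly": config.assembly,
            "genome_size": genome_size, "contig": c.contig,
            "centromere_number": numbers.get(id(c), 0),
            "full_sequence": c.full_seq, "cdei_sequence": c.cdei_seq,
            "cdeiii_sequence": c.cdeiii_seq, "cdeii_sequence": c.cdeii_seq,
            "cdeii_length": c.cdeii_length, "cdeii_at": round(c.cdeii_at, 2),
            "start": c.start, "end": c.end, "orientation": c.orientation,
            "score_cdei": round(c.score_cdei, 4),
            "score_cdeiii": round(c.score_cdeiii, 4),
            "combined_score": round(c.combined_score, 6),
            "status": c.status,
        })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def annotate_genome(records: Records, config: AnnotateConfig,
                    keep_removed: bool = False) -> AnnotationResult:
    """End-to-end annotation of one assembly.

    Deterministic given the inputs; the karyotype estimate is the number of
    retained calls.
    """
    records = [(name, seq.upper()) for name, seq in records]
    background = config.resolve_background(records)
    windows, edge_dropped = extract_windows(
        records, config.cdeiii, background, config.p_cdeiii,
        upstream=config.upstream, granularity=config.granularity)
    calls = attach_cdei(windows, config.cdei, background,
                        p_threshold=config.p_cdei, granularity=config.granularity)
    score_calls(calls, config.cdei, config.cdeiii, background, config.weights)
    calls = filter_cascade(calls, top_n=config.top_n,
                           length_window=config.length_window,
                           min_at=config.min_at,
                           joint_length=config.joint_length,
                           joint_at=config.joint_at)
    genome_size = sum(len(seq) for _, seq in records)
    table = build_table(calls, config, genome_size, keep_removed=keep_removed)
    removal_counts: dict = {}
    for c in calls:
        if not c.retained:
            removal_counts[c.status] = removal_counts.get(c.status, 0) + 1
    karyotype = sum(1 for c in calls if c.retained)
    logger.info("annotated %s: %d candidate(s), karyotype %d, removals %s",
                config.species, len(calls), karyotype, removal_counts)
    return AnnotationResult(calls=calls, table=table, karyotype=karyotype,
                            removal_counts=removal_counts,
                            n_edge_dropped=edge_dropped, config=config)
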