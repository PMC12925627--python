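"""Synthetic genomes with planted centromeres, for end-to-end verification.

The generator emulates the statistical structure the annotation pipeline
assumes: i.i.d. AT-biased background sequence, one planted point centromere
per chromosome (8-bp CDEI motif, AT-rich CDEII of a controlled length
distribution, 26-bp CDEIII motif, each with per-position substitution
noise), decoy loci designed to be caught by the filter cascade, and
Mucoromycota-style loci (41-bp motif followed by an AT-rich run).  Every
genome ships with a truth table of planted coordinates.

Planted motif instances are constrained to remain detectable at the
pipeline's nominal thresholds (noisy copies are redrawn if their calibrated
p-value falls above threshold).  This mirrors the biology: motif instances
at functional centromeres are maintained by selection, so a planted "true"
site that no longer matches its own motif would be a mislabelled truth
entry, not a harder test case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .motifs import (Background, MotifScanner, Pwm, at_percent, build_pwm,
                     gc_percent, revcomp)

#: Default motif consensus sequences.  CDEI is the 8-bp Cbf1-bound E-box
#: motif; CDEIII is a 26-bp motif with the conserved CCGAA core embedded in
#: AT-rich flanks; the 41-bp motif is the Mucoromycota core-centromere type.
DEFAULT_CDEI_CONSENSUS = "GTCACGTG"
DEFAULT_CDEIII_CONSENSUS = "TGTATTTGATTTCCGAAAGTTAAAAA"
DEFAULT_MUCOR_CONSENSUS = "GGATTTCAAGCTAGTTAAACGGTATCCAGATTTGAACGTCA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.38) -> str:
    """i.i.d. DNA with the given GC fraction (A=T and G=C each split evenly)."""
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    cum = np.cumsum(probs)
    codes = np.searchsorted(cum, rng.random(length), side="right")
    return _BASES[codes].tobytes().decode("ascii")


def noisy_copy(rng: np.random.Generator, consensus: str, rate: float) -> str:
    """Per-position substitution at the given rate (to a different base)."""
    seq = list(consensus)
    for i, base in enumerate(seq):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != base]
            seq[i] = choices[int(rng.integers(3))]
    return "".join(seq)


def at_rich(rng: np.random.Generator, length: int, at_fraction: float,
            min_at: Optional[float] = None, max_at: Optional[float] = None,
            max_tries: int = 100) -> str:
    """Random sequence with the given expected A+T fraction.

    ``min_at``/``max_at`` (percent) optionally constrain the *realized* AT
    content by redrawing: planted functional spacers must stay AT-rich to
    function, and planted low-AT decoys must actually be low-AT, so short
    sequences are not allowed to drift across that divide by sampling noise.
    """
    for _ in range(max_tries):
        seq = random_dna(rng, length, gc=1.0 - at_fraction)
        realized = at_percent(seq) if length else 100.0 * at_fraction
        if (min_at is None or realized >= min_at) and \
           (max_at is None or realized <= max_at):
            return seq
    return seq


def motif_sites(consensus: str, n_sites: int = 20, noise: float = 0.05,
                seed: int = 0) -> List[str]:
    """Noisy example sites for building a search matrix from a consensus."""
    rng = np.random.default_rng(seed)
    return [noisy_copy(rng, consensus, noise) for _ in range(n_sites)]


def _functional_copy(rng: np.random.Generator, consensus: str, rate: float,
                     scanner: Optional[MotifScanner], p_threshold: float,
                     min_score_frac: float, max_tries: int = 100) -> str:
    """Noisy copy constrained to remain functional: calibrated p-value at or
    below threshold and log-odds score at least ``min_score_frac`` of the
    maximum (substitutions are redrawn until the site still "binds")."""
    if scanner is None:
        return noisy_copy(rng, consensus, rate)
    floor = min_score_frac * float(scanner.lo.max(axis=1).sum())
    for _ in range(max_tries):
        site = noisy_copy(rng, consensus, rate)
        if (scanner.word_pvalue(site) <= p_threshold
                and scanner.word_score(site) >= floor):
            return site
    return consensus


@dataclass
class PlantSpec:
    """Conditions for a synthetic point-centromere genome."""

    n_chromosomes: int = 16
    chrom_length: int = 750_000
    gc_background: float = 0.38
    cdei_consensus: str = DEFAULT_CDEI_CONSENSUS
    cdeiii_consensus: str = DEFAULT_CDEIII_CONSENSUS
    motif_noise: float = 0.05
    #: CDEII length -> mixture weight (e.g. {50: 0.5, 61: 0.5} for a genome
    #: caught mid-transition between two centromere types)
    cdeii_length_classes: Dict[int, float] = field(default_factory=lambda: {85: 1.0})
    cdeii_at: float = 0.92
    #: floor on the *realized* AT% of planted functional CDEII spacers
    cdeii_at_min: float = 90.0
    #: decoys: full CDEI+CDEII+CDEIII cassettes whose CDEII has low AT
    #: content, and bare CDEIII sites with no planted CDEI upstream.  Decoy
    #: motif copies are not under selection, so they erode: they carry
    #: ``decoy_noise_multiplier`` times the site substitution rate and are
    #: never redrawn for detectability.
    n_decoy_low_at: int = 40
    n_decoy_cdeiii_only: int = 20
    decoy_at: float = 0.50
    #: ceiling on the realized AT%% of decoy spacers/contexts
    decoy_at_max: float = 60.0
    decoy_noise_multiplier: float = 2.0
    #: planted functional sites are redrawn until they pass the detection
    #: thresholds and keep >= this fraction of the maximal log-odds score
    #: (selection maintains binding-competent motif instances)
    ensure_detectable: bool = True
    detect_min_score_frac: float = 0.7
    p_detect_cdeiii: float = 1e-5
    p_detect_cdei: float = 1e-2
    #: size of the candidate window the annotation pipeline will inspect
    #: (motif + upstream); used to keep planted windows unambiguous
    upstream_window: int = 224
    margin: int = 5_000
    min_separation: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.cdeii_length_classes.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("cdeii length-class weights must sum to 1")
        if any(l <= 0 for l in self.cdeii_length_classes):
            raise ValueError("cdeii lengths must be positive")
        max_cassette = (len(self.cdei_consensus) + max(self.cdeii_length_classes)
                        + len(self.cdeiii_consensus))
        if self.chrom_length < 2 * self.margin + max_cassette:
            raise ValueError(
                f"chrom_length {self.chrom_length} too short for margins "
                f"{self.margin} and cassette length {max_cassette}")

    def background(self) -> Background:
        gc = self.gc_background
        return Background.user([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def default_motifs(spec: PlantSpec, n_sites: int = 20,
                   pseudocount: float = 0.1) -> Tuple[Pwm, Pwm]:
    """Search matrices (CDEI, CDEIII) built from noisy sites of the spec's
    consensus sequences, seeded from the spec seed."""
    cdei = build_pwm(motif_sites(spec.cdei_consensus, n_sites, spec.motif_noise,
                                 seed=spec.seed + 101),
                     pseudocount=pseudocount, name="CDEI")
    cdeiii = build_pwm(motif_sites(spec.cdeiii_consensus, n_sites, spec.motif_noise,
                                   seed=spec.seed + 202),
                       pseudocount=pseudocount, name="CDEIII")
    return cdei, cdeiii


def _place_intervals(rng: np.random.Generator, chrom_length: int, margin: int,
                     lengths: Sequence[int], min_sep: int) -> List[int]:
    """Non-overlapping start positions for cassettes of the given lengths."""
    placed: List[Tuple[int, int]] = []
    starts: List[int] = []
    for length in lengths:
        lo, hi = margin, chrom_length - margin - length
        if hi <= lo:
            raise ValueError("contig too short to place cassette inside margins")
        for _ in range(1000):
            s = int(rng.integers(lo, hi))
            if all(s + length + min_sep <= a or b + min_sep <= s for a, b in placed):
                placed.append((s, s + length))
                starts.append(s)
                break
        else:  # pragma: no cover - only for absurdly dense specs
            raise RuntimeError("could not place cassette without overlap")
    return starts


def make_point_centromere_genome(spec: PlantSpec
                                 ) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Generate a genome in which every chromosome carries exactly one planted
    centromere at a random interior position and strand, plus the configured
    decoys, and return (FASTA records, truth table)."""
    rng = np.random.default_rng(spec.seed)
    bg = spec.background()
    cdei_pwm, cdeiii_pwm = default_motifs(spec)
    cdei_scanner = MotifScanner(cdei_pwm, bg) if spec.ensure_detectable else None
    cdeiii_scanner = MotifScanner(cdeiii_pwm, bg) if spec.ensure_detectable else None

    classes = sorted(spec.cdeii_length_classes)
    weights = np.array([spec.cdeii_length_classes[c] for c in classes])

    # round-robin decoy assignment across chromosomes
    decoy_kinds: List[List[str]] = [[] for _ in range(spec.n_chromosomes)]
    for j in range(spec.n_decoy_low_at):
        decoy_kinds[j % spec.n_chromosomes].append("decoy_low_at")
    for j in range(spec.n_decoy_cdeiii_only):
        decoy_kinds[j % spec.n_chromosomes].append("decoy_cdeiii_only")

    records: List[Tuple[str, str]] = []
    truth_rows = []
    for chrom in range(spec.n_chromosomes):
        name = f"chr{chrom + 1:02d}"
        cls = int(classes[int(rng.choice(len(classes), p=weights))])
        cassettes = []  # (kind, sequence in cassette orientation, meta)
        cdei = _functional_copy(rng, spec.cdei_consensus, spec.motif_noise,
                                cdei_scanner, spec.p_detect_cdei,
                                spec.detect_min_score_frac)
        cdeiii = _functional_copy(rng, spec.cdeiii_consensus, spec.motif_noise,
                                  cdeiii_scanner, spec.p_detect_cdeiii,
                                  spec.detect_min_score_frac)
        # The planted CDEI must be the unique best CDEI reading of its own
        # candidate window, otherwise the truth table would be ambiguous;
        # redraw the AT spacer and the upstream pad until no spurious match
        # in the 224-bp window outscores (or 5'-ties) the planted site.
        pad_len = max(spec.upstream_window - len(cdei) - cls, 0)
        for _ in range(100):
            cdeii = at_rich(rng, cls, spec.cdeii_at, min_at=spec.cdeii_at_min)
            pad = random_dna(rng, pad_len, spec.gc_background)
            if cdei_scanner is None:
                break
            window = pad + cdei + cdeii
            hits = cdei_scanner.scan(window, spec.p_detect_cdei,
                                     strands="forward")
            best = min(hits, key=lambda h: (-h.score, h.start))
            if best.start == pad_len:
                break
        cassettes.append(("centromere", pad + cdei + cdeii + cdeiii,
                          {"cdeii_length": cls, "cdeii_at": at_percent(cdeii),
                           "class_length": cls, "pad": pad_len}))
        decoy_rate = spec.motif_noise * spec.decoy_noise_multiplier
        for kind in decoy_kinds[chrom]:
            if kind == "decoy_low_at":
                d1 = noisy_copy(rng, spec.cdei_consensus, decoy_rate)
                d2 = at_rich(rng, cls, spec.decoy_at, max_at=spec.decoy_at_max)
                d3 = noisy_copy(rng, spec.cdeiii_consensus, decoy_rate)
                cassettes.append((kind, d1 + d2 + d3,
                                  {"cdeii_length": cls, "cdeii_at": at_percent(d2),
                                   "class_length": cls}))
            else:
                # bare CDEIII site; its upstream context is a low-AT tract,
                # so whatever spurious CDEI spacing the rescan picks, the
                # implied CDEII fails the AT filter
                d3 = noisy_copy(rng, spec.cdeiii_consensus, decoy_rate)
                context = at_rich(rng, spec.upstream_window, spec.decoy_at,
                                  max_at=spec.decoy_at_max)
                cassettes.append((kind, context + d3,
                                  {"cdeii_length": None, "cdeii_at": None,
                                   "class_length": None,
                                   "pad": spec.upstream_window}))

        starts = _place_intervals(rng, spec.chrom_length, spec.margin,
                                  [len(s) for _, s, _ in cassettes],
                                  spec.min_separation)
        seq = np.frombuffer(random_dna(rng, spec.chrom_length,
                                       spec.gc_background).encode(),
                            dtype=np.uint8).copy()
        for (kind, cassette, meta), start in zip(cassettes, starts):
            strand = "+" if rng.random() < 0.5 else "-"
            insert = cassette if strand == "+" else revcomp(cassette)
            seq[start:start + len(insert)] = np.frombuffer(insert.encode(),
                                                           dtype=np.uint8)
            # truth coordinates cover the planted feature itself, not the
            # controlled upstream pad/context
            pad = meta.get("pad", 0)
            if strand == "+":
                fstart, fend = start + pad, start + len(insert)
            else:
                fstart, fend = start, start + len(insert) - pad
            truth_rows.append({
                "kind": kind, "contig": name, "start": fstart,
                "end": fend, "strand": strand,
                "cdeii_length": meta["cdeii_length"],
                "cdeii_at": meta["cdeii_at"],
                "class_length": meta["class_length"],
            })
        records.append((name, seq.tobytes().decode("ascii")))

    truth = pd.DataFrame(truth_rows, columns=[
        "kind", "contig", "start", "end", "strand",
        "cdeii_length", "cdeii_at", "class_length"])
    return records, truth


@dataclass
class MucorPlantSpec:
    """Conditions for a synthetic core-centromere (Mucoromycota-style) genome:
    one motif + AT-run locus per contig."""

    n_loci: int = 10
    contig_length: int = 20_000
    gc_background: float = 0.38
    motif_consensus: str = DEFAULT_MUCOR_CONSENSUS
    motif_noise: float = 0.05
    #: AT-run length -> mixture weight
    at_length_classes: Dict[int, float] = field(default_factory=lambda: {400: 1.0})
    at_fraction: float = 0.90
    #: number of loci planted so close to the contig 3' end that the
    #: downstream sequence is truncated (to this many bp of AT run)
    n_truncated: int = 0
    truncated_downstream: int = 100
    ensure_detectable: bool = True
    detect_min_score_frac: float = 0.7
    p_detect: float = 1e-6
    #: the AT run is followed by a terminator stretch of this many bp whose
    #: realized GC is kept above ``terminator_gc_min`` so the planted AT-region
    #: boundary is real (not blurred into an AT-rich background stretch)
    terminator_length: int = 100
    terminator_gc_min: float = 30.0
    margin: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.at_length_classes.values()) - 1.0) > 1e-9:
            raise ValueError("AT length-class weights must sum to 1")

    def background(self) -> Background:
        gc = self.gc_background
        return Background.user([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def default_mucor_motif(spec: MucorPlantSpec, n_sites: int = 20,
                        pseudocount: float = 0.1) -> Pwm:
    return build_pwm(motif_sites(spec.motif_consensus, n_sites,
                                 spec.motif_noise, seed=spec.seed + 303),
                     pseudocount=pseudocount, name="core_motif")


def make_mucor_genome(spec: MucorPlantSpec
                      ) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """One planted motif + AT-run per contig; the last ``n_truncated`` loci sit
    close enough to the contig end that the AT run is cut short."""
    rng = np.random.default_rng(spec.seed)
    bg = spec.background()
    scanner = (MotifScanner(default_mucor_motif(spec), bg)
               if spec.ensure_detectable else None)
    classes = sorted(spec.at_length_classes)
    weights = np.array([spec.at_length_classes[c] for c in classes])

    records: List[Tuple[str, str]] = []
    rows = []
    for i in range(spec.n_loci):
        name = f"contig{i + 1:02d}"
        truncated = i >= spec.n_loci - spec.n_truncated
        at_len = int(classes[int(rng.choice(len(classes), p=weights))])
        motif = _functional_copy(rng, spec.motif_consensus, spec.motif_noise,
                                 scanner, spec.p_detect,
                                 spec.detect_min_score_frac)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = np.frombuffer(random_dna(rng, spec.contig_length,
                                       spec.gc_background).encode(),
                            dtype=np.uint8).copy()
        if truncated:
            run_len = min(at_len, spec.truncated_downstream)
            cassette = motif + at_rich(rng, run_len, spec.at_fraction)
            # the contig ends (in motif orientation) right after the cut AT run
            if strand == "+":
                cassette_f = cassette
                start = spec.contig_length - len(cassette)
            else:
                cassette_f = revcomp(cassette)
                start = 0
            planted_at = run_len
        else:
            for _ in range(100):
                terminator = random_dna(rng, spec.terminator_length,
                                        spec.gc_background)
                if gc_percent(terminator) >= spec.terminator_gc_min:
                    break
            cassette = (motif + at_rich(rng, at_len, spec.at_fraction)
                        + terminator)
            cassette_f = revcomp(cassette) if strand == "-" else cassette
            lo = spec.margin
            hi = spec.contig_length - spec.margin - len(cassette)
            if hi <= lo:
                raise ValueError("contig too short for the planted locus")
            start = int(rng.integers(lo, hi))
            planted_at = at_len
        seq[start:start + len(cassette_f)] = np.frombuffer(
            cassette_f.encode(), dtype=np.uint8)
        records.append((name, seq.tobytes().decode("ascii")))
        if strand == "+":
            motif_start = start
        else:
            motif_start = start + len(cassette_f) - len(motif)
        rows.append({"contig": name, "motif_start": motif_start,
                     "motif_end": motif_start + len(motif), "strand": strand,
                     "at_length": planted_at, "class_length": at_len,
                     "truncated": truncated})
    truth = pd.DataFrame(rows, columns=["contig", "motif_start", "motif_end",
                                        "strand", "at_length", "class_length",
                                        "truncated"])
    return records, truth


# ---------------------------------------------------------------------------
# strain populations with CDEII length variants
# ---------------------------------------------------------------------------

def microhomology_expand(cdeii: str, delta: int, rng: np.random.Generator
                         ) -> Tuple[str, int]:
    """Lengthen CDEII by tandem-duplicating a ``delta``-bp internal stretch
    (the inserted sequence is an exact copy of the adjacent original
    stretch).  Returns (new sequence, duplication start)."""
    if delta > len(cdeii):
        raise ValueError("delta longer than CDEII")
    pos = int(rng.integers(0, len(cdeii) - delta + 1))
    return cdeii[:pos + delta] + cdeii[pos:], pos


def microhomology_contract(cdeii: str, delta: int, rng: np.random.Generator
                           ) -> Tuple[str, int]:
    """Shorten CDEII by deleting a ``delta``-bp internal stretch."""
    if delta >= len(cdeii):
        raise ValueError("delta must be shorter than CDEII")
    pos = int(rng.integers(0, len(cdeii) - delta + 1))
    return cdeii[:pos] + cdeii[pos + delta:], pos


@dataclass
class Strain:
    name: str
    records: List[Tuple[str, str]]
    truth: pd.DataFrame


def classify_variant_strain(cdeii_lengths: Sequence[int], low: int = 80,
                            high: int = 90) -> bool:
    """A strain is a variant carrier if any centromere's CDEII length falls
    outside the [low, high] bp band."""
    return any(l < low or l > high for l in cdeii_lengths)


def make_strain_population(n_strains: int, variant_fraction: float,
                           variant_delta_bp: int = 10, n_chromosomes: int = 16,
                           chrom_length: int = 4_000,
                           base_cdeii_length: int = 85, seed: int = 0,
                           **spec_overrides) -> Tuple[List[Strain], pd.DataFrame]:
    """A set of strain genomes, each carrying ``n_chromosomes`` centromeres.

    A ``variant_fraction`` of strains carry 1-2 centromeres whose CDEII is
    longer or shorter by ``variant_delta_bp`` via the microhomology
    mechanism.  Returns the strains and a summary table (per strain: planted
    CDEII lengths and variant status).
    """
    if not (0.0 <= variant_fraction <= 1.0):
        raise ValueError("variant_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_variant = int(round(variant_fraction * n_strains))
    variant_ids = set(rng.choice(n_strains, size=n_variant, replace=False).tolist())

    strains: List[Strain] = []
    summary_rows = []
    for s in range(n_strains):
        spec = PlantSpec(n_chromosomes=n_chromosomes, chrom_length=chrom_length,
                         cdeii_length_classes={base_cdeii_length: 1.0},
                         n_decoy_low_at=0, n_decoy_cdeiii_only=0,
                         margin=min(1000, chrom_length // 4),
                         min_separation=200,
                         seed=int(rng.integers(2**31 - 1)), **spec_overrides)
        records, truth = make_point_centromere_genome(spec)
        truth = truth[truth.kind == "centromere"].reset_index(drop=True)
        truth["insert_pos"] = -1
        truth["delta"] = 0
        if s in variant_ids:
            n_var = int(rng.integers(1, 3))  # 1 or 2 variant centromeres
            chroms = rng.choice(n_chromosomes, size=n_var, replace=False)
            for chrom in chroms:
                row = truth.iloc[int(chrom)]
                name, start, end, strand = (row.contig, int(row.start),
                                            int(row.end), row.strand)
                idx = [i for i, (n, _) in enumerate(records) if n == name][0]
                seq = records[idx][1]
                cassette = seq[start:end] if strand == "+" else revcomp(seq[start:end])
                lc1 = len(spec.cdei_consensus)
                lc3 = len(spec.cdeiii_consensus)
                cdei, cdeii, cdeiii = (cassette[:lc1], cassette[lc1:-lc3],
                                       cassette[-lc3:])
                if rng.random() < 0.5:
                    new_cdeii, pos = microhomology_expand(cdeii, variant_delta_bp, rng)
                    delta = variant_delta_bp
                else:
                    new_cdeii, pos = microhomology_contract(cdeii, variant_delta_bp, rng)
                    delta = -variant_delta_bp
                new_cassette = cdei + new_cdeii + cdeiii
                insert = new_cassette if strand == "+" else revcomp(new_cassette)
                records[idx] = (name, seq[:start] + insert + seq[end:])
                truth.loc[truth.contig == name, "cdeii_length"] = len(new_cdeii)
                truth.loc[truth.contig == name, "end"] = start + len(insert)
                truth.loc[truth.contig == name, "insert_pos"] = pos
                truth.loc[truth.contig == name, "delta"] = delta
        strain_name = f"strain{s + 1:03d}"
        strains.append(Strain(strain_name, records, truth))
        lengths = truth.cdeii_length.astype(int).tolist()
        summary_rows.append({
            "strain": strain_name,
            "planted_variant": s in variant_ids,
            "n_variant_centromeres": int(sum(1 for l in lengths
                                             if l != base_cdeii_length)),
            "cdeii_lengths": ",".join(map(str, lengths)),
            "classified_variant": classify_variant_strain(lengths),
        })
    summary = pd.DataFrame(summary_rows)
    return strains, summary
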