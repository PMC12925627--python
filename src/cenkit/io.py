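"""Readers and writers: FASTA, MEME-minimal motifs, sites files, annotation
tables (TSV / GFF3 / BED) and YAML/JSON run configuration.

Coordinates are 0-based half-open everywhere in memory and in BED output;
GFF3 output is 1-based inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import ALPHABET, Background, IUPAC_CODES, Pwm


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> List[Tuple[str, str]]:
    """Multi-FASTA reader (wrapped or unwrapped, case-insensitive).

    Returns (name, uppercased sequence) tuples.  Structural problems are
    reported with a line number; non-IUPAC characters are reported with the
    offending character and record.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected a '>' header before "
                        f"sequence data")
                break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_CODES
        if bad:
            ch = sorted(bad)[0]
            raise ValueError(
                f"{path}: record {rec.id!r} contains non-IUPAC character {ch!r}")
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[Tuple[str, str]], path, width: int = 60) -> None:
    seqrecs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# motif files
# ---------------------------------------------------------------------------

def read_sites(path) -> List[str]:
    """Plain sites file: one aligned site per line; blank lines and '#'
    comments ignored."""
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                sites.append(line.upper())
    if not sites:
        raise ValueError(f"{path}: no sites found")
    return sites


def read_meme_minimal(path) -> Tuple[List[Pwm], Optional[Background]]:
    """MEME minimal motif format: version line, ALPHABET, optional background
    frequencies, and MOTIF blocks with letter-probability matrices.

    Row sums are validated (tolerance 1e-4, then renormalized exactly).
    Returns the motifs in file order plus the file's background, if any.
    """
    path = Path(path)
    lines = Path(path).read_text().splitlines()
    i = 0
    n = len(lines)

    def err(msg):
        return ValueError(f"{path}: {msg}")

    if not any(l.strip().lower().startswith("meme version") for l in lines[:5]):
        raise err("missing 'MEME version' line")
    if not any(l.strip().upper().startswith("ALPHABET") for l in lines):
        raise err("missing ALPHABET line")

    background = None
    pwms: List[Pwm] = []
    while i < n:
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freqs = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = Background.user([freqs[b] for b in ALPHABET])
            i += 1
            continue
        if line.upper().startswith("MOTIF"):
            toks = line.split()
            name = toks[1] if len(toks) > 1 else f"motif{len(pwms) + 1}"
            i += 1
            while i < n and "letter-probability matrix" not in lines[i]:
                if lines[i].strip().upper().startswith("MOTIF"):
                    raise err(f"motif {name!r} has no letter-probability matrix")
                i += 1
            if i >= n:
                raise err(f"motif {name!r} has no letter-probability matrix")
            header = lines[i]
            width = None
            nsites = 0
            toks = header.replace("=", " = ").split()
            for j, t in enumerate(toks):
                if t == "w" and toks[j + 1] == "=":
                    width = int(toks[j + 2])
                if t == "nsites" and toks[j + 1] == "=":
                    nsites = int(float(toks[j + 2]))
            i += 1
            rows = []
            while i < n:
                stripped = lines[i].strip()
                if not stripped or stripped.upper().startswith(("MOTIF", "URL")):
                    break
                vals = [float(x) for x in stripped.split()]
                if len(vals) != 4:
                    raise err(f"motif {name!r}: matrix row {len(rows) + 1} has "
                              f"{len(vals)} values, expected 4")
                rows.append(vals)
                i += 1
            if width is not None and len(rows) != width:
                raise err(f"motif {name!r}: expected {width} rows, found {len(rows)}")
            probs = np.array(rows, dtype=np.float64)
            sums = probs.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-4
            if bad.any():
                r = int(np.nonzero(bad)[0][0])
                raise err(f"motif {name!r}: probability row {r + 1} sums to "
                          f"{sums[r]:.6g}, not 1")
            probs = probs / sums[:, None]
            pwms.append(Pwm(name=name, probs=probs, pseudocount=0.0,
                            n_sites=nsites))
            continue
        i += 1
    if not pwms:
        raise err("no MOTIF blocks found")
    return pwms, background


def write_meme_minimal(pwms: Sequence[Pwm], path,
                       background: Optional[Background] = None) -> None:
    """Write motifs in MEME minimal format (6-decimal probabilities)."""
    bg = background.freqs if background is not None else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                     f"nsites= {max(pwm.n_sites, 1)} E= 0\n")
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_motif(path, pseudocount: float = 0.1) -> Pwm:
    """Load one motif from either a MEME minimal file or a plain sites file
    (detected from the content)."""
    from .motifs import build_pwm

    text = Path(path).read_text()
    if "meme version" in text.lower():
        pwms, _ = read_meme_minimal(path)
        return pwms[0]
    return build_pwm(read_sites(path), pseudocount=pseudocount,
                     name=Path(path).stem)


# ---------------------------------------------------------------------------
# annotation output
# ---------------------------------------------------------------------------

def _subfeatures(call):
    """(label, fwd_start, fwd_end) for CDEI/CDEII/CDEIII of one call."""
    lc1, lc2 = len(call.cdei_seq), len(call.cdeii_seq)
    lc3 = len(call.cdeiii_seq)
    if call.orientation == "+":
        cdei = (call.start, call.start + lc1)
        cdeii = (call.start + lc1, call.start + lc1 + lc2)
        cdeiii = (call.end - lc3, call.end)
    else:
        cdei = (call.end - lc1, call.end)
        cdeii = (call.end - lc1 - lc2, call.end - lc1)
        cdeiii = (call.start, call.start + lc3)
    return [("CDEI", *cdei), ("CDEII", *cdeii), ("CDEIII", *cdeiii)]


def write_annotation(result, fmt: str, path, keep_removed: bool = False) -> None:
    """Write an :class:`~cenkit.annotate.AnnotationResult` as TSV, GFF3 or BED.

    TSV mirrors the per-centromere table schema; GFF3 is 1-based inclusive
    with a ``centromere`` parent and CDEI/CDEII/CDEIII children; BED is
    0-based half-open.  Removed candidates are included only with
    ``keep_removed``.
    """
    if fmt == "tsv":
        from .annotate import build_table
        table = build_table(result.calls, result.config,
                            int(result.table.genome_size.iloc[0]) if len(result.table) else 0,
                            keep_removed=keep_removed)
        table.to_csv(path, sep="\t", index=False)
        return

    calls = sorted((c for c in result.calls
                    if c.retained or keep_removed),
                   key=lambda c: (c.contig, c.start))
    if fmt == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, c in enumerate(calls, start=1):
                cid = f"CEN{i}"
                attrs = (f"ID={cid};cdeii_length={c.cdeii_length};"
                         f"cdeii_at={c.cdeii_at:.2f};status={c.status}")
                fh.write("\t".join([
                    c.contig, "cenkit", "centromere", str(c.start + 1),
                    str(c.end), f"{c.combined_score:.4f}", c.orientation, ".",
                    attrs]) + "\n")
                for label, s, e in _subfeatures(c):
                    fh.write("\t".join([
                        c.contig, "cenkit", label, str(s + 1), str(e),
                        ".", c.orientation, ".",
                        f"ID={cid}.{label};Parent={cid}"]) + "\n")
    elif fmt == "bed":
        with open(path, "w") as fh:
            for i, c in enumerate(calls, start=1):
                cid = f"CEN{i}"
                fh.write("\t".join([
                    c.contig, str(c.start), str(c.end), cid,
                    f"{c.combined_score:.4f}", c.orientation]) + "\n")
                for label, s, e in _subfeatures(c):
                    fh.write("\t".join([
                        c.contig, str(s), str(e), f"{cid}.{label}",
                        ".", c.orientation]) + "\n")
    else:
        raise ValueError(f"unknown annotation format {fmt!r} "
                         "(expected tsv, gff3 or bed)")


def load_config(path) -> dict:
    """YAML (or JSON) run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
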