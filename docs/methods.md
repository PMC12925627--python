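# Methods

## Motif model and scoring

Motifs (CDEI, CDEIII, the Mucoromycota core motif) are position weight
matrices over A, C, G, T. Built from `n` aligned sites with pseudocount
`c` (default 0.1), entry *(i, b)* is `(count(b at i) + c/4) / (n + c)`;
`N` in a site contributes 0.25 to each base. A window scores the sum of
per-position log₂ likelihood ratios against a 0-order background model.
The background defaults to frequencies estimated from the scanned assembly
(pooled contigs, ambiguity codes ignored, floored at 10⁻⁶ and
renormalized); uniform and user-supplied backgrounds are available.

P-values are exact for a discretized score: each log-odds entry is floored
onto an integer grid (1,000 bins spanning the widest per-position score
range, one global scale so that real scores map to grid levels), and the
distribution of the integer score of a background-random word is obtained
by per-position convolution. `P(score ≥ s)` comes from the reversed
cumulative sum; reported p-values use the floor of the observed score, so
they are conservative, with a score discretization error bounded by
width/scale bits (≈ 0.2 bits for a 26-wide motif). For widths ≤ 8 the
table is bit-identical to exhaustive enumeration of all 4^w words, which
the test suite checks.

Scanning evaluates every window on the forward strand and, for the minus
strand, the same positions under the reverse-complemented matrix, which is
equivalent to scoring the reverse complement of each window. Windows
containing any non-ACGT character are skipped rather than scored —
fragmented assemblies contain gap runs, and a partially defined window has
no meaningful score. Coordinates are 0-based half-open on the forward
strand everywhere in memory and in BED output; GFF3 output is 1-based
inclusive. All overlapping hits are reported at this layer; resolution
happens downstream.

## Point-centromere annotation

Stage one scans both strands with the CDEIII matrix (default threshold
10⁻⁵, the midpoint of the useful 10⁻³–10⁻⁷ range; per-clade overrides
belong in the run configuration). Each hit yields a candidate window of
the motif plus 224 bp upstream in centromere orientation; hits with less
upstream sequence than that are dropped and counted. Stage two rescans
each window with the CDEI matrix at 10⁻², forward orientation only,
keeping hits that end before the CDEIII start; with several matches the
best score wins and ties go to the 5′-most match (a deterministic rule —
the data do not identify which of two equal matches is functional). CDEII
is the subsequence strictly between CDEI end and CDEIII start; its AT%
excludes ambiguous bases from numerator and denominator.

The combined score is a max-normalized weighted sum,
`w₁·(score_CDEIII/max) + w₂·(score_CDEI/max) + w₃·(AT%/100)` with default
weights (1, 1, 1): scale-free, strictly increasing in each component, and
equal to `Σwᵢ` for a perfect-consensus call with 100% AT. The filter
cascade then runs in order: (1) top 50 by combined score; (2) remove calls
whose CDEII length deviates more than 30 nt from the median of the top 5
(all available when fewer than 5 survive); (3) remove CDEII AT < 70%;
(4) remove duplicates — identical full sequence, or >50% coordinate
overlap on the same contig and strand — keeping the higher score, ties to
the lexicographically smaller (contig, start); (5) recompute length and AT
medians over survivors and remove calls deviating in *both* length
(outside median ± 10 nt) and AT (below median − 7). The joint rule is a
strict AND: a call failing only one criterion is kept. Medians of
even-sized sets are midpoint medians. The karyotype estimate is the number
of retained calls.

## Core-centromere annotation

A single motif search (default threshold 10⁻⁶ — a 41-bp motif supports
higher specificity and no filter cascade follows) extends each hit by up
to 750 bp downstream in motif orientation, truncating at contig ends with
a flag. GC content is profiled with a 100-bp moving window at 1-bp step
(configurable); windows with more than 50% ambiguous bases are omitted and
the denominator excludes ambiguous bases. The AT-region length is the
maximal run of consecutive windows from offset 0 with GC ≤ 25%, reported
as `(run − 1)·step + window` bp and capped at the downstream length; 0
when the first window exceeds the cutoff. The 25% cutoff makes an
explicit, testable rule out of what is otherwise a visual call; it sits
midway between the AT-run composition (~10% GC) and genomic background
(~38% GC), so the estimate lands within one window of the true boundary —
the tests assert exactly that. Calls with a positive AT-region estimate
are flagged bona fide; bare motif matches without one are chance hits and
are excluded from centromere numbering. Iterative refinement rebuilds the
matrix from the matched sites of the current hit set and rescans until the
hit set is unchanged (at most 10 iterations).

## Transition simulations

A genome carries `n` centromeres of type A or B (haploid n = 16, diploid
n = 32). Each step picks one centromere uniformly and sets it to A with
the retention probability `p`, to B otherwise — regardless of its current
type, so `p` is the per-event probability that the ancestral type is
retained or restored. Draws use a real uniform by default; the historical
scheme of integers 0–999 compared with `round(1000·p)` is available via
`integer_draws` and is distributionally identical at 3-decimal
granularity. Lineage runs are vectorized across replicates and fully
reproducible from the config seed (default constant 715).

An exact oracle tracks the (n+1)-state Markov chain on the B-count k:
up-transitions with probability `(n−k)/n · (1−p)`, down with `k/n · p`.
Simulator state frequencies at 10,000 replicates are compared with the
matrix-power probabilities within 4 standard errors plus a 3-count
allowance — the allowance corrects the normal approximation for states
with expected counts of order one, where 4·SE under-covers the Poisson
tail. At `p = 0` the absorption time to all-B is a coupon-collector
problem with mean `n·H_n` (≈ 54.09 for n = 16), which the simulator
reproduces. Two boundary facts anchor the biology: at pure drift
(p = 0.5) the exact full-transition probability after 1,000 steps is
~1.5 × 10⁻⁵ for 16 centromeres (and ~2 × 10⁻¹⁰ for 32) — new centromere
types do not fix without selection — while at p = 0.01 it exceeds 0.85.

The population model holds 100 diploid individuals (16 chromosome pairs).
Each iteration applies `mutations_per_step` mutation events (a random
individual, chromosome pair, and chromatid each), then, when meiosis is
enabled, every individual reassorts every chromosome: one of its own
chromatids is kept (uniformly) and the partner is drawn uniformly, with
replacement, from the population-wide pool of 2N chromatids at that
chromosome, as a synchronous update. Drawing from the full pool including
the focal individual is the default; exclusion of own chromatids is a
flag. The update is synchronous by design: a sequential update would make
the outcome depend on an arbitrary individual ordering.

`mutations_per_step` defaults to 1. For the meiosis-contrast experiment
that default is uninformative: 500 steps then supply at most 500 variant
alleles for 3,200 chromatid slots, so no individual can ever carry 32
variant centromeres and both conditions trivially report zero. The
contrast experiment therefore uses 16 events per step (~2.5 expected hits
per chromatid over a 500-step run), the regime in which the phenomenon is
expressed: without reassortment each individual must independently
accumulate all 32 variants, while reassortment lets population-frequency
fluctuations assemble fully transitioned individuals. The effect is
heavy-tailed — reassortment yields more zero replicates but far larger
positive outcomes — so rank tests misread it; the acceptance check uses a
one-sided Welch test on the per-replicate count of fully transitioned
individuals at 2,000 replicates, where the advantage (~2× the mean) is
significant at p ≪ 10⁻²⁰.

## Synthetic genomes

Background sequence is i.i.d. with configurable GC (default 38%,
yeast-like); no repeat families are modelled — sufficient for testing a
0-order scanner and the cascade, and deliberately free of the repeat
structure real assemblies have. Each chromosome (default 16 × 750 kb)
carries exactly one planted centromere at a random interior position and
strand: a noisy CDEI copy, an AT-rich CDEII drawn from a configurable
length-class mixture (default 85 bp, AT target 92%), and a noisy CDEIII
copy. Per-position substitution noise is 0.05.

Three constraints keep the truth table true rather than merely plausible:

* **Functional sites stay functional.** Planted motif copies are redrawn
  until their calibrated p-value passes the detection threshold *and*
  their score keeps ≥ 70% of the maximum — selection maintains
  binding-competent sites, and a planted "centromere" whose CDEI no
  longer matches its own motif would be a mislabelled truth entry.
  Decoy motif copies are under no such constraint and erode at twice the
  substitution rate.
* **Windows are unambiguous.** The upstream pad and the CDEII spacer are
  redrawn if a chance CDEI-like match inside the 224-bp candidate window
  outscores (or 5′-ties) the planted site, so the planted coordinates are
  the unique best reading of their own window.
* **Realized composition respects the planted class.** Functional CDEII
  spacers are redrawn to ≥ 90% realized AT (the 90–95% range of real
  point-centromere spacers) and decoy spacers/contexts to ≤ 60%, so
  binomial sampling noise cannot carry a short planted sequence across
  the annotation filters' 70% / median−7 cutoffs in either direction.

Decoys (default 40 + 20 ≥ the 40 used in the recovery experiments) come in
two kinds: full cassettes with a low-AT spacer (caught by the AT filter)
and bare CDEIII sites planted in a low-AT context tract (caught by the
top-N or AT filters). Mucoromycota-style genomes plant one motif + AT-run
locus per contig (runs 90% AT, default 400 bp, optional truncation at
contig ends) followed by a 100-bp terminator stretch constrained to ≥ 30%
GC so the planted AT-region boundary is a real boundary. Strain
populations plant identical 85-bp-CDEII genomes and give a configurable
fraction of strains 1–2 variant centromeres whose CDEII is lengthened by
tandem-duplicating an internal stretch (microhomology-style: the insert is
a verbatim copy of the adjacent sequence) or shortened by deletion; a
CDEII-length band classifier (<80 or >90 bp) recovers the planted variant
strains exactly.

What passing tests on these genomes show: the scanner, window logic,
cascade, and estimators implement their specifications and recover planted
truth at realistic composition, scale, and noise. What they do not show:
robustness to repeat families, assembly artefacts beyond gap runs and
truncated contigs, or motif divergence beyond the modelled substitution
noise — real-assembly performance still depends on choosing clade-
appropriate motifs and thresholds.

## Numerical and interface choices

Discretized p-values are floors (conservative). Even-length medians are
midpoints. Degenerate inputs: empty candidate lists pass through the
cascade; windows shorter than the GC window give empty profiles; empty or
all-ambiguous sequences have AT/GC of 0. Annotation output is deterministic
and diff-stable for fixed inputs; every CLI run logs the tool version, a
configuration hash, and per-filter removal counts to stderr. TSV output
mirrors the per-centromere table schema (species, assembly, genome size,
contig, centromere number, full/CDEI/CDEIII/CDEII sequences, CDEII length
and AT); GFF3 uses a `centromere` parent with CDEI/CDEII/CDEIII children.

## Known limitations

No synteny or homology verification is built in (flanking-sequence export
supports external checks); no higher-order background models; no
q-value/multiple-testing layer (fixed p thresholds by design); the
population model has no explicit fitness, recombination map, or
centromere-drive asymmetry. The AT-region estimator assumes the AT tract
begins immediately downstream of the motif.
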