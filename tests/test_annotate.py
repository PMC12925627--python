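"""Point-centromere pipeline: window extraction, CDEI attachment, combined
scoring, the filter cascade, and end-to-end annotation."""

import numpy as np
import pytest

from cenkit.annotate import (AnnotateConfig, CentromereCall, annotate_genome,
                             attach_cdei, build_table, combined_score,
                             extract_windows, filter_cascade, score_calls)
from cenkit.motifs import Background, revcomp
from cenkit.synth import (PlantSpec, default_motifs,
                          make_point_centromere_genome, random_dna)

CDEI = "GTCACGTG"
CDEIII = "TGTATTTGATTTCCGAAAGTTAAAAA"


def _contig_with_site(site, pos, length=8000, seed=0):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, length, gc=0.5)
    return seq[:pos] + site + seq[pos + len(site):]


# ---------------------------------------------------------------------------
# extract_windows
# ---------------------------------------------------------------------------

class TestExtractWindows:
    def test_window_coordinates_for_forward_hit(self, cdeiii_pwm, uniform_bg):
        seq = _contig_with_site(CDEIII, 5000)
        windows, dropped = extract_windows([("c", seq)], cdeiii_pwm,
                                           uniform_bg, 1e-7)
        assert dropped == 0
        assert len(windows) == 1
        w = windows[0]
        assert (w.window_start, w.window_end) == (4776, 5026)
        assert len(w.window_seq) == 224 + cdeiii_pwm.width
        assert w.window_seq.endswith(CDEIII)

    def test_hit_near_contig_edge_dropped_and_counted(self, cdeiii_pwm,
                                                      uniform_bg):
        seq = _contig_with_site(CDEIII, 100)
        windows, dropped = extract_windows([("c", seq)], cdeiii_pwm,
                                           uniform_bg, 1e-7)
        assert windows == []
        assert dropped == 1

    def test_minus_strand_window_reverse_complemented(self, cdeiii_pwm,
                                                      uniform_bg):
        seq = _contig_with_site(revcomp(CDEIII), 5000)
        windows, _ = extract_windows([("c", seq)], cdeiii_pwm, uniform_bg, 1e-7)
        assert len(windows) == 1
        w = windows[0]
        assert w.orientation == "-"
        assert w.window_seq.endswith(CDEIII)
        assert (w.window_start, w.window_end) == (5000, 5000 + 26 + 224)


# ---------------------------------------------------------------------------
# attach_cdei
# ---------------------------------------------------------------------------

class TestAttachCdei:
    def _make_window(self, window_seq, contig="c", start=1000):
        from cenkit.annotate import CandidateWindow
        from cenkit.motifs import MotifHit
        cdeiii_start = len(window_seq) - 26
        hit = MotifHit(contig, start + cdeiii_start, start + len(window_seq),
                       "+", 40.0, 1e-9, window_seq[cdeiii_start:])
        return CandidateWindow(contig, start, start + len(window_seq), "+",
                               window_seq, hit)

    def test_planted_at_spacer_measured_exactly(self, cdei_pwm, uniform_bg):
        spacer = "AT" * 42 + "A"  # 85 bp, all A/T
        pad = random_dna(np.random.default_rng(1), 224 - 8 - 85, gc=0.5)
        win = self._make_window(pad + CDEI + spacer + CDEIII)
        calls = attach_cdei([win], cdei_pwm, uniform_bg)
        assert len(calls) == 1
        call = calls[0]
        assert call.cdeii_length == 85
        assert call.cdeii_at == pytest.approx(100.0)
        assert call.cdei_seq == CDEI
        assert call.cdeiii_seq == CDEIII
        assert call.full_seq == CDEI + spacer + CDEIII
        assert call.start == 1000 + len(pad)
        assert call.cdeii_length == (len(call.full_seq) - len(call.cdei_seq)
                                     - len(call.cdeiii_seq))

    def test_window_without_cdei_match_dropped(self, cdei_pwm, uniform_bg):
        win = self._make_window("G" * 100 + "C" * 124 + CDEIII)
        assert attach_cdei([win], cdei_pwm, uniform_bg) == []

    def test_best_scoring_cdei_wins_over_weaker_match(self, cdei_pwm,
                                                      uniform_bg):
        weak = "GTCACGTA"  # one mismatch
        filler = "C" * 20
        win = self._make_window(
            filler + weak + "C" * 50 + CDEI + "AT" * 59 + CDEIII)
        calls = attach_cdei([win], cdei_pwm, uniform_bg)
        assert len(calls) == 1
        # oracle: enumerate every in-window placement and keep the best score
        from cenkit.motifs import MotifScanner
        scanner = MotifScanner(cdei_pwm, uniform_bg)
        seq = win.window_seq
        best = max(range(len(seq) - 26 - 8 + 1),
                   key=lambda j: (scanner.word_score(seq[j:j + 8])
                                  if set(seq[j:j + 8]) <= set("ACGT") else -1e9))
        assert calls[0].cdei_seq == seq[best:best + 8] == CDEI

    def test_minus_strand_coordinates(self, cdei_pwm, cdeiii_pwm, uniform_bg):
        cassette = CDEI + "AT" * 42 + "A" + CDEIII
        pad = 224 - 8 - 85
        seq = _contig_with_site(revcomp(cassette), 3000, seed=9)
        windows, _ = extract_windows([("c", seq)], cdeiii_pwm, uniform_bg, 1e-7)
        assert len(windows) == 1
        calls = attach_cdei(windows, cdei_pwm, uniform_bg)
        assert len(calls) == 1
        call = calls[0]
        assert call.orientation == "-"
        assert call.full_seq == cassette
        # forward-strand span covers the reverse-complemented cassette
        assert seq[call.start:call.end] == revcomp(cassette)


# ---------------------------------------------------------------------------
# combined score
# ---------------------------------------------------------------------------

def _call(cdeii_length=85, cdeii_at=92.0, score_cdei=10.0, score_cdeiii=40.0,
          contig="c", start=0, full_seq=None, orientation="+", spacing=1000):
    # crafted calls are spaced out so the duplicate (overlap) rule only
    # triggers where a test constructs an overlap on purpose
    start = start * spacing
    end = start + 8 + cdeii_length + 26
    return CentromereCall(
        contig=contig, start=start, end=end, orientation=orientation,
        full_seq=full_seq or f"{contig}:{start}", cdei_seq="G" * 8,
        cdeii_seq="A" * cdeii_length, cdeiii_seq="T" * 26,
        cdeii_length=cdeii_length, cdeii_at=cdeii_at,
        score_cdei=score_cdei, score_cdeiii=score_cdeiii)


class TestCombinedScore:
    def test_perfect_call_scores_sum_of_weights(self):
        call = _call(cdeii_at=100.0, score_cdei=10.0, score_cdeiii=40.0)
        assert combined_score(call, (1, 1, 1), max_cdei=10.0,
                              max_cdeiii=40.0) == pytest.approx(3.0)

    def test_linear_in_at_content(self):
        a = _call(cdeii_at=90.0)
        b = _call(cdeii_at=80.0)
        w3 = 2.0
        diff = (combined_score(a, (1, 1, w3), max_cdei=10, max_cdeiii=40)
                - combined_score(b, (1, 1, w3), max_cdei=10, max_cdeiii=40))
        assert diff == pytest.approx(0.1 * w3)

    def test_ranking_matches_independent_recomputation(self):
        rng = np.random.default_rng(2)
        calls = [_call(cdeii_at=float(rng.uniform(60, 100)),
                       score_cdei=float(rng.uniform(0, 10)),
                       score_cdeiii=float(rng.uniform(0, 40)),
                       start=i) for i in range(10)]
        for c in calls:
            c.combined_score = combined_score(c, (1, 1, 1), max_cdei=10,
                                              max_cdeiii=40)
        manual = [c.score_cdeiii / 40 + c.score_cdei / 10 + c.cdeii_at / 100
                  for c in calls]
        assert ([c.start for c in sorted(calls, key=lambda c: -c.combined_score)]
                == [c.start for _, c in
                    sorted(zip(manual, calls), key=lambda t: -t[0])])


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

def _scored(calls):
    for c in calls:
        if c.combined_score is None:
            c.combined_score = combined_score(c, (1, 1, 1), max_cdei=10,
                                              max_cdeiii=40)
    return calls


class TestFilterCascade:
    def test_empty_input(self):
        assert filter_cascade([]) == []

    def test_requires_combined_score(self):
        with pytest.raises(ValueError, match="combined_score"):
            filter_cascade([_call()])

    def test_top50_rule_removes_lowest_scored(self):
        calls = _scored([_call(score_cdei=float(i) / 6, start=i)
                         for i in range(60)])
        out = filter_cascade(calls)
        removed = [c for c in out if c.status == "removed:top50"]
        assert len(removed) == 10
        assert {c.start for c in removed} == {i * 1000 for i in range(10)}

    def test_length_outlier_rule_uses_top5_median(self):
        # top-5 by score have lengths 85; a 116-bp call differs by 31 (>30)
        # and a 115-bp call by 30 (boundary, kept)
        calls = [_call(score_cdei=10, cdeii_length=85, start=i) for i in range(5)]
        calls.append(_call(score_cdei=1, cdeii_length=116, start=5))
        calls.append(_call(score_cdei=1, cdeii_length=115, start=6))
        out = filter_cascade(_scored(calls))
        by_start = {c.start: c.status for c in out}
        assert by_start[5000] == "removed:length_outlier"
        assert by_start[6000] == "retained"

    def test_at_content_rule_boundary(self):
        calls = _scored([_call(cdeii_at=69.9, start=0),
                         _call(cdeii_at=70.0, start=1),
                         _call(cdeii_at=92.0, start=2)])
        out = filter_cascade(calls)
        assert {c.start: c.status for c in out} == {
            0: "removed:at_content", 1000: "retained", 2000: "retained"}

    def test_identical_sequences_deduplicated_across_contigs(self):
        a = _call(contig="c1", full_seq="SAME", start=0)
        b = _call(contig="c2", full_seq="SAME", start=0)
        c = _call(contig="c3", full_seq="OTHER", start=0)
        out = filter_cascade(_scored([a, b, c]))
        statuses = sorted(x.status for x in (a, b))
        assert statuses == ["removed:duplicate", "retained"]
        assert a.status == "retained"  # tie -> lexicographically smaller contig
        assert c.status == "retained"

    def test_overlapping_calls_same_contig_deduplicated(self):
        a = _call(contig="c", start=100, score_cdei=10, spacing=1)
        b = _call(contig="c", start=110, score_cdei=5, spacing=1)  # >50% overlap, weaker
        out = filter_cascade(_scored([a, b]))
        assert a.status == "retained"
        assert b.status == "removed:duplicate"

    def test_joint_rule_requires_both_conditions(self):
        # median length 85, median AT ~92
        base = [_call(start=i) for i in range(10)]
        long_only = _call(cdeii_length=97, cdeii_at=90.0, start=10)
        low_at_only = _call(cdeii_length=85, cdeii_at=84.0, start=11)
        both = _call(cdeii_length=97, cdeii_at=84.0, start=12)
        out = filter_cascade(_scored(base + [long_only, low_at_only, both]))
        assert long_only.status == "retained"     # length off, AT fine
        assert low_at_only.status == "retained"   # AT off, length fine
        assert both.status == "removed:length_at_joint"

    def test_planted_truth_bookkeeping(self):
        """16 true calls plus 40 low-AT decoys: exactly the 16 retained,
        decoys flagged by the AT rule or the top-N cut."""
        true_calls = [_call(contig=f"t{i}", score_cdei=9.0, cdeii_at=93.0,
                            start=i) for i in range(16)]
        decoys = [_call(contig=f"d{i}", score_cdei=8.0, cdeii_at=55.0,
                        start=i) for i in range(40)]
        out = filter_cascade(_scored(true_calls + decoys))
        assert all(c.status == "retained" for c in true_calls)
        decoy_statuses = {c.status for c in decoys}
        assert decoy_statuses <= {"removed:at_content", "removed:top50"}
        assert sum(1 for c in out if c.status == "retained") == 16

    def test_retained_calls_satisfy_rules_when_rechecked(self, toy_result):
        from statistics import median
        retained = [c for c in toy_result.calls if c.retained]
        assert retained
        med_len = median(c.cdeii_length for c in retained)
        med_at = median(c.cdeii_at for c in retained)
        for c in retained:
            assert c.cdeii_at >= 70.0
            assert not (abs(c.cdeii_length - med_len) > 10
                        and c.cdeii_at < med_at - 7)


# ---------------------------------------------------------------------------
# end-to-end annotation
# ---------------------------------------------------------------------------

class TestAnnotateGenome:
    def test_recall_precision_karyotype_on_planted_genome(self, toy_spec,
                                                          toy_genome,
                                                          toy_result):
        records, truth = toy_genome
        tt = truth[truth.kind == "centromere"]
        true_keys = set(zip(tt.contig, tt.start))
        retained = toy_result.table[toy_result.table.status == "retained"]
        called = set(zip(retained.contig, retained.start))
        assert called == true_keys
        assert toy_result.karyotype == toy_spec.n_chromosomes

    def test_per_genome_cdeii_length_homogeneity(self, toy_result):
        lengths = [c.cdeii_length for c in toy_result.calls if c.retained]
        assert np.std(lengths) == 0.0  # single planted class, no jitter

    def test_zero_planted_motifs_gives_empty_karyotype(self):
        rng = np.random.default_rng(31)
        records = [(f"c{i}", random_dna(rng, 30_000, gc=0.38))
                   for i in range(4)]
        spec = PlantSpec(seed=31)
        cdei, cdeiii = default_motifs(spec)
        res = annotate_genome(records, AnnotateConfig(cdei=cdei, cdeiii=cdeiii))
        assert res.karyotype == 0
        assert len(res.table) == 0

    def test_determinism_byte_identical_tables(self, toy_spec, toy_genome):
        records, _ = toy_genome
        cdei, cdeiii = default_motifs(toy_spec)
        cfg = AnnotateConfig(cdei=cdei, cdeiii=cdeiii)
        a = annotate_genome(records, cfg).table.to_csv(sep="\t")
        b = annotate_genome(records, cfg).table.to_csv(sep="\t")
        assert a == b

    def test_tightening_threshold_never_adds_calls(self, toy_spec, toy_genome):
        records, _ = toy_genome
        cdei, cdeiii = default_motifs(toy_spec)
        counts = []
        for p in (1e-3, 1e-5, 1e-7):
            cfg = AnnotateConfig(cdei=cdei, cdeiii=cdeiii, p_cdeiii=p)
            counts.append(annotate_genome(records, cfg).karyotype)
        assert counts[0] >= counts[1] >= counts[2]

    def test_two_planted_length_classes_both_retained(self):
        spec = PlantSpec(n_chromosomes=8, chrom_length=80_000, seed=41,
                         cdeii_length_classes={50: 0.5, 61: 0.5},
                         n_decoy_low_at=12, n_decoy_cdeiii_only=6,
                         margin=2_000)
        records, truth = make_point_centromere_genome(spec)
        cdei, cdeiii = default_motifs(spec)
        res = annotate_genome(records, AnnotateConfig(cdei=cdei, cdeiii=cdeiii))
        retained = res.table[res.table.status == "retained"]
        assert set(retained.cdeii_length) == {50, 61}
        assert res.karyotype == 8

    def test_table_schema_and_numbering(self, toy_result):
        from cenkit.annotate import TABLE_COLUMNS
        table = toy_result.table
        assert list(table.columns) == TABLE_COLUMNS
        retained = table[table.status == "retained"]
        assert list(retained.centromere_number) == list(
            range(1, len(retained) + 1))
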