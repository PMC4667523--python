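"""PWM scanning, enrichment, and inducible-binding fractions."""

import numpy as np
import pytest

from remodelscan.genomic_signal import GenomicInterval
from remodelscan.mode_classifier import ModeCall, RemodelingSegment
from remodelscan.motif_scan import (MotifHit, Pwm, default_pwms,
                                    extract_noncentral_sequences,
                                    hits_from_bed, hits_to_bed,
                                    inducible_binding_fraction,
                                    motif_enrichment, pwm_from_consensus,
                                    scan_pwm)
from conftest import anchor

BASES = "ACGT"
COMP = str.maketrans("ACGTN", "TGCAN")


def random_seq(rng, n):
    return "".join(rng.choice(list(BASES), n))


def brute_force_hits(seq, pwm):
    """Position-by-position scorer, fully independent of the implementation."""
    hits = []
    for strand in "+-":
        for start in range(len(seq) - pwm.width + 1):
            window = seq[start:start + pwm.width]
            if strand == "-":
                window = window.translate(COMP)[::-1]
            score = 0.0
            for j, base in enumerate(window):
                if base in BASES:
                    score += pwm.matrix[BASES.index(base), j]
            if score >= pwm.threshold:
                hits.append((start, start + pwm.width, strand, round(score, 9)))
    return sorted(hits)


class TestScanPwm:
    ets = staticmethod(lambda: default_pwms()["ETS"])

    def test_planted_consensus_found_at_position(self, rng):
        pwm = pwm_from_consensus("M", "ACGTACGT")
        seq = random_seq(rng, 60)
        seq = seq[:17] + "ACGTACGT" + seq[25:]
        starts = [h.start for h in scan_pwm(seq, pwm) if h.strand == "+"]
        assert 17 in starts

    def test_reverse_complement_symmetry(self, rng):
        pwm = default_pwms()["ETS"]
        seq = random_seq(rng, 80)
        seq = seq[:30] + "ACAGGAAG" + seq[38:]
        fwd = scan_pwm(seq, pwm)
        rc = seq.translate(COMP)[::-1]
        rev = scan_pwm(rc, pwm)
        mirrored = sorted((len(seq) - h.end, len(seq) - h.start,
                           "+" if h.strand == "-" else "-") for h in rev)
        assert mirrored == sorted((h.start, h.end, h.strand) for h in fwd)

    def test_all_n_sequence_has_no_hits(self):
        pwm = default_pwms()["GRE"]
        assert scan_pwm("N" * 100, pwm) == []

    def test_agrees_with_bruteforce_on_random_sequences(self, rng):
        pwm = Pwm("loose", default_pwms()["RUNX"].matrix, threshold=4.0)
        for _ in range(50):
            seq = random_seq(rng, 200)
            got = sorted((h.start, h.end, h.strand, round(h.score, 9))
                         for h in scan_pwm(seq, pwm))
            assert got == brute_force_hits(seq, pwm)

    def test_deterministic_order(self, rng):
        pwm = Pwm("loose", default_pwms()["ETS"].matrix, threshold=0.0)
        seq = random_seq(rng, 50)
        hits = scan_pwm(seq, pwm)
        keys = [(h.start, h.strand) for h in hits]
        assert keys == sorted(keys)

    def test_bed_roundtrip_preserves_coordinates(self, tmp_path, rng):
        pwm = default_pwms()["ETS"]
        seq = random_seq(rng, 300) + "ACAGGAAG" + random_seq(rng, 20)
        hits = scan_pwm(seq, pwm, chrom="chr3", offset=1000)
        assert hits
        hits_to_bed(hits, tmp_path / "hits.bed")
        back = hits_from_bed(tmp_path / "hits.bed")
        assert [(h.chrom, h.start, h.end, h.strand) for h in back] == \
               [(h.chrom, h.start, h.end, h.strand) for h in hits]


class TestExtractSequences:
    def make_call(self, mode, site="s0"):
        return ModeCall(site=site, cluster=0, mode=mode, central_loss=False,
                        flank_losses=(0, 0), alternations=(0, 0),
                        footprint=None)

    def test_coordinates_converted_to_absolute(self):
        genome = {"chr1": "A" * 10_400 + "G" * 200 + "A" * 2000}
        segs = {"s0": [RemodelingSegment(400, 600, "loss", -1.0)]}
        pairs = extract_noncentral_sequences(
            [self.make_call("non_central")], segs, [anchor(10_000, name="s0")],
            genome)
        assert pairs == [("s0", "G" * 200)]

    def test_central_sites_contribute_nothing(self):
        genome = {"chr1": "A" * 20_000}
        segs = {"s0": [RemodelingSegment(-100, 100, "loss", -1.0)]}
        assert extract_noncentral_sequences(
            [self.make_call("central")], segs,
            [anchor(10_000, name="s0")], genome) == []

    def test_footprint_overlapping_segment_excluded(self):
        genome = {"chr1": "A" * 20_000}
        segs = {"s0": [RemodelingSegment(100, 400, "loss", -1.0),
                       RemodelingSegment(500, 700, "loss", -1.0)]}
        pairs = extract_noncentral_sequences(
            [self.make_call("non_central")], segs,
            [anchor(10_000, name="s0")], genome)
        assert len(pairs) == 1  # only the fully-outside segment


class TestEnrichment:
    def test_identical_sets_not_enriched(self, rng):
        pwm = default_pwms()["ETS"]
        seqs = [random_seq(rng, 100) + "ACAGGAAG" for _ in range(5)]
        odds, p = motif_enrichment(seqs, list(seqs), pwm)
        assert odds == pytest.approx(1.0) and p == 1.0

    def test_full_separation_matches_hypergeometric(self, rng):
        import math
        pwm = default_pwms()["ETS"]
        targets = ["TTTT" + "ACAGGAAG" + "TTTT" for _ in range(10)]
        background = ["T" * 16 for _ in range(10)]
        _, p = motif_enrichment(targets, background, pwm)
        # all 10 targets hit, 0 of 10 background: p = 2 / C(20, 10)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_degenerate_table_warns_p_one(self, rng):
        pwm = default_pwms()["GRE"]
        with pytest.warns(UserWarning, match="degenerate"):
            _, p = motif_enrichment(["T" * 30], ["T" * 30], pwm)
        assert p == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            motif_enrichment([], ["ACGT"], default_pwms()["ETS"])


class TestInducibleFraction:
    def hits_at(self, positions, chrom="chr1"):
        return [MotifHit(chrom, p, p + 8, "+", 10.0, "ETS") for p in positions]

    sites = [anchor(10_000, name="s0")]

    def test_no_inducible_peaks_gives_zero(self):
        frac = inducible_binding_fraction(
            self.hits_at([9000, 9500]), self.sites, [], [])
        assert frac == 0.0

    def test_all_hits_inducible_gives_one(self):
        hits = self.hits_at([9000, 9500])
        ind = [GenomicInterval("chr1", 8900, 9600)]
        assert inducible_binding_fraction(hits, self.sites, [], ind) == 1.0

    def test_planted_fraction(self, rng):
        # 200 motif hits in windows, 9 covered by inducible peaks -> 0.045
        sites = [anchor(20_000 * (i + 1), name=f"s{i}") for i in range(200)]
        hits = self.hits_at([s.anchor + 400 for s in sites])
        ind = [GenomicInterval("chr1", s.anchor + 350, s.anchor + 500)
               for s in sites[:9]]
        frac = inducible_binding_fraction(hits, sites, [], ind)
        assert frac == pytest.approx(0.045)

    def test_tf_peaks_excluded_from_denominator(self):
        hits = self.hits_at([9990, 9400])  # first hit under the TF peak
        tf = [GenomicInterval("chr1", 9850, 10_150)]
        ind = [GenomicInterval("chr1", 9300, 9500)]
        assert inducible_binding_fraction(hits, self.sites, tf, ind) == 1.0

    def test_monotone_in_inducible_peaks(self):
        hits = self.hits_at([9000, 9300, 9600, 10_200])
        peaks = [GenomicInterval("chr1", 8950, 9050),
                 GenomicInterval("chr1", 9250, 9350),
                 GenomicInterval("chr1", 10_150, 10_250)]
        prev = -1.0
        for i in range(len(peaks) + 1):
            frac = inducible_binding_fraction(hits, self.sites, [], peaks[:i])
            assert frac >= prev
            prev = frac

    def test_empty_denominator_rejected(self):
        tf = [GenomicInterval("chr1", 8000, 12_000)]
        with pytest.raises(ValueError, match="retained"):
            inducible_binding_fraction(self.hits_at([9000]), self.sites, tf, [])
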