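"""PWM motif scanning at non-centrally remodeled segments.

Non-central remodeling — loss of histone-methylation signal near, but not
under, the TF peak — is hypothesized to mark binding of cooperating factors.
This module extracts the DNA under those loss segments, scans position
weight matrices (a pseudo-palindromic GRE, an ETS core and a RUNX core are
bundled; any JASPAR-format matrix can replace them), tests hit enrichment
against background sequences, and computes the fraction of motif occurrences
that acquire inducible cofactor binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enhancer_state import _IntervalIndex, fisher_exact_2x2
from .genomic_signal import GenomicInterval
from .mode_classifier import ModeCall, RemodelingSegment

__all__ = [
    "Pwm",
    "MotifHit",
    "default_pwms",
    "pwm_from_consensus",
    "read_jaspar",
    "extract_noncentral_sequences",
    "scan_pwm",
    "motif_enrichment",
    "inducible_binding_fraction",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Pwm:
    """Log-odds position weight matrix (log2, vs. background composition).

    ``matrix`` is 4 x width with rows indexed A, C, G, T.  ``threshold`` is
    the minimum score for a reported hit; by default 80 % of the maximum
    achievable score.
    """

    name: str
    matrix: np.ndarray
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("PWM must be 4 x width with width >= 4")
        if self.threshold is None:
            self.threshold = 0.8 * self.max_score
        if self.threshold > self.max_score:
            raise ValueError("threshold exceeds maximum achievable score")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())


def pwm_from_consensus(name: str, consensus: str, p_consensus: float = 0.85,
                       background: float = 0.25) -> Pwm:
    """Build a log2-odds PWM from a consensus with fixed per-column weights.

    Each column gives probability ``p_consensus`` to the consensus base and
    the remainder split evenly; log-odds are taken against a uniform
    background.
    """
    w = len(consensus)
    p_off = (1.0 - p_consensus) / 3.0
    probs = np.full((4, w), p_off)
    for j, base in enumerate(consensus.upper()):
        probs[_BASES.index(base), j] = p_consensus
    return Pwm(name, np.log2(probs / background))


def default_pwms() -> dict[str, Pwm]:
    """Bundled motifs: GRE (15 bp pseudo-palindrome), ETS and RUNX cores.

    Synthetic consensus-derived stand-ins for the motif families named in
    the analysis; replace with JASPAR matrices for real genomes.
    """
    return {
        "GRE": pwm_from_consensus("GRE", "AGAACATTGTGTTCT"),
        "ETS": pwm_from_consensus("ETS", "ACAGGAAG"),
        "RUNX": pwm_from_consensus("RUNX", "TGTGGTC"),
    }


def read_jaspar(path) -> dict[str, Pwm]:
    """Read JASPAR-format PFM file(s) into log2-odds PWMs (uniform bg).

    Counts are converted to probabilities with a +0.5 pseudocount per cell.
    """
    pwms: dict[str, Pwm] = {}
    name = None
    rows: dict[str, list[float]] = {}
    def _flush():
        if name is None:
            return
        counts = np.array([rows[b] for b in _BASES])
        probs = (counts + 0.5) / (counts + 0.5).sum(axis=0, keepdims=True)
        pwms[name] = Pwm(name, np.log2(probs / 0.25))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0]
                rows = {}
            else:
                base = line[0].upper()
                nums = line[1:].replace("[", " ").replace("]", " ").split()
                rows[base] = [float(x) for x in nums]
    _flush()
    return pwms


@dataclass(frozen=True)
class MotifHit:
    """One PWM match (0-based half-open, score in log2-odds units)."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float
    pwm_name: str


def _encode(sequence: str) -> np.ndarray:
    """Map sequence to row indices 0-3; N (or any other code) -> 4."""
    seq = sequence.upper()
    idx = np.full(len(seq), 4, dtype=np.int8)
    for i, base in enumerate(_BASES):
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = i
    return idx


def _scan_strand(idx: np.ndarray, pwm: Pwm) -> np.ndarray:
    """Score every window start on one strand; N contributes 0 log-odds."""
    w = pwm.width
    n = idx.size - w + 1
    if n <= 0:
        return np.empty(0)
    padded = np.vstack([pwm.matrix, np.zeros(pwm.width)])  # row 4 = N -> 0
    scores = np.zeros(n)
    for j in range(w):
        scores += padded[idx[j:j + n], j]
    return scores


def scan_pwm(sequence: str, pwm: Pwm, chrom: str = ".",
             offset: int = 0) -> list[MotifHit]:
    """Scan both strands of a sequence for PWM hits above threshold.

    Overlapping hits are allowed; results are ordered by position, then
    strand (+ before -).  ``offset`` shifts reported coordinates so hits on
    an extracted sub-sequence land in absolute chromosome space.
    """
    idx = _encode(sequence)
    w = pwm.width
    fwd = _scan_strand(idx, pwm)
    rc = _encode(sequence.translate(_COMP)[::-1])
    rev = _scan_strand(rc, pwm)[::-1]  # rev[i] scores window starting at i
    hits: list[MotifHit] = []
    for i in range(fwd.size):
        if fwd[i] >= pwm.threshold:
            hits.append(MotifHit(chrom, offset + i, offset + i + w, "+",
                                 float(fwd[i]), pwm.name))
        if rev[i] >= pwm.threshold:
            hits.append(MotifHit(chrom, offset + i, offset + i + w, "-",
                                 float(rev[i]), pwm.name))
    return hits


def extract_noncentral_sequences(
        mode_calls: list[ModeCall],
        segments_by_site: dict[str, list[RemodelingSegment]],
        anchors: list[GenomicInterval],
        genome) -> list[tuple[str, str]]:
    """DNA under loss segments of non-central sites, outside the footprint.

    ``genome`` maps chromosome name to sequence (a dict of strings or a
    ``pyfaidx.Fasta``).  Summit-relative segment offsets are converted to
    absolute coordinates; segments that are not fully outside the footprint,
    or that exceed chromosome bounds, contribute nothing.  Returns
    (site, sequence) pairs, one per qualifying loss segment.
    """
    anchor_by_site = {a.name: a for a in anchors}
    out: list[tuple[str, str]] = []
    for call in mode_calls:
        if call.mode != "non_central":
            continue
        anchor = anchor_by_site[call.site]
        summit = anchor.anchor
        if call.footprint is not None:
            fp_lo = call.footprint.start - summit
            fp_hi = call.footprint.end - summit
        else:
            fp_lo, fp_hi = -150, 150
        for seg in segments_by_site.get(call.site, []):
            if seg.sign != "loss":
                continue
            if not (seg.end_offset <= fp_lo or seg.start_offset >= fp_hi):
                continue  # must be fully outside the TF footprint
            start = summit + seg.start_offset
            end = summit + seg.end_offset
            try:
                chrom_seq = genome[anchor.chrom]
            except KeyError:
                continue
            if start < 0 or end > len(chrom_seq):
                continue
            seq = str(chrom_seq[start:end])
            out.append((call.site, seq.upper()))
    return out


def motif_enrichment(target_seqs: list[str], background_seqs: list[str],
                     pwm: Pwm) -> tuple[float, float]:
    """Fisher exact enrichment of >= 1 PWM hit in target vs background.

    Returns (odds_ratio, two-sided p).  A degenerate 2x2 table (any zero
    margin) yields p = 1.
    """
    if not target_seqs or not background_seqs:
        raise ValueError("need at least one sequence per set")
    t_hit = sum(1 for s in target_seqs if scan_pwm(s, pwm))
    b_hit = sum(1 for s in background_seqs if scan_pwm(s, pwm))
    a, b = t_hit, len(target_seqs) - t_hit
    c, d = b_hit, len(background_seqs) - b_hit
    if (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0):
        import warnings
        warnings.warn("degenerate 2x2 table in motif enrichment; p = 1")
        return 1.0, 1.0
    return fisher_exact_2x2(a, b, c, d)


def inducible_binding_fraction(motif_hits: list[MotifHit],
                               window_sites: list[GenomicInterval],
                               tf_peaks_to_exclude: list[GenomicInterval],
                               inducible_peaks: list[GenomicInterval],
                               window_halfwidth: int = 1500) -> float:
    """Fraction of retained motif hits overlapped by an inducible peak.

    The denominator is the motif hits inside the sites' 3-kb windows that do
    *not* overlap any excluded TF peak (the TF's own binding is subtracted);
    the numerator is the subset overlapped by an inducible (after-only)
    cofactor peak.
    """
    win_idx = _IntervalIndex([
        GenomicInterval(s.chrom, max(0, s.anchor - window_halfwidth),
                        s.anchor + window_halfwidth, s.name)
        for s in window_sites])
    tf_idx = _IntervalIndex(tf_peaks_to_exclude)
    ind_idx = _IntervalIndex(inducible_peaks)
    denom = num = 0
    for hit in motif_hits:
        if not win_idx.overlaps(hit.chrom, hit.start, hit.end):
            continue
        if tf_idx.overlaps(hit.chrom, hit.start, hit.end):
            continue
        denom += 1
        if ind_idx.overlaps(hit.chrom, hit.start, hit.end):
            num += 1
    if denom == 0:
        raise ValueError("no motif hits retained after TF-peak exclusion")
    return num / denom


def hits_to_bed(hits: list[MotifHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.pwm_name}\t"
                     f"{h.score:.4f}\t{h.strand}\n")


def hits_from_bed(path) -> list[MotifHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 6:
                continue
            hits.append(MotifHit(parts[0], int(parts[1]), int(parts[2]),
                                 parts[5], float(parts[4]), parts[3]))
    return hits
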