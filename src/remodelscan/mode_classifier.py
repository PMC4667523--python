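"""Delta-signal segment calling and four-mode remodeling classification.

A delta profile (stimulated minus unstimulated, in z-units of the input
tracks) around each TF summit is reduced to contiguous *segments* of
significant signal change, and each cluster of sites is assigned one of four
remodeling modes:

* ``central`` — signal loss confined to the TF-occupied footprint
  (nucleosome eviction under the factor);
* ``non_central`` — loss clearly outside the footprint but within the
  flanking limit (cofactor-associated eviction nearby);
* ``phased`` — alternating gains and losses of flanking signal
  (repositioning of the flanking nucleosome array);
* ``minimal`` — none of the above.

Classification runs on each cluster's mean profile and members inherit the
cluster call (per-site classification is available as an option); the
decision precedence is phased > central > non_central > minimal because the
definitions overlap (phased sites typically also lose central signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomic_signal import GenomicInterval, smooth_profile
from .profile_matrix import ProfileMatrix
from .remodeling_cluster import ClusterResult

__all__ = [
    "RemodelingSegment",
    "ModeCall",
    "ClassifierParams",
    "MODES",
    "call_segments",
    "classify_profile",
    "assign_modes",
]

MODES = ("central", "non_central", "phased", "minimal")


@dataclass(frozen=True)
class RemodelingSegment:
    """Contiguous run of significant delta signal, summit-relative.

    Offsets are signed bp relative to the anchoring summit; ``sign`` is
    ``"loss"`` for negative runs and ``"gain"`` for positive ones.
    """

    start_offset: int
    end_offset: int
    sign: str
    mean_delta: float

    def __post_init__(self) -> None:
        if self.end_offset <= self.start_offset:
            raise ValueError("segment must have positive length")
        if self.sign not in ("loss", "gain"):
            raise ValueError(f"bad segment sign {self.sign!r}")
        if (self.sign == "loss") != (self.mean_delta < 0):
            raise ValueError("mean_delta sign inconsistent with segment sign")

    @property
    def length(self) -> int:
        return self.end_offset - self.start_offset


@dataclass
class ModeCall:
    """Per-site remodeling mode with its supporting evidence features."""

    site: str
    cluster: int
    mode: str
    central_loss: bool
    flank_losses: tuple[int, int]
    alternations: tuple[int, int]
    footprint: GenomicInterval | None = None


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds for segment calling and mode classification.

    threshold_z
        Minimum |delta| (input z-units) for a bin to be significant.
    min_segment_length
        Minimum segment span in bp; sub-nucleosomal runs are discarded.
    merge_gap
        Same-sign runs separated by <= this many bp are merged.
    footprint_halfwidth
        Fallback TF footprint half-width when no peak interval is supplied.
    flank_limit
        Non-central evidence must lie within this distance of the summit.
    smooth_sd_bp
        Gaussian sd for the smoothed profile used by phased detection.
    phased spacing gate
        Consecutive alternating extrema must be 60-250 bp apart — from half
        the nucleosome repeat (alternating-wave extremum spacing) up to the
        full repeat.
    """

    threshold_z: float = 0.3
    min_segment_length: int = 100
    merge_gap: int = 30
    footprint_halfwidth: int = 150
    flank_limit: int = 1500
    smooth_sd_bp: float = 20.0
    phased_min_spacing: int = 60
    phased_max_spacing: int = 250
    phased_min_alternations: int = 2
    #: flanks that must show the alternating pattern (2 = both sides; the
    #: repositioned flanking array is two-sided, unlike non-central eviction)
    phased_sides: int = 2
    #: cluster-level calls only: fraction of member profiles that must show
    #: same-sign signal (|mean over the segment span| >= threshold_z) for a
    #: cluster-mean segment to count as evidence
    member_support: float = 0.5


def call_segments(profile: np.ndarray, bin_size: int, half_width: int,
                  threshold_z: float = 0.3, min_len: int = 100,
                  merge_gap: int = 30) -> list[RemodelingSegment]:
    """Find maximal runs of significant, sign-consistent delta signal.

    Bins with |value| >= ``threshold_z`` form runs of a single sign; runs of
    the same sign separated by <= ``merge_gap`` bp are merged; merged runs
    shorter than ``min_len`` bp are discarded.  The input must be the
    *unsmoothed* delta profile.
    """
    profile = np.asarray(profile, dtype=np.float64)
    sig = np.where(profile >= threshold_z, 1, np.where(profile <= -threshold_z, -1, 0))
    runs: list[tuple[int, int, int]] = []  # (start_bin, end_bin, sign)
    i = 0
    n = profile.size
    while i < n:
        if sig[i] == 0:
            i += 1
            continue
        j = i
        while j < n and sig[j] == sig[i]:
            j += 1
        runs.append((i, j, int(sig[i])))
        i = j
    # merge same-sign runs separated by small gaps
    merged: list[tuple[int, int, int]] = []
    gap_bins = merge_gap // bin_size
    for run in runs:
        if merged and merged[-1][2] == run[2] and run[0] - merged[-1][1] <= gap_bins:
            merged[-1] = (merged[-1][0], run[1], run[2])
        else:
            merged.append(list(run))  # type: ignore[arg-type]
    out: list[RemodelingSegment] = []
    for s, e, sgn in merged:
        length = (e - s) * bin_size
        if length < min_len:
            continue
        mean_delta = float(profile[s:e].mean())
        out.append(RemodelingSegment(
            start_offset=s * bin_size - half_width,
            end_offset=e * bin_size - half_width,
            sign="loss" if sgn < 0 else "gain",
            mean_delta=mean_delta,
        ))
    return out


def _local_extrema(smoothed: np.ndarray, bin_size: int,
                   half_width: int) -> list[tuple[int, float]]:
    """All local extrema of the smoothed profile, ordered by position.

    Returns (summit-relative offset of the bin center, value).  Plateau
    extrema are reported once at their left edge.  No magnitude filter is
    applied here — significance is judged pairwise in the alternation count,
    which keeps the phased call monotone in the threshold.
    """
    v = np.asarray(smoothed)
    ext: list[tuple[int, float]] = []
    for i in range(1, v.size - 1):
        left, right = v[i] - v[i - 1], v[i + 1] - v[i]
        if (left > 0 and right <= 0 and v[i] > 0) or (left < 0 and right >= 0 and v[i] < 0):
            offset = i * bin_size - half_width + bin_size // 2
            ext.append((offset, float(v[i])))
    return ext


def _count_alternations(extrema: list[tuple[int, float]],
                        params: ClassifierParams) -> int:
    """Longest chain of sign alternations among consecutive extrema.

    A consecutive pair qualifies when both extrema reach
    |value| >= threshold_z, their signs differ, and their spacing falls in
    the nucleosomal gate.  The count is the longest *run* of qualifying
    pairs, so "2 alternations" means three extrema in an unbroken
    peak-valley-peak (or valley-peak-valley) chain — the alternating
    pattern, not two isolated sign flips.
    """
    best = run = 0
    for (o1, v1), (o2, v2) in zip(extrema, extrema[1:]):
        spacing = abs(o2 - o1)
        if (abs(v1) >= params.threshold_z and abs(v2) >= params.threshold_z
                and np.sign(v1) != np.sign(v2)
                and params.phased_min_spacing <= spacing <= params.phased_max_spacing):
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def profile_features(profile: np.ndarray, bin_size: int, half_width: int,
                     footprint_halfwidth: int,
                     params: ClassifierParams = ClassifierParams(),
                     smoothed: np.ndarray | None = None):
    """Segments, flank alternation counts and central-loss flag for a profile."""
    segments = call_segments(profile, bin_size, half_width,
                             params.threshold_z, params.min_segment_length,
                             params.merge_gap)
    if smoothed is None:
        smoothed = smooth_profile(profile, params.smooth_sd_bp, bin_size)
    extrema = _local_extrema(smoothed, bin_size, half_width)
    fp = footprint_halfwidth
    left = [e for e in extrema if e[0] < -fp]
    right = [e for e in extrema if e[0] > fp]
    alternations = (_count_alternations(left, params),
                    _count_alternations(right, params))
    central_loss = any(
        s.sign == "loss" and s.start_offset < fp and s.end_offset > -fp
        for s in segments)
    flank_losses = (
        sum(1 for s in segments
            if s.sign == "loss" and s.end_offset <= -fp and s.start_offset >= -params.flank_limit),
        sum(1 for s in segments
            if s.sign == "loss" and s.start_offset >= fp and s.end_offset <= params.flank_limit),
    )
    return segments, central_loss, flank_losses, alternations


def classify_profile(segments: list[RemodelingSegment],
                     footprint_halfwidth: int,
                     smoothed_profile: np.ndarray,
                     bin_size: int, half_width: int,
                     params: ClassifierParams = ClassifierParams()) -> str:
    """Assign one of the four remodeling modes from segment evidence.

    Decision order (first match wins):

    1. ``phased`` — flanking-array remodeling *in addition to* the central
       one: a loss segment overlapping the footprint, plus >= 2 chained sign
       alternations among significant extrema of the smoothed profile at
       nucleosomal spacing, beyond the footprint on ``phased_sides`` flanks
       (both by default — repositioning shifts the whole flanking array);
    2. ``central`` — loss overlapping the footprint that dominates (by
       |mean| x length weight) any loss fully outside it;
    3. ``non_central`` — dominant loss fully outside the footprint but
       within the flank limit;
    4. ``minimal`` — otherwise (including gain-only profiles).

    Weighing central against flanking loss, rather than demanding that no
    loss at all lies outside the footprint, keeps cluster-mean calls stable
    when residual noise produces a marginal stray segment.
    """
    fp = footprint_halfwidth
    losses = [s for s in segments if s.sign == "loss"]
    overlapping = [s for s in losses if s.start_offset < fp and s.end_offset > -fp]
    extrema = _local_extrema(smoothed_profile, bin_size, half_width)
    left = [e for e in extrema if e[0] < -fp]
    right = [e for e in extrema if e[0] > fp]
    alternating_sides = sum(
        _count_alternations(side, params) >= params.phased_min_alternations
        for side in (left, right))
    if overlapping and alternating_sides >= params.phased_sides:
        return "phased"
    outside = [s for s in losses
               if (s.end_offset <= -fp or s.start_offset >= fp)
               and s.start_offset >= -params.flank_limit
               and s.end_offset <= params.flank_limit]

    def weight(segs):
        return sum(abs(s.mean_delta) * s.length for s in segs)

    if overlapping and weight(overlapping) >= weight(outside):
        return "central"
    if outside:
        return "non_central"
    return "minimal"


def _supported_segments(segments: list[RemodelingSegment], rows: np.ndarray,
                        bin_size: int, half_width: int,
                        params: ClassifierParams) -> list[RemodelingSegment]:
    """Keep cluster-mean segments corroborated by a majority of members.

    A member supports a segment when its own profile, averaged over the
    segment's span, reaches |threshold_z| with the segment's sign.  Residual
    noise in the mean of a small cluster can clear the per-bin threshold
    over a short span, but such spans are rarely reproduced across members.
    """
    if rows.shape[0] <= 1 or params.member_support <= 0:
        return segments
    kept = []
    for seg in segments:
        lo = (seg.start_offset + half_width) // bin_size
        hi = (seg.end_offset + half_width) // bin_size
        span_means = rows[:, lo:hi].mean(axis=1)
        sign = -1.0 if seg.sign == "loss" else 1.0
        support = np.mean(sign * span_means >= params.threshold_z)
        if support >= params.member_support:
            kept.append(seg)
    return kept


def _footprint_halfwidth_for(anchor: GenomicInterval,
                             footprint: GenomicInterval | None,
                             default: int) -> int:
    """Half-width of the TF-occupied region around the anchor's summit."""
    if footprint is None:
        return default
    summit = anchor.anchor
    return max(footprint.end - summit, summit - footprint.start)


def assign_modes(matrix: ProfileMatrix, clusters: ClusterResult,
                 footprints: list[GenomicInterval | None] | None = None,
                 params: ClassifierParams = ClassifierParams(),
                 per_site: bool = False) -> list[ModeCall]:
    """Classify every site of a clustered delta matrix into a mode.

    By default each cluster's *mean* profile is classified and member sites
    inherit the cluster mode; ``per_site=True`` classifies each row
    independently.  Per-site evidence features (central loss, flank losses,
    alternation counts) are always computed per site for reporting.

    ``footprints`` optionally supplies the called TF peak interval per site
    (aligned with ``matrix.anchors``); sites without one use the default
    ``params.footprint_halfwidth`` around the summit.
    """
    if footprints is None:
        footprints = [None] * matrix.n_sites
    if len(footprints) != matrix.n_sites:
        raise ValueError("footprints must align with matrix anchors")
    bs, hw = matrix.bin_size, matrix.half_width

    fp_halfwidths = np.array([
        _footprint_halfwidth_for(a, f, params.footprint_halfwidth)
        for a, f in zip(matrix.anchors, footprints)])

    cluster_mode: dict[int, str] = {}
    if not per_site:
        for c in range(clusters.k):
            member_idx = np.flatnonzero(clusters.labels == c)
            if member_idx.size == 0:
                continue
            rows = matrix.values[member_idx]
            mean_profile = rows.mean(axis=0)
            fp = int(np.median(fp_halfwidths[member_idx]))
            segs = call_segments(mean_profile, bs, hw, params.threshold_z,
                                 params.min_segment_length, params.merge_gap)
            segs = _supported_segments(segs, rows, bs, hw, params)
            smoothed = smooth_profile(mean_profile, params.smooth_sd_bp, bs)
            cluster_mode[c] = classify_profile(segs, fp, smoothed, bs, hw, params)

    calls: list[ModeCall] = []
    for i, anchor in enumerate(matrix.anchors):
        profile = matrix.values[i]
        fp = int(fp_halfwidths[i])
        segs, central_loss, flank_losses, alternations = profile_features(
            profile, bs, hw, fp, params)
        if per_site:
            smoothed = smooth_profile(profile, params.smooth_sd_bp, bs)
            mode = classify_profile(segs, fp, smoothed, bs, hw, params)
        else:
            mode = cluster_mode[int(clusters.labels[i])]
        calls.append(ModeCall(
            site=anchor.name,
            cluster=int(clusters.labels[i]),
            mode=mode,
            central_loss=central_loss,
            flank_losses=flank_losses,
            alternations=alternations,
            footprint=footprints[i],
        ))
    return calls
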