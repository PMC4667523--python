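"""Summit-anchored signal matrices, aggregate profiles and AUC scores.

Every downstream step (clustering, mode classification, activation calls)
consumes a sites x bins matrix of signal extracted in a fixed window centered
on each peak summit — by default a 3-kb window (half-width 1500 bp).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np

from .genomic_signal import GenomicInterval, SignalTrack

__all__ = [
    "ProfileMatrix",
    "AucScore",
    "build_matrix",
    "aggregate_profile",
    "auc_score",
    "correlate_scores",
]


@dataclass
class ProfileMatrix:
    """Sites x bins signal matrix anchored on peak summits.

    ``values[i, j]`` is the track signal in the j-th bin of the window
    ``[summit_i - half_width, summit_i + half_width)``.  Anchors whose window
    would leave the covered chromosome are dropped, never NaN-padded; the
    dropped anchors are kept in ``dropped`` for reporting.
    """

    values: np.ndarray
    anchors: list[GenomicInterval]
    half_width: int
    bin_size: int
    track_origin: str = ""
    dropped: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = 2 * self.half_width // self.bin_size
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise ValueError(
                f"matrix must have {expected} columns for half_width="
                f"{self.half_width}, bin_size={self.bin_size}")
        if self.values.shape[0] != len(self.anchors):
            raise ValueError("row count must match anchor count")
        if np.isnan(self.values).any():
            raise ValueError("matrix may not contain missing values")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def bin_offsets(self) -> np.ndarray:
        """Summit-relative start (bp) of each matrix column."""
        return np.arange(self.n_bins) * self.bin_size - self.half_width

    def site_names(self) -> list[str]:
        return [a.name for a in self.anchors]

    def to_tsv(self, path) -> None:
        """Serialize as (optionally gzip) TSV with summit-relative headers."""
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            header = "\t".join(["site"] + [str(o) for o in self.bin_offsets()])
            fh.write(header + "\n")
            for anchor, row in zip(self.anchors, self.values):
                fh.write(anchor.name + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


@dataclass(frozen=True)
class AucScore:
    """Signed area under a site's window profile, in signal x bp units."""

    site: str
    value: float


def build_matrix(track: SignalTrack, anchors: list[GenomicInterval],
                 half_width: int = 1500) -> ProfileMatrix:
    """Extract track signal in ``[summit - half_width, summit + half_width)``.

    Each anchor must define a summit (narrowPeak offset) or fall back to its
    midpoint.  Anchors on chromosomes absent from the track, or whose window
    extends past the covered chromosome, are dropped and reported via
    ``ProfileMatrix.dropped``.
    """
    if half_width % track.bin_size != 0:
        raise ValueError("half_width must be a multiple of bin_size")
    w = half_width // track.bin_size
    rows: list[np.ndarray] = []
    kept: list[GenomicInterval] = []
    dropped: list[GenomicInterval] = []
    for anchor in anchors:
        values = track.chrom_values.get(anchor.chrom)
        if values is None:
            dropped.append(anchor)
            continue
        center = anchor.anchor // track.bin_size
        lo, hi = center - w, center + w
        if lo < 0 or hi > values.size:
            dropped.append(anchor)
            continue
        rows.append(values[lo:hi])
        kept.append(anchor)
    mat = np.vstack(rows) if rows else np.empty((0, 2 * w))
    return ProfileMatrix(mat, kept, half_width, track.bin_size,
                         track_origin=track.origin, dropped=dropped)


def aggregate_profile(matrix: ProfileMatrix) -> np.ndarray:
    """Column-wise mean profile over all sites (the aggregate metaprofile)."""
    if matrix.n_sites == 0:
        raise ValueError("cannot aggregate an empty matrix")
    return matrix.values.mean(axis=0)


def auc_score(matrix: ProfileMatrix) -> list[AucScore]:
    """Signed area under each row: bin_size x sum of bin values.

    Captures both the height and the width of the signal change in the
    window; used for TF peak size and per-mark delta quantification.
    """
    sums = matrix.values.sum(axis=1) * matrix.bin_size
    return [AucScore(a.name, float(s)) for a, s in zip(matrix.anchors, sums)]


def correlate_scores(x: list[AucScore], y: list[AucScore]) -> float:
    """Squared Pearson correlation between two AUC score lists.

    Scores are matched by site identifier; both lists must cover the same
    sites (order-independent) and have non-zero variance.
    """
    ymap = {s.site: s.value for s in y}
    if set(ymap) != {s.site for s in x}:
        raise ValueError("score lists must cover identical site identifiers")
    xv = np.array([s.value for s in x])
    yv = np.array([ymap[s.site] for s in x])
    if xv.size < 3:
        raise ValueError("need at least 3 matched sites")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero variance in scores: correlation undefined")
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)
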