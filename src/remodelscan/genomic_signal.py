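"""Genome signal tracks and interval files.

A :class:`SignalTrack` holds binned per-chromosome signal at one fixed bin
size and is the unit of all track algebra in the package: z-score
normalization, subtraction (condition deltas), summation (the composite
delta-H3K4methyls signal) and Gaussian smoothing.  Interval files (BED6 and
ENCODE narrowPeak) are parsed into :class:`GenomicInterval` records whose
summits anchor all downstream profile windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SignalTrack",
    "GenomicInterval",
    "TrackParseError",
    "read_track",
    "write_bedgraph",
    "write_bigwig",
    "zscore_normalize",
    "subtract_tracks",
    "add_tracks",
    "gaussian_smooth",
    "gaussian_kernel",
    "smooth_profile",
    "read_intervals",
    "write_intervals",
]


class TrackParseError(ValueError):
    """Malformed record in a track or interval file (carries the line number)."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class SignalTrack:
    """Binned genome signal.

    Parameters
    ----------
    chrom_values
        Mapping chromosome -> 1-D float array; bin ``i`` covers
        ``[i*bin_size, (i+1)*bin_size)`` in 0-based coordinates.
    bin_size
        Bin width in bp; shared by every chromosome.
    origin
        Free-text label (condition + assay), propagated through algebra.
    normalized
        True once the track has been globally z-scored.
    """

    chrom_values: dict[str, np.ndarray]
    bin_size: int
    origin: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be a positive integer")
        self.chrom_values = {
            c: np.asarray(v, dtype=np.float64) for c, v in self.chrom_values.items()
        }

    @property
    def n_bins(self) -> int:
        return sum(v.size for v in self.chrom_values.values())

    def chrom_length(self, chrom: str) -> int:
        """Covered length of ``chrom`` in bp (number of stored bins x bin_size)."""
        return self.chrom_values[chrom].size * self.bin_size

    def all_values(self) -> np.ndarray:
        if not self.chrom_values:
            return np.empty(0)
        return np.concatenate([v for v in self.chrom_values.values()])


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with an optional summit."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def anchor(self) -> int:
        """Summit if defined, otherwise the interval midpoint."""
        return self.summit if self.summit is not None else self.midpoint


# ---------------------------------------------------------------------------
# Track reading: wiggle / bedGraph / bigWig, rebinned to a fixed bin size
# ---------------------------------------------------------------------------

def _rebin(intervals_by_chrom: dict[str, list[tuple[int, int, float]]],
           bin_size: int) -> dict[str, np.ndarray]:
    """Coverage-weighted mean rebinning; uncovered bp contribute 0.

    Each record (start, end, value) deposits value * overlap_bp into every bin
    it touches; bins are then divided by bin_size.  Equivalent to averaging
    the bp-resolution step function (zero where uncovered) over each bin.
    """
    out: dict[str, np.ndarray] = {}
    for chrom, recs in intervals_by_chrom.items():
        if not recs:
            continue
        recs.sort(key=lambda r: r[0])
        prev_end = -1
        for i, (s, e, _) in enumerate(recs):
            if s < prev_end:
                raise TrackParseError(
                    f"overlapping records on {chrom} near position {s}")
            prev_end = e
        max_end = recs[-1][1]
        n_bins = (max_end + bin_size - 1) // bin_size
        mass = np.zeros(n_bins + 1)
        # full-bin spans via a difference array; partial edge bins directly
        starts = np.array([r[0] for r in recs], dtype=np.int64)
        ends = np.array([r[1] for r in recs], dtype=np.int64)
        vals = np.array([r[2] for r in recs], dtype=np.float64)
        first_full = (starts + bin_size - 1) // bin_size
        last_full = ends // bin_size
        diff = np.zeros(n_bins + 2)
        span_ok = first_full < last_full
        np.add.at(diff, first_full[span_ok], vals[span_ok] * bin_size)
        np.add.at(diff, last_full[span_ok], -vals[span_ok] * bin_size)
        mass[:n_bins] += np.cumsum(diff)[:n_bins]
        # leading partial piece: [start, min(end, first_full*bin)) in start's bin
        has_lead = starts < first_full * bin_size
        lead_len = (np.minimum(ends, first_full * bin_size) - starts)[has_lead]
        np.add.at(mass, starts[has_lead] // bin_size, vals[has_lead] * lead_len)
        # trailing partial piece: [last_full*bin, end) in bin last_full,
        # unless the lead piece already covered it (record inside one bin)
        has_trail = (ends > last_full * bin_size) & (last_full * bin_size >= starts)
        trail_len = (ends - last_full * bin_size)[has_trail]
        np.add.at(mass, last_full[has_trail], vals[has_trail] * trail_len)
        out[chrom] = mass[:n_bins] / bin_size
    return out


def _parse_bedgraph(lines) -> dict[str, list[tuple[int, int, float]]]:
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise TrackParseError("bedGraph record needs 4 fields", lineno)
        try:
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        except ValueError as exc:
            raise TrackParseError(f"unparseable bedGraph record: {exc}", lineno) from None
        if start < 0 or start >= end:
            raise TrackParseError(f"invalid span {start}-{end}", lineno)
        by_chrom.setdefault(chrom, []).append((start, end, value))
    return by_chrom


def _parse_wiggle(lines) -> dict[str, list[tuple[int, int, float]]]:
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    mode = None  # ("fixed", chrom, start, step, span) | ("variable", chrom, span)
    pos = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if line.startswith("fixedStep"):
            kv = dict(tok.split("=") for tok in line.split()[1:])
            try:
                chrom = kv["chrom"]
                start = int(kv["start"]) - 1  # wiggle declarations are 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", step))
            except (KeyError, ValueError) as exc:
                raise TrackParseError(f"bad fixedStep header: {exc}", lineno) from None
            mode, pos = ("fixed", chrom, step, span), start
        elif line.startswith("variableStep"):
            kv = dict(tok.split("=") for tok in line.split()[1:])
            try:
                chrom = kv["chrom"]
                span = int(kv.get("span", 1))
            except (KeyError, ValueError) as exc:
                raise TrackParseError(f"bad variableStep header: {exc}", lineno) from None
            mode = ("variable", chrom, span)
        elif mode is None:
            raise TrackParseError("data before any wiggle declaration", lineno)
        elif mode[0] == "fixed":
            _, chrom, step, span = mode
            try:
                value = float(line)
            except ValueError:
                raise TrackParseError(f"expected numeric value, got {line!r}", lineno) from None
            by_chrom.setdefault(chrom, []).append((pos, pos + span, value))
            pos += step
        else:
            _, chrom, span = mode
            parts = line.split()
            if len(parts) != 2:
                raise TrackParseError("variableStep record needs 2 fields", lineno)
            try:
                start, value = int(parts[0]) - 1, float(parts[1])
            except ValueError as exc:
                raise TrackParseError(f"unparseable record: {exc}", lineno) from None
            by_chrom.setdefault(chrom, []).append((start, start + span, value))
    return by_chrom


def read_track(path, format: str = "bedGraph", bin_size: int = 10,
               origin: str = "") -> SignalTrack:
    """Read a signal file and rebin it to ``bin_size``.

    Supported formats: ``wiggle`` (fixedStep/variableStep), ``bedGraph``,
    ``bigWig``.  Values are rebinned by coverage-weighted mean with
    uncovered bp counting as 0; overlapping source records are rejected.
    """
    fmt = format.lower()
    if fmt in ("bedgraph", "bg"):
        with open(path) as fh:
            by_chrom = _parse_bedgraph(fh)
    elif fmt in ("wiggle", "wig"):
        with open(path) as fh:
            by_chrom = _parse_wiggle(fh)
    elif fmt in ("bigwig", "bw"):
        import pyBigWig
        bw = pyBigWig.open(str(path))
        by_chrom = {}
        try:
            for chrom in bw.chroms():
                ivals = bw.intervals(chrom)
                if ivals:
                    by_chrom[chrom] = [(s, e, v) for s, e, v in ivals]
        finally:
            bw.close()
    else:
        raise ValueError(f"unknown track format {format!r}")
    values = _rebin(by_chrom, bin_size)
    if not values:
        raise TrackParseError("no data records found in track file")
    return SignalTrack(values, bin_size=bin_size, origin=origin or str(path))


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write a track as bedGraph, run-length-compressing equal adjacent bins.

    Zero bins are written too, so a read/write round trip at the same bin
    size is exact.
    """
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in track.chrom_values:
            v = track.chrom_values[chrom]
            if v.size == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [v.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s * bs}\t{e * bs}\t{v[s]:.6g}\n")


def write_bigwig(track: SignalTrack, path) -> None:
    import pyBigWig
    bw = pyBigWig.open(str(path), "w")
    header = [(c, track.chrom_length(c)) for c in sorted(track.chrom_values)]
    bw.addHeader(header)
    bs = track.bin_size
    for chrom, _ in header:
        v = track.chrom_values[chrom]
        bw.addEntries(chrom, 0, values=v.astype(np.float64),
                      span=bs, step=bs)
    bw.close()


# ---------------------------------------------------------------------------
# Track algebra
# ---------------------------------------------------------------------------

def zscore_normalize(track: SignalTrack) -> SignalTrack:
    """Globally z-score a track: (v - mean) / sd over every stored bin.

    Population statistics over all stored bins of all chromosomes, explicit
    zeros included; bins absent from the source file never existed and are
    excluded.  The result has global mean 0 and sd 1.
    """
    values = track.all_values()
    if values.size < 2:
        raise ValueError("track needs at least 2 bins to normalize")
    mean = values.mean()
    sd = values.std()  # population sd
    if sd == 0:
        raise ValueError("constant track: zero variance, cannot z-score")
    return SignalTrack(
        {c: (v - mean) / sd for c, v in track.chrom_values.items()},
        bin_size=track.bin_size,
        origin=track.origin,
        normalized=True,
    )


def _check_compatible(tracks) -> int:
    sizes = {t.bin_size for t in tracks}
    if len(sizes) != 1:
        raise ValueError(f"bin_size mismatch among tracks: {sorted(sizes)}")
    return sizes.pop()


def subtract_tracks(a: SignalTrack, b: SignalTrack) -> SignalTrack:
    """Bin-wise ``a - b`` over the union of chromosomes (absent bins are 0).

    Used on normalized tracks to form the condition delta (stimulated minus
    unstimulated); the result is a delta in the inputs' z-units, so the
    ``normalized`` flag is cleared.
    """
    bs = _check_compatible([a, b])
    out: dict[str, np.ndarray] = {}
    for chrom in list(a.chrom_values) + [c for c in b.chrom_values if c not in a.chrom_values]:
        va = a.chrom_values.get(chrom)
        vb = b.chrom_values.get(chrom)
        n = max(va.size if va is not None else 0, vb.size if vb is not None else 0)
        v = np.zeros(n)
        if va is not None:
            v[: va.size] += va
        if vb is not None:
            v[: vb.size] -= vb
        out[chrom] = v
    return SignalTrack(out, bin_size=bs,
                       origin=f"({a.origin})-({b.origin})", normalized=False)


def add_tracks(tracks: list[SignalTrack]) -> SignalTrack:
    """Bin-wise sum of >= 2 tracks over the union of chromosomes.

    Summing the three H3K4 methylation deltas yields the composite
    delta-H3K4methyls remodeling signal.
    """
    if len(tracks) < 2:
        raise ValueError("add_tracks needs at least 2 tracks")
    bs = _check_compatible(tracks)
    chroms: list[str] = []
    for t in tracks:
        for c in t.chrom_values:
            if c not in chroms:
                chroms.append(c)
    out: dict[str, np.ndarray] = {}
    for chrom in chroms:
        n = max(t.chrom_values[chrom].size for t in tracks if chrom in t.chrom_values)
        v = np.zeros(n)
        for t in tracks:
            tv = t.chrom_values.get(chrom)
            if tv is not None:
                v[: tv.size] += tv
        out[chrom] = v
    return SignalTrack(out, bin_size=bs,
                       origin="+".join(t.origin for t in tracks), normalized=False)


def gaussian_kernel(sd_bins: float) -> np.ndarray:
    """Discrete Gaussian kernel truncated at +/- 4 sd and renormalized to sum 1."""
    radius = max(1, int(math.ceil(4.0 * sd_bins)))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sd_bins) ** 2)
    return k / k.sum()


def smooth_profile(profile: np.ndarray, sd_bp: float, bin_size: int) -> np.ndarray:
    """Smooth a single profile vector with the truncated Gaussian kernel."""
    kernel = gaussian_kernel(sd_bp / bin_size)
    return np.convolve(np.asarray(profile, dtype=np.float64), kernel, mode="same")


def gaussian_smooth(track: SignalTrack, sd_bp: float = 20.0) -> SignalTrack:
    """Gaussian-smooth every chromosome of a track (visualization transform).

    Kernel sd is given in bp, truncated at +/- 4 sd and renormalized, so total
    signal mass is conserved away from chromosome ends.  Requires
    ``sd_bp >= bin_size / 2`` so the kernel is resolvable at the bin grid.
    """
    if sd_bp < track.bin_size / 2:
        raise ValueError(
            f"sd_bp={sd_bp} too small for bin_size={track.bin_size} "
            "(need sd_bp >= bin_size/2)")
    kernel = gaussian_kernel(sd_bp / track.bin_size)
    return SignalTrack(
        {c: np.convolve(v, kernel, mode="same") for c, v in track.chrom_values.items()},
        bin_size=track.bin_size,
        origin=f"smooth({track.origin},sd={sd_bp})",
        normalized=False,
    )


# ---------------------------------------------------------------------------
# Interval files
# ---------------------------------------------------------------------------

def read_intervals(path, format: str = "auto") -> list[GenomicInterval]:
    """Read BED6 or ENCODE narrowPeak intervals.

    narrowPeak column 10 (0-based offset of the summit from ``start``)
    populates ``summit``; an offset of -1, or a plain BED6 file, falls back
    to the interval midpoint as the anchor (``summit`` left unset).
    """
    fmt = format.lower()
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if fmt == "auto":
                fmt = "narrowpeak" if len(parts) >= 10 else "bed6"
            if len(parts) < 3:
                raise TrackParseError("interval record needs >= 3 fields", lineno)
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise TrackParseError(f"unparseable interval: {exc}", lineno) from None
            name = parts[3] if len(parts) > 3 else "."
            try:
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            except ValueError:
                score = 0.0
            summit = None
            if fmt == "narrowpeak":
                if len(parts) < 10:
                    raise TrackParseError("narrowPeak record needs 10 fields", lineno)
                offset = int(parts[9])
                if offset >= 0:
                    summit = start + offset
            try:
                out.append(GenomicInterval(chrom, start, end, name, score, summit))
            except ValueError as exc:
                raise TrackParseError(str(exc), lineno) from None
    return out


def write_intervals(intervals: list[GenomicInterval], path,
                    format: str = "bed6") -> None:
    fmt = format.lower()
    with open(path, "w") as fh:
        for iv in intervals:
            base = f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t."
            if fmt == "narrowpeak":
                offset = (iv.summit - iv.start) if iv.summit is not None else -1
                fh.write(base + f"\t0\t-1\t-1\t{offset}\n")
            else:
                fh.write(base + "\n")
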