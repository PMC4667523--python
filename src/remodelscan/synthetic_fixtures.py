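"""Synthetic paired-condition cohorts with planted remodeling modes.

The generator emulates the inputs the analysis consumes — per-condition
histone-mark signal tracks around TF binding summits, peak calls, a genome
sequence with planted motifs, and a gene-expression table — with known
ground truth per site, so every pipeline stage can be tested without any
sequencing data.

The model: nucleosomes are Gaussian occupancy bumps (sd = footprint/4) at
phased positions (repeat 190 bp) anchored on each TF summit; the
unstimulated track is the bump raster plus white noise, and the stimulated
track is the same raster with a mode-specific modification planted before
independent noise is added:

* ``central`` — attenuate the summit-overlying bump (and, more weakly, its
  immediate neighbours): eviction under the factor;
* ``non_central`` — attenuate one bump at 380-1140 bp on a random side:
  cofactor-associated eviction;
* ``phased`` — shift the two innermost bumps on each side outward by
  40-80 bp and deepen/widen the central trough: repositioning, which makes
  the condition difference alternate in sign along the flanks;
* ``minimal`` — no deterministic change.

Signal is simulated directly at track level: the method consumes normalized
tracks, so read-level simulation would add nothing testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_signal import GenomicInterval, SignalTrack, write_bedgraph, write_intervals
from .gene_association import TssRecord

__all__ = [
    "CohortConfig",
    "SimulatedCohort",
    "simulate_nucleosome_track",
    "plant_remodeling",
    "simulate_cohort",
    "make_archetype_matrix",
    "MODE_PROPORTIONS_DEFAULT",
]

#: Cohort mode mix mirroring the reported prevalences (non-central ~49 %,
#: phased ~6 %), with the remainder split between central and minimal.
MODE_PROPORTIONS_DEFAULT = {
    "central": 0.25, "non_central": 0.49, "phased": 0.06, "minimal": 0.20,
}

H3K4_MARKS = ("H3K4me1", "H3K4me2", "H3K4me3")
#: Per-mark global scale factors (different ChIP efficiencies; z-scoring
#: removes them, which is the point of normalizing before subtraction).
MARK_SCALE = {"H3K4me1": 1.0, "H3K4me2": 1.4, "H3K4me3": 0.7, "H3K27Ac": 1.1}


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort."""

    n_sites: int = 400
    mode_proportions: dict = field(
        default_factory=lambda: dict(MODE_PROPORTIONS_DEFAULT))
    repeat_bp: int = 190
    footprint_bp: int = 147
    site_spacing: int = 8000
    bin_size: int = 10
    amplitude_z: float = 1.0
    noise_sd: float = 0.25
    occupancy: float = 1.0
    seed: int = 1729
    chrom: str = "chrS"
    n_nopeak_genes: int = 200

    def __post_init__(self) -> None:
        total = sum(self.mode_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mode proportions sum to {total}, expected 1")
        if self.repeat_bp <= self.footprint_bp:
            raise ValueError("repeat_bp must exceed footprint_bp")

    @property
    def footprint_halfwidth(self) -> int:
        return round(self.footprint_bp / 2)  # 147/2 -> 74

    @property
    def chrom_length(self) -> int:
        return self.site_spacing * (self.n_sites + 1)

    def summits(self) -> np.ndarray:
        return self.site_spacing * np.arange(1, self.n_sites + 1)


def _bump(length_bins: int, center_bp: float, height: float, sd_bp: float,
          bin_size: int, out: np.ndarray) -> None:
    """Add one Gaussian occupancy bump to a binned array (+/- 4 sd support)."""
    lo = max(0, int((center_bp - 4 * sd_bp) // bin_size))
    hi = min(length_bins, int((center_bp + 4 * sd_bp) // bin_size) + 1)
    if hi <= lo:
        return
    x = (np.arange(lo, hi) + 0.5) * bin_size
    out[lo:hi] += height * np.exp(-0.5 * ((x - center_bp) / sd_bp) ** 2)


def simulate_nucleosome_track(chrom_length: int, repeat_bp: int = 190,
                              footprint_bp: int = 147, occupancy: float = 1.0,
                              noise_sd: float = 0.25, seed: int = 0,
                              bin_size: int = 10,
                              chrom: str = "chrS") -> SignalTrack:
    """Periodic nucleosome-occupancy track: phased bumps plus white noise.

    Bumps of height ``occupancy`` and sd ``footprint_bp / 4`` sit at every
    multiple of ``repeat_bp``; white noise of sd ``noise_sd`` is added per
    bin.  Deterministic for a fixed seed.
    """
    if repeat_bp <= footprint_bp:
        raise ValueError("repeat_bp must exceed footprint_bp")
    rng = np.random.default_rng(seed)
    n_bins = chrom_length // bin_size
    values = np.zeros(n_bins)
    sd_bp = footprint_bp / 4
    for center in np.arange(repeat_bp / 2, chrom_length, repeat_bp):
        _bump(n_bins, center, occupancy, sd_bp, bin_size, values)
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, n_bins)
    return SignalTrack({chrom: values}, bin_size=bin_size,
                       origin=f"sim-nucleosome(seed={seed})")


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def _plant_on_array(values: np.ndarray, summit: int, mode: str,
                    rng: np.random.Generator, *, bin_size: int,
                    repeat_bp: int, footprint_bp: int, height: float,
                    amplitude_z: float) -> tuple[int, int, str] | None:
    """Apply one site's mode-specific modification to a raw signal array.

    Returns the planted primary segment geometry (start_offset, end_offset,
    sign) relative to the summit, or None for minimal sites.  ``height`` is
    the nominal bump height in the array's units; ``amplitude_z`` scales the
    canonical attenuation depths.
    """
    n = values.size
    sd_bp = footprint_bp / 4
    depth = min(0.95, 0.8 * amplitude_z)

    def attenuate(center_offset: int, frac: float) -> None:
        _bump(n, summit + center_offset, -frac * height, sd_bp, bin_size, values)

    if mode == "central":
        # evict the nucleosome(s) under the footprint; with the default
        # repeat (190) and footprint (147) exactly one bump qualifies
        _bump(n, summit, -depth * height, sd_bp * 1.2, bin_size, values)
        half = int(footprint_bp / 2 + 2 * sd_bp)
        return (-half, half, "loss")
    if mode == "non_central":
        side = rng.choice([-1, 1])
        k = rng.integers(2, 7)  # bump index: 380-1140 bp from the summit
        offset = int(side * k * repeat_bp)
        attenuate(offset, depth)
        w = int(2 * sd_bp)
        lo, hi = offset - w, offset + w
        return (min(lo, hi), max(lo, hi), "loss")
    if mode == "phased":
        shift = int(rng.integers(40, 81))
        for side in (-1, 1):
            for k in (1, 2):
                center = side * k * repeat_bp
                # move the bump outward: remove at the old position, add at new
                _bump(n, summit + center, -height * min(1.0, amplitude_z),
                      sd_bp, bin_size, values)
                _bump(n, summit + center + side * shift,
                      height * min(1.0, amplitude_z), sd_bp, bin_size, values)
        # the central depletion is both deeper and wider at phased sites
        _bump(n, summit, -depth * height, sd_bp * 1.4, bin_size, values)
        half = int(2 * repeat_bp + shift + 2 * sd_bp)
        return (-half, half, "loss")
    if mode == "minimal":
        return None
    raise ValueError(f"unknown mode {mode!r}")


def plant_remodeling(track_pair: tuple[SignalTrack, SignalTrack],
                     site: GenomicInterval, mode: str,
                     amplitude_z: float = 1.0, seed: int = 0,
                     repeat_bp: int = 190, footprint_bp: int = 147,
                     height: float = 1.0) -> SignalTrack:
    """Plant one remodeling event into the after-track of a condition pair.

    Returns a modified copy of the after-track; the before-track is
    untouched.  The site must sit far enough from the chromosome edge for
    the full flanking-array modification (2 x repeat + footprint).
    """
    before, after = track_pair
    values = after.chrom_values[site.chrom].copy()
    margin = 2 * repeat_bp + footprint_bp + 100
    summit = site.anchor
    if summit < margin or summit > values.size * after.bin_size - margin:
        raise ValueError(f"site {site.name} too close to the chromosome edge")
    rng = np.random.default_rng(seed)
    _plant_on_array(values, summit, mode, rng, bin_size=after.bin_size,
                    repeat_bp=repeat_bp, footprint_bp=footprint_bp,
                    height=height, amplitude_z=amplitude_z)
    new_values = dict(after.chrom_values)
    new_values[site.chrom] = values
    return SignalTrack(new_values, after.bin_size,
                       origin=f"{after.origin}+plant({mode})",
                       normalized=False)


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

#: Pre-stimulation enhancer-mark probabilities per mode; minimal sites first
#: draw "has any prior enhancer" (57 % do not — pioneer candidates).
_STATE_PROBS = {
    "central": {"k4me2": 0.80, "k27ac": 0.60, "dhs": 0.60},
    "non_central": {"k4me2": 0.90, "k27ac": 0.85, "dhs": 0.85},
    "phased": {"k4me2": 0.80, "k27ac": 0.60, "dhs": 0.70},
    "minimal": {"k4me2": 0.80, "k27ac": 0.60, "dhs": 0.50},
}
_MINIMAL_NO_MARKS_P = 0.57
_DHS_GAIN_P = {"central": 0.40, "non_central": 0.10, "phased": 0.70,
               "minimal": 0.10}
_GRE_P = {"central": 0.60, "non_central": 0.50, "phased": 0.90, "minimal": 0.30}
_LOG2FC_MEAN_8H = {"central": 1.2, "non_central": 1.0, "phased": 2.5,
                   "minimal": 1.2}
_GR_SCORE_MEAN = {"central": 40.0, "non_central": 30.0, "phased": 80.0,
                  "minimal": 12.0}

_GRE_SEQ = "AGAACATTGTGTTCT"
_ETS_SEQ = "ACAGGAAG"
_RUNX_SEQ = "TGTGGTC"


@dataclass
class SimulatedCohort:
    """All inputs for one synthetic study, plus the ground truth."""

    config: CohortConfig
    tracks: dict  # (mark, condition) -> SignalTrack; condition in {before, after}
    gr_peaks: list
    k4me2_peaks_before: list
    k27ac_peaks_before: list
    dhs_peaks_before: list
    dhs_peaks_after: list
    cofactor_peaks_after: list
    genome: dict
    tss: list
    expression: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir) -> None:
        """Emit every input as plain-text files (bedGraph, BED, FASTA, TSV)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for (mark, cond), track in self.tracks.items():
            write_bedgraph(track, out / f"{mark}_{cond}.bedGraph")
        write_intervals(self.gr_peaks, out / "gr_peaks.narrowPeak", "narrowpeak")
        write_intervals(self.k4me2_peaks_before, out / "k4me2_before.bed")
        write_intervals(self.k27ac_peaks_before, out / "k27ac_before.bed")
        write_intervals(self.dhs_peaks_before, out / "dhs_before.bed")
        write_intervals(self.dhs_peaks_after, out / "dhs_after.bed")
        write_intervals(self.cofactor_peaks_after,
                        out / "cofactor_after.narrowPeak", "narrowpeak")
        with open(out / "genome.fa", "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        with open(out / "tss.tsv", "w") as fh:
            fh.write("gene\tchrom\ttss\tstrand\n")
            for t in self.tss:
                fh.write(f"{t.gene}\t{t.chrom}\t{t.tss}\t{t.strand}\n")
        self.expression.to_csv(out / "expression.tsv", sep="\t")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def _raster_base(config: CohortConfig) -> np.ndarray:
    """Noise-free bump raster shared by every mark and condition."""
    n_bins = config.chrom_length // config.bin_size
    values = np.zeros(n_bins)
    sd_bp = config.footprint_bp / 4
    for summit in config.summits():
        for k in range(-10, 11):
            _bump(n_bins, summit + k * config.repeat_bp, config.occupancy,
                  sd_bp, config.bin_size, values)
    return values


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, length, dtype=np.int8)


def simulate_cohort(config: CohortConfig | None = None) -> SimulatedCohort:
    """Generate a full synthetic study: tracks, peaks, genome, expression.

    Deterministic per ``config.seed``.  Sites receive modes in the
    configured proportions (assigned by exact quota, then shuffled), each
    planted into the after-condition rasters of the three H3K4 marks;
    H3K27Ac tracks carry mode-specific activation gains; non-central sites
    carry ETS/RUNX consensus sequence in their remodeled segments; phased
    sites carry GREs most often and the largest planted expression effects.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    bs = config.bin_size
    n_bins = config.chrom_length // bs
    summits = config.summits()
    n = config.n_sites

    # --- mode assignment by exact quota, shuffled ---
    modes: list[str] = []
    for mode, frac in config.mode_proportions.items():
        modes.extend([mode] * int(round(frac * n)))
    modes = (modes + ["minimal"] * n)[:n]
    rng.shuffle(modes)

    # --- signal tracks ---
    base = _raster_base(config)
    h3k4_after = base.copy()
    seg_geometry: dict[int, tuple[int, int, str] | None] = {}
    for i, (summit, mode) in enumerate(zip(summits, modes)):
        seg_geometry[i] = _plant_on_array(
            h3k4_after, int(summit), mode, rng, bin_size=bs,
            repeat_bp=config.repeat_bp, footprint_bp=config.footprint_bp,
            height=config.occupancy, amplitude_z=config.amplitude_z)

    fp_hw = config.footprint_halfwidth
    k27_after = base.copy()
    flank_gain_truth = np.zeros(n, dtype=bool)
    sd_bp = config.footprint_bp / 4
    for i, (summit, mode) in enumerate(zip(summits, modes)):
        summit = int(summit)
        if mode == "phased":
            for side in (-1, 1):
                for k in (1, 2):
                    _bump(n_bins, summit + side * k * config.repeat_bp, 0.9,
                          sd_bp * 1.5, bs, k27_after)
            flank_gain_truth[i] = True
        elif mode == "central":
            _bump(n_bins, summit, 0.4, sd_bp * 2, bs, k27_after)
        elif mode == "non_central":
            geom = seg_geometry[i]
            center = (geom[0] + geom[1]) // 2
            _bump(n_bins, summit + center, -0.5, sd_bp, bs, k27_after)
        elif mode == "minimal" and rng.random() < 0.32:
            side = rng.choice([-1, 1])
            for k in (1, 2):
                _bump(n_bins, summit + side * k * config.repeat_bp, 0.9,
                      sd_bp * 1.5, bs, k27_after)
            flank_gain_truth[i] = True

    tracks: dict[tuple[str, str], SignalTrack] = {}
    for mark in H3K4_MARKS + ("H3K27Ac",):
        scale = MARK_SCALE[mark]
        raw_after = k27_after if mark == "H3K27Ac" else h3k4_after
        for cond, raw in (("before", base), ("after", raw_after)):
            noise = rng.normal(0.0, config.noise_sd, n_bins)
            tracks[(mark, cond)] = SignalTrack(
                {config.chrom: scale * (raw + noise)}, bin_size=bs,
                origin=f"{mark}_{cond}")

    # --- peak sets ---
    gr_peaks = []
    for i, (summit, mode) in enumerate(zip(summits, modes)):
        summit = int(summit)
        score = max(1.0, rng.normal(_GR_SCORE_MEAN[mode],
                                    0.3 * _GR_SCORE_MEAN[mode]))
        gr_peaks.append(GenomicInterval(config.chrom, summit - 150,
                                        summit + 150, f"site_{i:04d}",
                                        score, summit))

    def _mark_peak(summit: int, halfwidth: int) -> GenomicInterval:
        return GenomicInterval(config.chrom, max(0, summit - halfwidth),
                               summit + halfwidth)

    k4me2_before, k27ac_before, dhs_before, dhs_after = [], [], [], []
    state_truth = np.zeros((n, 3), dtype=bool)
    dhs_gain_truth = np.zeros(n, dtype=bool)
    for i, (summit, mode) in enumerate(zip(summits, modes)):
        summit = int(summit)
        probs = _STATE_PROBS[mode]
        if mode == "minimal" and rng.random() < _MINIMAL_NO_MARKS_P:
            has = {"k4me2": False, "k27ac": False, "dhs": False}
        else:
            has = {m: bool(rng.random() < p) for m, p in probs.items()}
        state_truth[i] = (has["k4me2"], has["k27ac"], has["dhs"])
        if has["k4me2"]:
            k4me2_before.append(_mark_peak(summit, 800))
        if has["k27ac"]:
            k27ac_before.append(_mark_peak(summit, 700))
        if has["dhs"]:
            dhs_before.append(_mark_peak(summit, 300))
            dhs_after.append(_mark_peak(summit, 300))
        elif rng.random() < _DHS_GAIN_P[mode]:
            dhs_after.append(_mark_peak(summit, 300))
            dhs_gain_truth[i] = True

    # --- genome with planted motifs ---
    seq = _random_seq(rng, config.chrom_length)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def _plant_seq(pos: int, motif: str) -> None:
        enc = np.frombuffer(motif.encode(), dtype=np.uint8)
        idx = np.searchsorted(bases, enc)
        seq[pos:pos + len(motif)] = idx

    gre_truth = np.zeros(n, dtype=bool)
    cofactor_peaks_after = []
    n_noncentral_ets = 0
    for i, (summit, mode) in enumerate(zip(summits, modes)):
        summit = int(summit)
        if rng.random() < _GRE_P[mode]:
            _plant_seq(summit - len(_GRE_SEQ) // 2, _GRE_SEQ)
            gre_truth[i] = True
        if mode == "non_central":
            geom = seg_geometry[i]
            center = summit + (geom[0] + geom[1]) // 2
            motif = _ETS_SEQ if rng.random() < 0.7 else _RUNX_SEQ
            _plant_seq(center - len(motif) // 2, motif)
            if motif == _ETS_SEQ:
                n_noncentral_ets += 1
                # a minority of these acquire inducible cofactor binding
                if rng.random() < 0.09:
                    cofactor_peaks_after.append(GenomicInterval(
                        config.chrom, center - 100, center + 100,
                        f"cof_{i:04d}", 10.0, center))
        else:
            # background ETS occurrences away from the footprint
            if rng.random() < 0.6:
                side = rng.choice([-1, 1])
                off = int(rng.integers(300, 1400))
                _plant_seq(summit + side * off, _ETS_SEQ)
    genome = {config.chrom: "".join("ACGT"[b] for b in seq)}

    # --- genes and expression ---
    tss: list[TssRecord] = []
    gene_of_site: list[str | None] = [None] * n
    planted_fc = np.zeros(n)
    i = 0
    while i < n:
        shared = (i % 5 == 0) and (i + 1 < n)
        gene = f"gene_{i:04d}"
        if shared:
            pos = int((summits[i] + summits[i + 1]) // 2)
            gene_of_site[i] = gene_of_site[i + 1] = gene
        else:
            d = int(rng.integers(1000, 3501)) * int(rng.choice([-1, 1]))
            pos = int(summits[i]) + d
            gene_of_site[i] = gene
        tss.append(TssRecord(gene, config.chrom, pos))
        i += 2 if shared else 1
    genes, fc8, fc24 = [], [], []
    seen = set()
    for i in range(n):
        gene = gene_of_site[i]
        if gene in seen:
            continue
        seen.add(gene)
        mean8 = _LOG2FC_MEAN_8H[modes[i]]
        v8 = rng.normal(mean8, 0.6)
        genes.append(gene)
        fc8.append(v8)
        fc24.append(rng.normal(0.5 * mean8, 0.6))
        planted_fc[i] = v8
    for j in range(config.n_nopeak_genes):
        genes.append(f"nopeak_{j:04d}")
        fc8.append(rng.normal(0.0, 0.6))
        fc24.append(rng.normal(0.0, 0.6))
    expression = pd.DataFrame(
        {"gene": genes, "log2fc_8h": fc8, "log2fc_24h": fc24}).set_index("gene")

    truth = pd.DataFrame({
        "site": [p.name for p in gr_peaks],
        "chrom": config.chrom,
        "summit": summits.astype(int),
        "planted_mode": modes,
        "seg_start": [seg_geometry[i][0] if seg_geometry[i] else 0 for i in range(n)],
        "seg_end": [seg_geometry[i][1] if seg_geometry[i] else 0 for i in range(n)],
        "seg_sign": [seg_geometry[i][2] if seg_geometry[i] else "none"
                     for i in range(n)],
        "has_k4me2": state_truth[:, 0],
        "has_k27ac": state_truth[:, 1],
        "has_dhs": state_truth[:, 2],
        "gained_dhs": dhs_gain_truth,
        "flank_gain_k27ac": flank_gain_truth,
        "has_gre": gre_truth,
        "gene": gene_of_site,
        "planted_log2fc": planted_fc,
        "seed": config.seed,
    })

    return SimulatedCohort(
        config=config, tracks=tracks, gr_peaks=gr_peaks,
        k4me2_peaks_before=k4me2_before, k27ac_peaks_before=k27ac_before,
        dhs_peaks_before=dhs_before, dhs_peaks_after=dhs_after,
        cofactor_peaks_after=cofactor_peaks_after, genome=genome, tss=tss,
        expression=expression, truth=truth)


def make_archetype_matrix(n_sites: int = 400, noise_sd: float = 0.2,
                          seed: int = 0, half_width: int = 1500,
                          bin_size: int = 10):
    """Sites x bins matrix of four fixed delta-profile archetypes plus noise.

    Archetypes (equal counts): central loss, one-sided non-central loss,
    phased alternation, and flat.  Noise sd is given as a fraction of the
    archetype amplitude (1.0).  Returns (ProfileMatrix, labels array).
    """
    from .profile_matrix import ProfileMatrix

    rng = np.random.default_rng(seed)
    n_bins = 2 * half_width // bin_size
    x = (np.arange(n_bins) + 0.5) * bin_size - half_width
    archetypes = np.zeros((4, n_bins))
    archetypes[0] = -np.exp(-0.5 * (x / 150) ** 2)
    archetypes[1] = -np.exp(-0.5 * ((x - 500) / 80) ** 2)
    archetypes[2] = (-np.exp(-0.5 * (x / 120) ** 2)
                     + 0.8 * np.sin(2 * np.pi * np.abs(x) / 190)
                     * np.exp(-np.abs(x) / 600) * (np.abs(x) > 150))
    # archetypes[3] stays flat
    labels = np.repeat(np.arange(4), n_sites // 4)
    labels = np.concatenate([labels, np.zeros(n_sites - labels.size, dtype=int)])
    rng.shuffle(labels)
    values = archetypes[labels] + rng.normal(0.0, noise_sd, (n_sites, n_bins))
    anchors = [GenomicInterval("chrA", i * 4000 + 2000 - 1, i * 4000 + 2000 + 1,
                               f"a_{i:04d}", 0.0, i * 4000 + 2000)
               for i in range(n_sites)]
    return ProfileMatrix(values, anchors, half_width, bin_size,
                         track_origin="archetypes"), labels
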