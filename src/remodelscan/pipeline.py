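"""End-to-end orchestration: tracks -> delta -> matrix -> clusters -> modes
-> enhancer state -> motifs -> genes, from one validated configuration.

The pipeline mirrors the analysis order of the method: per-condition tracks
are z-scored, subtracted and summed into the composite delta signal; a
summit-anchored matrix is clustered; clusters are classified into the four
remodeling modes; and the downstream association analyses (enhancer state,
activation, motif enrichment, gene expression) are run per mode.  Every
stage writes its intermediate, and a JSON report collects the headline
numbers, the full parameter set and a parameter hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .genomic_signal import (GenomicInterval, add_tracks, read_intervals,
                             read_track, subtract_tracks, write_bedgraph,
                             zscore_normalize)
from .profile_matrix import auc_score, build_matrix
from .remodeling_cluster import kmeans_cluster
from .mode_classifier import (ClassifierParams, MODES, assign_modes,
                              profile_features)
from .enhancer_state import (annotate_state, call_activation, category_counts,
                             compare_modes, DEFAULT_GAIN_THRESHOLD)
from .motif_scan import (default_pwms, extract_noncentral_sequences,
                         inducible_binding_fraction, scan_pwm)
from .mode_classifier import RemodelingSegment, call_segments
from .gene_association import (assign_nearest_gene, filter_consistent_genes,
                               mode_expression_test, read_expression_table,
                               read_tss_table)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "run_cohort"]

log = logging.getLogger("remodelscan")

_SECTION_KEYS = {
    "tracks": {"h3k4me1_before", "h3k4me1_after", "h3k4me2_before",
               "h3k4me2_after", "h3k4me3_before", "h3k4me3_after",
               "h3k27ac_before", "h3k27ac_after", "format", "bin_size"},
    "peaks": {"gr", "k4me2_before", "k27ac_before", "dhs_before", "dhs_after",
              "cofactor_after"},
    "genome": {"fasta"},
    "genes": {"tss", "expression"},
    "matrix": {"half_width"},
    "cluster": {"k", "restarts", "row_scale"},
    "classifier": {"threshold_z", "min_segment_length", "merge_gap",
                   "footprint_halfwidth", "flank_limit", "smooth_sd_bp",
                   "phased_min_spacing", "phased_max_spacing",
                   "phased_min_alternations", "phased_sides",
                   "member_support", "per_site"},
    "activation": {"gain_threshold"},
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated pipeline configuration (TOML-loadable)."""

    tracks: dict
    peaks: dict
    outdir: str
    seed: int = 1729
    genome: dict = field(default_factory=dict)
    genes: dict = field(default_factory=dict)
    matrix: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    activation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for section, allowed in _SECTION_KEYS.items():
            value = getattr(self, section)
            unknown = set(value) - allowed
            if unknown:
                raise ValueError(
                    f"unknown key(s) {sorted(unknown)} in section [{section}]")
        required = ["h3k4me1_before", "h3k4me1_after", "h3k4me2_before",
                    "h3k4me2_after", "h3k4me3_before", "h3k4me3_after"]
        missing = [k for k in required if k not in self.tracks]
        if missing:
            raise ValueError(f"missing required track path(s): {missing}")
        if "gr" not in self.peaks:
            raise ValueError("missing required peak path: peaks.gr")
        for section in ("tracks", "peaks", "genome", "genes"):
            for key, path in getattr(self, section).items():
                if key in ("format", "bin_size"):
                    continue
                if not Path(path).exists():
                    raise ValueError(f"{section}.{key}: file not found: {path}")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = set(_SECTION_KEYS) | {"outdir", "seed"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
        return cls(**data)

    def param_hash(self) -> str:
        payload = json.dumps(
            {s: getattr(self, s) for s in
             ("matrix", "cluster", "classifier", "activation")}
            | {"seed": self.seed}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _classifier_params(config: RunConfig) -> ClassifierParams:
    kwargs = {k: v for k, v in config.classifier.items() if k != "per_site"}
    return ClassifierParams(**kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the JSON run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software": {"package": "remodelscan", "version": __version__},
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "parameters": {s: getattr(config, s) for s in
                       ("matrix", "cluster", "classifier", "activation")},
    }
    fmt = config.tracks.get("format", "bedGraph")
    bin_size = int(config.tracks.get("bin_size", 10))

    # --- stage 1: normalize and combine tracks ---
    stage = "tracks"
    try:
        log.info("reading and normalizing tracks")
        deltas = []
        for mark in ("h3k4me1", "h3k4me2", "h3k4me3"):
            before = zscore_normalize(read_track(
                config.tracks[f"{mark}_before"], fmt, bin_size, f"{mark}_before"))
            after = zscore_normalize(read_track(
                config.tracks[f"{mark}_after"], fmt, bin_size, f"{mark}_after"))
            deltas.append(subtract_tracks(after, before))
        delta_h3k4 = add_tracks(deltas)
        write_bedgraph(delta_h3k4, outdir / "delta_h3k4methyls.bedGraph")
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, str(exc)) from exc

    # --- stage 2: summit-anchored matrix ---
    stage = "matrix"
    try:
        gr_peaks = read_intervals(config.peaks["gr"], "narrowpeak")
        half_width = int(config.matrix.get("half_width", 1500))
        matrix = build_matrix(delta_h3k4, gr_peaks, half_width)
        log.info("matrix: %d sites x %d bins (%d dropped)",
                 matrix.n_sites, matrix.n_bins, len(matrix.dropped))
        matrix.to_tsv(outdir / "delta_matrix.tsv.gz")
        report["n_sites"] = matrix.n_sites
        report["n_dropped_anchors"] = len(matrix.dropped)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage 3: clustering ---
    stage = "cluster"
    try:
        clusters = kmeans_cluster(
            matrix, k=int(config.cluster.get("k", 27)),
            restarts=int(config.cluster.get("restarts", 10)),
            seed=config.seed,
            row_scale=bool(config.cluster.get("row_scale", False)))
        np.savetxt(outdir / "cluster_labels.tsv",
                   np.column_stack([matrix.site_names(), clusters.labels]),
                   fmt="%s", delimiter="\t", header="site\tcluster")
        report["cluster"] = {"k": clusters.k, "wss": clusters.wss,
                             "seed": clusters.seed}
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage 4: mode classification ---
    stage = "classify"
    try:
        params = _classifier_params(config)
        peak_by_name = {p.name: p for p in gr_peaks}
        footprints = [peak_by_name.get(a.name) for a in matrix.anchors]
        calls = assign_modes(matrix, clusters, footprints, params,
                             per_site=bool(config.classifier.get("per_site",
                                                                 False)))
        mode_counts = {m: sum(1 for c in calls if c.mode == m) for m in MODES}
        report["mode_counts"] = mode_counts
        report["mode_fractions"] = {
            m: mode_counts[m] / max(1, matrix.n_sites) for m in MODES}
        with open(outdir / "mode_calls.tsv", "w") as fh:
            fh.write("site\tchrom\tsummit\tcluster\tmode\tcentral_loss\t"
                     "flank_losses\talternations\n")
            for anchor, c in zip(matrix.anchors, calls):
                fh.write(f"{c.site}\t{anchor.chrom}\t{anchor.anchor}\t"
                         f"{c.cluster}\t{c.mode}\t{int(c.central_loss)}\t"
                         f"{c.flank_losses[0]},{c.flank_losses[1]}\t"
                         f"{c.alternations[0]},{c.alternations[1]}\n")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    mode_of = {c.site: c.mode for c in calls}
    anchors_by_mode: dict[str, list[GenomicInterval]] = {m: [] for m in MODES}
    for anchor, c in zip(matrix.anchors, calls):
        anchors_by_mode[c.mode].append(anchor)

    # --- stage 5: enhancer state and mode statistics ---
    stage = "state"
    try:
        have_states = all(k in config.peaks for k in
                          ("k4me2_before", "k27ac_before", "dhs_before"))
        if have_states:
            states = annotate_state(
                matrix.anchors,
                read_intervals(config.peaks["k4me2_before"]),
                read_intervals(config.peaks["k27ac_before"]),
                read_intervals(config.peaks["dhs_before"]),
                window_halfwidth=half_width)
            report["enhancer_categories"] = category_counts(states)
        # GR peak size (score) by mode, KS vs all sites
        scores_by_mode = {
            m: np.array([peak_by_name[a.name].score
                         for a in anchors_by_mode[m]])
            for m in MODES if anchors_by_mode[m]}
        all_scores = np.array([peak_by_name[a.name].score
                               for a in matrix.anchors])
        ks = compare_modes(scores_by_mode, "ks", all_scores)
        report["gr_size_ks"] = {m: {"D": s, "p": p} for m, (s, p) in ks.items()}
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage 6: activation (H3K27Ac delta, DHS gain) ---
    stage = "activation"
    try:
        if "h3k27ac_before" in config.tracks and "h3k27ac_after" in config.tracks:
            k27_before = zscore_normalize(read_track(
                config.tracks["h3k27ac_before"], fmt, bin_size))
            k27_after = zscore_normalize(read_track(
                config.tracks["h3k27ac_after"], fmt, bin_size))
            delta_k27 = subtract_tracks(k27_after, k27_before)
            k27_matrix = build_matrix(delta_k27, matrix.anchors, half_width)
            activations = call_activation(
                k27_matrix, footprints,
                gain_threshold=float(config.activation.get(
                    "gain_threshold", DEFAULT_GAIN_THRESHOLD)),
                dhs_peaks_before=read_intervals(config.peaks["dhs_before"])
                if "dhs_before" in config.peaks else [],
                dhs_peaks_after=read_intervals(config.peaks["dhs_after"])
                if "dhs_after" in config.peaks else [])
            act_by_mode: dict[str, dict] = {}
            for m in MODES:
                acts = [a for a in activations if mode_of[a.site] == m]
                if acts:
                    act_by_mode[m] = {
                        "n": len(acts),
                        "dhs_gain_fraction": float(np.mean(
                            [a.gained_dhs for a in acts])),
                        "flank_gain_fraction": float(np.mean(
                            [a.flank_gain for a in acts])),
                        "median_delta_k27ac_auc": float(np.median(
                            [a.delta_auc for a in acts]))}
            report["activation_by_mode"] = act_by_mode
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage 7: motifs at non-central segments ---
    stage = "motifs"
    try:
        if "fasta" in config.genome:
            from pyfaidx import Fasta
            genome = Fasta(str(config.genome["fasta"]))
            segs_by_site: dict[str, list[RemodelingSegment]] = {}
            for i, c in enumerate(calls):
                segs_by_site[c.site] = call_segments(
                    matrix.values[i], matrix.bin_size, matrix.half_width,
                    params.threshold_z, params.min_segment_length,
                    params.merge_gap)
            pairs = extract_noncentral_sequences(
                calls, segs_by_site, matrix.anchors, genome)
            pwms = default_pwms()
            report["n_noncentral_sequences"] = len(pairs)
            motif_hit_fraction = {}
            for name, pwm in pwms.items():
                hit = sum(1 for _, s in pairs if scan_pwm(s, pwm))
                motif_hit_fraction[name] = hit / len(pairs) if pairs else 0.0
            report["noncentral_motif_hit_fraction"] = motif_hit_fraction
            if "cofactor_after" in config.peaks:
                ets = pwms["ETS"]
                hits_all, hits_nc = [], []
                nc_sites = {c.site for c in calls if c.mode == "non_central"}
                for anchor in matrix.anchors:
                    s = anchor.anchor - half_width
                    seq = str(genome[anchor.chrom][s:anchor.anchor + half_width])
                    site_hits = scan_pwm(seq.upper(), ets, anchor.chrom, s)
                    hits_all.extend(site_hits)
                    if anchor.name in nc_sites:
                        hits_nc.extend(site_hits)
                cof = read_intervals(config.peaks["cofactor_after"])
                frac_all = inducible_binding_fraction(
                    hits_all, matrix.anchors, gr_peaks, cof, half_width)
                nc_anchors = anchors_by_mode["non_central"]
                frac_nc = (inducible_binding_fraction(
                    hits_nc, nc_anchors, gr_peaks, cof, half_width)
                    if hits_nc and nc_anchors else None)
                report["ets_inducible_fraction"] = {
                    "all_sites": frac_all, "non_central_sites": frac_nc}
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage 8: gene association and expression ---
    stage = "genes"
    try:
        if "tss" in config.genes and "expression" in config.genes:
            tss = read_tss_table(config.genes["tss"])
            expression = read_expression_table(config.genes["expression"])
            associations, unassigned = assign_nearest_gene(
                matrix.anchors, mode_of, tss)
            gene_modes = filter_consistent_genes(associations)
            report["genes"] = {
                "n_assigned": len(associations),
                "n_unassigned": unassigned,
                "n_consistent_genes": len(gene_modes)}
            for direction in ("induced", "repressed"):
                report["genes"][f"expression_{direction}"] = (
                    mode_expression_test(gene_modes, expression, direction))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    log.info("report written to %s", outdir / "report.json")
    return report


def run_cohort(cohort, outdir, seed: int | None = None,
               classifier: dict | None = None,
               cluster: dict | None = None) -> dict:
    """Write a simulated cohort to disk and run the full pipeline on it.

    Convenience wrapper used by tests and the acceptance analysis; returns
    the run report.
    """
    outdir = Path(outdir)
    data_dir = outdir / "inputs"
    cohort.write(data_dir)
    config = RunConfig(
        tracks={
            "h3k4me1_before": str(data_dir / "H3K4me1_before.bedGraph"),
            "h3k4me1_after": str(data_dir / "H3K4me1_after.bedGraph"),
            "h3k4me2_before": str(data_dir / "H3K4me2_before.bedGraph"),
            "h3k4me2_after": str(data_dir / "H3K4me2_after.bedGraph"),
            "h3k4me3_before": str(data_dir / "H3K4me3_before.bedGraph"),
            "h3k4me3_after": str(data_dir / "H3K4me3_after.bedGraph"),
            "h3k27ac_before": str(data_dir / "H3K27Ac_before.bedGraph"),
            "h3k27ac_after": str(data_dir / "H3K27Ac_after.bedGraph"),
            "bin_size": cohort.config.bin_size,
        },
        peaks={
            "gr": str(data_dir / "gr_peaks.narrowPeak"),
            "k4me2_before": str(data_dir / "k4me2_before.bed"),
            "k27ac_before": str(data_dir / "k27ac_before.bed"),
            "dhs_before": str(data_dir / "dhs_before.bed"),
            "dhs_after": str(data_dir / "dhs_after.bed"),
            "cofactor_after": str(data_dir / "cofactor_after.narrowPeak"),
        },
        genome={"fasta": str(data_dir / "genome.fa")},
        genes={"tss": str(data_dir / "tss.tsv"),
               "expression": str(data_dir / "expression.tsv")},
        outdir=str(outdir / "results"),
        seed=seed if seed is not None else cohort.config.seed,
        classifier=classifier or {},
        cluster=cluster or {},
    )
    return run_pipeline(config)
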