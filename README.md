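# remodelscan

Classification of transcription-factor-associated **nucleosome remodeling
modes** from paired-condition, MNase-based histone-modification ChIP-seq
signal.

When a ligand-activated factor such as the glucocorticoid receptor (GR)
engages chromatin, the nucleosomes around its binding site are evicted,
repositioned, or left alone — and these outcomes have distinct consequences
for enhancer activation and gene expression. `remodelscan` detects and
classifies these events from signal tracks alone:

1. **Delta signal.** Per-condition tracks for H3K4me1/me2/me3 are globally
   z-scored (mean 0, sd 1), the unstimulated track is subtracted from the
   stimulated one, and the three methylation deltas are summed into a
   composite remodeling signal (ΔH3K4methyls). Because MNase-digested
   native chromatin is the ChIP substrate, a drop in this signal reports a
   loss or shift of the underlying nucleosome.
2. **Summit-anchored profiles.** The delta signal is extracted in a 3-kb
   window centered on each TF peak summit (sites × 300 bins at 10-bp
   resolution).
3. **Clustering.** Profiles are partitioned by k-means (default k = 27;
   the within-cluster sum-of-squares curve over k = 5–80 suggests an
   elbow, and `--k` overrides it).
4. **Mode classification.** Each cluster's mean profile is reduced to
   significant-delta segments (|z| ≥ 0.3 over ≥ 100 bp) and assigned one of
   four modes, inherited by its member sites:
   - **central** — signal loss confined to the TF footprint (eviction
     under the factor),
   - **non_central** — loss outside the footprint but within 1.5 kb
     (cofactor-associated eviction),
   - **phased** — alternating flanking gains/losses at nucleosomal spacing
     plus a central loss (repositioning of the flanking array),
   - **minimal** — none of the above.
5. **Downstream association.** Per-mode enhancer state (H3K4me2 / H3K27Ac /
   DHS overlap before stimulation), activation (ΔDHS, ΔH3K27Ac AUC,
   flank-specific gains), PWM motif enrichment (GRE, ETS, RUNX) in
   non-centrally remodeled sequence, inducible cofactor-binding fractions,
   and nearest-gene (≤ 500 kb) expression tests (KS, Fisher exact,
   Mann–Whitney).

A fully seeded synthetic-cohort generator plants all four modes at known
sites, so every stage is testable without any sequencing data.

## Worked example

Simulate a small cohort and run the full pipeline:

```python
import remodelscan as rs

cohort = rs.simulate_cohort(rs.CohortConfig(n_sites=400, seed=1))
report = rs.run_cohort(cohort, "scratch/demo")
print(report["mode_counts"])
```

```
{'central': 100, 'non_central': 196, 'phased': 24, 'minimal': 80}
```

The cohort planted 25 % central, 49 % non-central, 6 % phased and 20 %
minimal sites; the pipeline recovers those proportions (196/400 = 49 %
non-central, 24/400 = 6 % phased). `scratch/demo/results/` contains the
composite delta track (bedGraph), the summit-anchored matrix (gzip TSV),
per-site mode calls (TSV) and the JSON run report with enhancer-state
counts, per-mode activation summaries, motif-hit fractions and
expression-test p-values.

The same analysis is scriptable from the shell:

```bash
remodelscan simulate --n-sites 400 --seed 1 --outdir scratch/inputs
remodelscan tracks delta scratch/inputs/H3K4me2_after.bedGraph \
    scratch/inputs/H3K4me2_before.bedGraph --output scratch/d_k4me2.bedGraph
remodelscan run --config run.toml
```

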