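"""Peak-to-gene assignment and mode-wise expression tests.

Each TF binding site is assumed to modulate its nearest gene, provided that
gene's transcriptional start site lies within 500 kb of the peak summit.
Genes reached by several peaks keep only a single mode when all their peaks
agree; mode-wise log2 fold-change distributions are then compared against
genes with no proximal peak by Mann–Whitney, separately for induced and
repressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_signal import GenomicInterval
from .mode_classifier import ModeCall

__all__ = [
    "GeneAssociation",
    "TssRecord",
    "assign_nearest_gene",
    "filter_consistent_genes",
    "mode_expression_test",
    "read_tss_table",
    "read_expression_table",
]

MAX_DISTANCE_DEFAULT = 500_000


@dataclass(frozen=True)
class TssRecord:
    gene: str
    chrom: str
    tss: int
    strand: str = "+"


@dataclass(frozen=True)
class GeneAssociation:
    """One site assigned to its nearest gene (summit-to-TSS distance)."""

    site: str
    gene: str
    tss: int
    distance: int
    mode: str


def read_tss_table(path) -> list[TssRecord]:
    """Read a TSS table: BED6 (TSS = start) or TSV (gene, chrom, tss, strand)."""
    records = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#") or parts[0] == "gene":
                continue
            if parts[1].isdigit() and len(parts) >= 3 and parts[2].isdigit():
                # BED6: chrom start end name score strand
                records.append(TssRecord(parts[3], parts[0], int(parts[1]),
                                         parts[5] if len(parts) > 5 else "+"))
            else:
                records.append(TssRecord(parts[0], parts[1], int(parts[2]),
                                         parts[3] if len(parts) > 3 else "+"))
    return records


def read_expression_table(path) -> pd.DataFrame:
    """Read the gene-level log2 fold-change table (gene, log2fc_8h, log2fc_24h)."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("gene")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("expression table contains non-finite values")
    return df


def assign_nearest_gene(sites: list[GenomicInterval],
                        modes: dict[str, str],
                        tss_table: list[TssRecord],
                        max_distance: int = MAX_DISTANCE_DEFAULT,
                        ) -> tuple[list[GeneAssociation], int]:
    """Assign each site to the nearest TSS within ``max_distance``.

    Distance is unsigned summit-to-TSS, strand-ignored; equidistant TSS ties
    break to the lexicographically smaller gene identifier.  Returns the
    assignments plus the count of sites left unassigned (no TSS in range on
    the site's chromosome).
    """
    if not tss_table:
        raise ValueError("TSS table is empty")
    genes = {t.gene for t in tss_table}
    if len(genes) != len(tss_table):
        raise ValueError("TSS table has duplicate gene identifiers")
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in {t.chrom for t in tss_table}:
        recs = sorted((t for t in tss_table if t.chrom == chrom),
                      key=lambda t: (t.tss, t.gene))
        by_chrom[chrom] = (np.array([t.tss for t in recs]), [t.gene for t in recs])

    out: list[GeneAssociation] = []
    unassigned = 0
    for site in sites:
        entry = by_chrom.get(site.chrom)
        if entry is None:
            unassigned += 1
            continue
        positions, names = entry
        summit = site.anchor
        i = int(np.searchsorted(positions, summit))
        # candidates: nearest on either side, plus equals
        cand = [j for j in (i - 1, i, i + 1) if 0 <= j < positions.size]
        best = min(cand, key=lambda j: (abs(int(positions[j]) - summit), names[j]))
        dist = abs(int(positions[best]) - summit)
        if dist > max_distance:
            unassigned += 1
            continue
        out.append(GeneAssociation(
            site=site.name, gene=names[best], tss=int(positions[best]),
            distance=dist, mode=modes.get(site.name, "unclassified")))
    return out, unassigned


def filter_consistent_genes(associations: list[GeneAssociation]) -> dict[str, str]:
    """Keep genes whose associated peaks all share one mode.

    Genes reached by >= 2 peaks of differing modes are dropped; the rest
    map to their common mode.
    """
    modes_by_gene: dict[str, set[str]] = {}
    for assoc in associations:
        modes_by_gene.setdefault(assoc.gene, set()).add(assoc.mode)
    return {g: next(iter(m)) for g, m in modes_by_gene.items() if len(m) == 1}


def mode_expression_test(gene_mode_map: dict[str, str],
                         expression: pd.DataFrame,
                         direction: str,
                         timepoint: str = "log2fc_8h") -> dict[str, dict]:
    """Mann–Whitney of each mode's gene fold changes vs no-peak genes.

    ``direction`` selects the stratum: ``induced`` keeps genes with
    log2fc > 0 at the timepoint, ``repressed`` keeps log2fc < 0 (zeros are
    excluded).  Within the stratum, each mode's genes are compared two-sided
    against genes with no proximal site.  Empty strata are reported as
    not-testable records rather than raised.
    """
    if direction not in ("induced", "repressed"):
        raise ValueError("direction must be 'induced' or 'repressed'")
    if timepoint not in expression.columns:
        raise ValueError(f"timepoint {timepoint!r} not in expression table")
    fc = expression[timepoint]
    stratum = fc[fc > 0] if direction == "induced" else fc[fc < 0]
    nopeak = stratum[~stratum.index.isin(gene_mode_map)]
    if nopeak.empty:
        raise ValueError("no-peak gene set is empty in this stratum")
    results: dict[str, dict] = {}
    modes = sorted(set(gene_mode_map.values()))
    for mode in modes:
        genes = [g for g, m in gene_mode_map.items() if m == mode]
        values = stratum[stratum.index.isin(genes)]
        if values.empty:
            results[mode] = {"testable": False, "n": 0,
                             "statistic": None, "p_value": None}
            continue
        method = "exact" if min(values.size, nopeak.size) <= 8 else "asymptotic"
        res = stats.mannwhitneyu(values.to_numpy(), nopeak.to_numpy(),
                                 alternative="two-sided", method=method)
        results[mode] = {"testable": True, "n": int(values.size),
                         "statistic": float(res.statistic),
                         "p_value": float(res.pvalue),
                         "median_log2fc": float(values.median())}
    return results
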