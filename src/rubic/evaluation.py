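"""Benchmark metrics, region filters and the rotation enrichment test.

The metrics score how well called regions recover a known driver-gene set:
the proportion of drivers hit, the proportion of regions hitting no driver
(the measured FDR), and two per-region focality measures — the fraction of a
region's genes that are drivers, and one over the region's gene count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rubic.data_io import GeneTable, InputError

__all__ = [
    "MetricReport",
    "overlapping_genes",
    "filter_regions",
    "compute_metrics",
    "enrichment_test",
]


def overlapping_genes(genes: GeneTable, chrom: str, start: int, end: int) -> list[str]:
    """Names of genes overlapping ``chrom:start-end`` by at least one base."""
    mask = (genes.chrom == chrom) & (genes.start < end) & (genes.end > start)
    return list(genes.gene_name[mask])


def _regions_hit(genes: GeneTable, regions: pd.DataFrame) -> np.ndarray:
    """Boolean per gene: overlapped by at least one region."""
    hit = np.zeros(len(genes), dtype=bool)
    for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
        hit |= (genes.chrom == chrom) & (genes.start < end) & (genes.end > start)
    return hit


@dataclass
class MetricReport:
    """Driver-recovery metrics; a metric with an empty denominator is None."""

    tp_driver_prop: float | None
    fp_region_prop: float | None
    mean_driver_fraction: float | None
    mean_inverse_gene_count: float | None
    n_regions: int
    n_drivers: int

    def to_dict(self) -> dict:
        return {
            "tp_driver_prop": self.tp_driver_prop,
            "fp_region_prop": self.fp_region_prop,
            "mean_driver_fraction": self.mean_driver_fraction,
            "mean_inverse_gene_count": self.mean_inverse_gene_count,
            "n_regions": self.n_regions,
            "n_drivers": self.n_drivers,
        }


def filter_regions(
    regions: pd.DataFrame,
    genes: GeneTable | None = None,
    max_width: int | None = 10_000_000,
    require_gene_overlap: bool = True,
) -> pd.DataFrame:
    """Drop regions with no overlapping gene and regions wider than the cap.

    When ``genes`` is provided the ``genes`` column is (re)computed before
    filtering; otherwise the existing annotation is used.  Filters only
    remove rows — coordinates and order are untouched.
    """
    regions = regions.copy()
    if genes is not None:
        regions["genes"] = [
            overlapping_genes(genes, c, s, e)
            for c, s, e in zip(regions["chrom"], regions["start"], regions["end"])
        ]
    keep = np.ones(len(regions), dtype=bool)
    if require_gene_overlap:
        keep &= np.array([len(g) > 0 for g in regions["genes"]], dtype=bool)
    if max_width is not None:
        keep &= (regions["end"] - regions["start"]).to_numpy() <= max_width
    return regions.loc[keep]


def compute_metrics(
    regions: pd.DataFrame, drivers: GeneTable, all_genes: GeneTable
) -> MetricReport:
    """Score a region table against known drivers (overlap = >= 1 bp).

    ``mean_driver_fraction`` averages, over regions overlapping at least one
    gene, the fraction of those genes that are drivers;
    ``mean_inverse_gene_count`` averages one over the gene count of the same
    regions (the region "driver density" focality measure).
    """
    n_regions = len(regions)
    n_drivers = len(drivers)

    tp = None
    if n_drivers:
        tp = float(_regions_hit(drivers, regions).mean()) if n_regions else 0.0

    fp = None
    fractions = []
    inv_counts = []
    if n_regions:
        fp_count = 0
        for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
            d_hit = int(
                ((drivers.chrom == chrom) & (drivers.start < end) & (drivers.end > start)).sum()
            )
            g_hit = int(
                (
                    (all_genes.chrom == chrom)
                    & (all_genes.start < end)
                    & (all_genes.end > start)
                ).sum()
            )
            if d_hit == 0:
                fp_count += 1
            if g_hit > 0:
                fractions.append(d_hit / g_hit)
                inv_counts.append(1.0 / g_hit)
        fp = fp_count / n_regions
    return MetricReport(
        tp_driver_prop=tp,
        fp_region_prop=fp,
        mean_driver_fraction=float(np.mean(fractions)) if fractions else None,
        mean_inverse_gene_count=float(np.mean(inv_counts)) if inv_counts else None,
        n_regions=n_regions,
        n_drivers=n_drivers,
    )


def _chrom_layout(genome) -> tuple[list[str], np.ndarray]:
    """Chromosome names and cumulative offsets from a mapping or genome model."""
    if hasattr(genome, "names") and hasattr(genome, "lengths"):
        names = list(genome.names)
        lengths = np.asarray(genome.lengths, dtype=np.int64)
    elif isinstance(genome, dict):
        names = list(genome)
        lengths = np.asarray([genome[n] for n in names], dtype=np.int64)
    else:
        raise InputError("genome must be a {chrom: length} mapping or a genome model")
    if (lengths <= 0).any():
        raise InputError("chromosome lengths must be positive")
    offsets = np.concatenate(([0], np.cumsum(lengths)))
    return names, offsets


def enrichment_test(
    regions: pd.DataFrame,
    gene_set: GeneTable,
    genome,
    n_rot: int = 10_000,
    seed: int = 0,
    offsets=None,
) -> float:
    """Cyclic-rotation enrichment test of called regions against a gene set.

    The statistic is the number of gene-set members overlapped by at least
    one region.  The null rotates *all regions jointly* by a random offset
    along the concatenated genome (wrapping at the end), preserving the
    regions' relative spacing.  Returns
    ``(1 + #{rotations with statistic >= observed}) / (1 + n_rot)``.
    ``offsets`` overrides the random draw with explicit rotation offsets
    (e.g. for exhaustive enumeration on a small genome).
    """
    names, cum = _chrom_layout(genome)
    off_of = {n: cum[i] for i, n in enumerate(names)}
    L = int(cum[-1])

    gs = np.array([off_of[c] + s for c, s in zip(gene_set.chrom, gene_set.start)], dtype=np.int64)
    ge = np.array([off_of[c] + e for c, e in zip(gene_set.chrom, gene_set.end)], dtype=np.int64)
    if len(regions) == 0:
        return 1.0
    rs = np.array([off_of[c] + s for c, s in zip(regions["chrom"], regions["start"])], dtype=np.int64)
    rw = (regions["end"] - regions["start"]).to_numpy(dtype=np.int64)

    def statistic(shift: int) -> int:
        hit = np.zeros(len(gs), dtype=bool)
        starts = (rs + shift) % L
        ends = starts + rw
        for a, b in zip(starts, ends):
            if b <= L:
                hit |= (gs < b) & (ge > a)
            else:  # wraps past the end of the concatenated genome
                hit |= (gs < L) & (ge > a)
                hit |= (gs < b - L) & (ge > 0)
        return int(hit.sum())

    observed = statistic(0)
    if offsets is None:
        if n_rot < 1:
            raise InputError("n_rot must be >= 1")
        rng = np.random.default_rng(seed)
        offsets = rng.integers(0, L, size=n_rot)
    offsets = np.asarray(offsets, dtype=np.int64)
    exceed = sum(1 for k in offsets if statistic(int(k)) >= observed)
    return (1 + exceed) / (1 + len(offsets))
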