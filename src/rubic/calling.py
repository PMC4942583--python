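"""Region calling: local maxima, FDR-adaptive threshold, null refinement.

A called region is a *local maximum* segment of the segmented aggregate —
bordered by a positive jump on its left and a negative jump on its right —
so for the gain half of the data it is a candidate recurrent amplification
(and, run on the mirrored loss half, a candidate recurrent deletion).

``E/2`` bounds the expected number of false-positive local-maximum segments,
which links the clustering threshold directly to a Benjamini–Hochberg-style
iteration on called regions: starting from ``E = 2 * fdr``, the threshold is
repeatedly reset to ``n * 2 * fdr`` for the current region count ``n`` until
the count stabilises.  Because the cyclic-shift null is contaminated by true
driver breaks, the null can optionally be re-estimated after deleting, in
every sample, the breakpoints that fall inside called break windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from rubic.break_stats import (
    AggregateProfile,
    EulerCurveTable,
    NullConfig,
    aggregate,
    estimate_euler_curves,
)
from rubic.data_io import (
    CopyNumberMatrix,
    GeneTable,
    InputError,
    ProbeMap,
    REGION_COLUMNS,
    empty_region_table,
    split_gains_losses,
)
from rubic.evaluation import filter_regions, overlapping_genes
from rubic.segmentation import SegmentationResult, segment_genome

logger = logging.getLogger(__name__)

__all__ = [
    "CallingConfig",
    "call_local_maxima",
    "adaptive_threshold",
    "refine_null",
    "run_rubic",
]

#: extra bookkeeping columns carried on region tables (probe-index geometry)
_PROBE_COLUMNS = ["_start_probe", "_end_probe", "_left_bound", "_right_bound"]


@dataclass
class CallingConfig:
    """User-facing knobs of the calling step.

    ``fdr`` is the target false discovery rate on called regions (the only
    essential parameter).  ``max_region_width`` (bp) and
    ``require_gene_overlap`` are the post-hoc region filters; set
    ``max_region_width=None`` to disable the width filter.
    """

    fdr: float = 0.25
    max_bh_iters: int = 50
    max_null_refinements: int = 3
    max_region_width: int | None = 10_000_000
    require_gene_overlap: bool = True
    refine_margin: int = 0  # probes added either side of a break window

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise InputError("fdr must be in (0, 1)")


def _empty_regions() -> pd.DataFrame:
    df = empty_region_table()
    for c in _PROBE_COLUMNS:
        df[c] = pd.Series(dtype=np.int64)
    return df


def call_local_maxima(seg: SegmentationResult, direction: str = "gain") -> pd.DataFrame:
    """Call local-maximum segments of a segmentation as candidate regions.

    A segment qualifies only when bordered by a positive jump discontinuity
    on its left *and* a negative one on its right.  Chromosome-end segments
    (which lack one bounding break) are never called: a called region must be
    enclosed by a recurrent positive and a recurrent negative break, which is
    what keeps the expected number of false-positive regions below ``E/2``
    (each false region spends one component of each excursion set).

    Region coordinates run from the first base of the segment's first probe
    to the base before the first probe right of the segment (half-open).
    """
    probes = seg.probes
    pos = probes.pos
    bound_of = {int(p): i for i, p in enumerate(seg.bound_pos)}
    rows = []
    for chrom, sl in probes.chrom_slices():
        idx = np.flatnonzero(seg.seg_chrom == chrom)
        m = len(idx)
        if m < 3:
            continue
        for si in idx[1:-1]:
            left = bound_of[int(seg.seg_start[si])]
            right = bound_of[int(seg.seg_end[si])]
            if not (seg.bound_jump[left] > 0 and seg.bound_jump[right] < 0):
                continue
            s_probe = int(seg.seg_start[si])
            e_probe = int(seg.seg_end[si])
            end_bp = int(pos[e_probe]) if e_probe < sl.stop else int(pos[e_probe - 1]) + 1
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[s_probe]),
                    "end": end_bp,
                    "direction": direction,
                    "amplitude": float(seg.amplitude[si]),
                    "left_sig": float(seg.bound_sig[left]),
                    "right_sig": float(seg.bound_sig[right]),
                    "genes": [],
                    "_start_probe": s_probe,
                    "_end_probe": e_probe,
                    "_left_bound": s_probe,
                    "_right_bound": e_probe,
                }
            )
    if not rows:
        return _empty_regions()
    return pd.DataFrame(rows, columns=REGION_COLUMNS + _PROBE_COLUMNS)


def adaptive_threshold(
    call_at: Callable[[float], pd.DataFrame],
    cfg: CallingConfig,
) -> tuple[float, pd.DataFrame]:
    """Adapt the global threshold ``E`` to the target region-level FDR.

    ``call_at`` maps a threshold to the region table obtained by segmenting
    and calling at that threshold.  Starting from ``E0 = 2 * fdr``, the
    threshold is reset to ``n * 2 * fdr`` for the current count ``n`` until
    the count repeats (``E/2`` false positives out of ``n`` calls is then the
    target rate).  An empty first call returns ``(E0, empty)``; an
    oscillating count returns the smaller-count member of the cycle with a
    warning.
    """
    E, regions, _ = _adapt(call_at, cfg)
    return E, regions


def _adapt(call_at, cfg: CallingConfig):
    E = 2.0 * cfg.fdr
    regions = call_at(E)
    n = len(regions)
    trajectory = [(E, n)]
    if n == 0:
        return E, regions, trajectory
    seen: dict[int, tuple[float, pd.DataFrame]] = {n: (E, regions)}
    for _ in range(cfg.max_bh_iters):
        E_next = n * 2.0 * cfg.fdr
        regions_next = call_at(E_next)
        n_next = len(regions_next)
        trajectory.append((E_next, n_next))
        if n_next == n:
            return E_next, regions_next, trajectory
        if n_next == 0:
            return E_next, regions_next, trajectory
        if n_next in seen:
            logger.warning(
                "threshold adaptation oscillates (counts %s); keeping the smaller count",
                sorted(seen),
            )
            n_min = min(n_next, min(seen))
            if n_min == n_next:
                return E_next, regions_next, trajectory
            E_min, regions_min = seen[n_min]
            return E_min, regions_min, trajectory
        seen[n_next] = (E_next, regions_next)
        n, regions = n_next, regions_next
    logger.warning("threshold adaptation hit max_bh_iters=%d", cfg.max_bh_iters)
    return E, regions, trajectory


def refine_null(
    m: CopyNumberMatrix, break_windows: Iterable[int], margin: int = 0
) -> CopyNumberMatrix:
    """Delete sample breakpoints inside called break windows.

    ``break_windows`` are genome-order boundary indices (a boundary ``b``
    separates probes ``b - 1`` and ``b``); ``margin`` widens each window by
    that many boundaries on both sides.  In every sample, each run-length
    breakpoint of the profile that falls in a window is removed by replacing
    the flanking runs with their length-weighted mean.  The result is used
    only for re-estimating the Euler curves; it is idempotent for fixed
    windows.
    """
    windows = set()
    for b in break_windows:
        for d in range(-margin, margin + 1):
            windows.add(int(b) + d)
    if not windows:
        return m
    P = m.probes.n_probes
    cs = m.probes.chrom_starts
    values = m.values.copy()
    chrom_start_set = set(int(x) for x in cs[:-1])
    for s in range(values.shape[0]):
        row = values[s]
        change = np.flatnonzero(row[1:] != row[:-1]) + 1
        keep = [
            b
            for b in change
            if int(b) not in windows or int(b) in chrom_start_set
        ]
        # piecewise means between kept breakpoints and chromosome edges
        edges = np.unique(
            np.concatenate([cs, np.asarray(keep, dtype=np.int64)])
        )
        for a, b in zip(edges[:-1], edges[1:]):
            row[a:b] = row[a:b].mean()
    return CopyNumberMatrix(m.sample_ids, values, m.probes, m.sign_mode)


def _annotate_genes(regions: pd.DataFrame, genes: GeneTable | None) -> pd.DataFrame:
    if genes is None or not len(regions):
        return regions
    regions = regions.copy()
    regions["genes"] = [
        overlapping_genes(genes, chrom, start, end)
        for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"])
    ]
    return regions


def _direction_label(sign_mode: str) -> str:
    return {"gains": "gain", "losses": "loss"}[sign_mode]


def run_direction(
    m_dir: CopyNumberMatrix,
    cfg: CallingConfig,
    null_cfg: NullConfig,
) -> tuple[pd.DataFrame, dict]:
    """Full calling pipeline for one (gain or loss) half of the data.

    Estimates Euler curves, adapts ``E`` to the FDR, then alternates null
    refinement (deleting called breaks from the permuted profiles) with
    re-estimation until the region count converges or the refinement cap is
    reached.  The aggregate that is segmented is always that of the original
    half; refinement only changes the null.
    """
    direction = _direction_label(m_dir.sign_mode)
    agg = aggregate(m_dir)
    m_null = m_dir
    report: dict = {"direction": direction, "rounds": []}
    prev_n = None
    E_final, regions = 2.0 * cfg.fdr, _empty_regions()
    for r in range(cfg.max_null_refinements + 1):
        table = estimate_euler_curves(m_null, null_cfg)

        def call_at(E: float) -> pd.DataFrame:
            return call_local_maxima(segment_genome(agg, table, E), direction)

        E_final, regions, trajectory = _adapt(call_at, cfg)
        n = len(regions)
        report["rounds"].append(
            {"refinement": r, "E_final": E_final, "n_regions": n, "trajectory": trajectory}
        )
        logger.info(
            "%s round %d: E=%.4g, %d regions (trajectory %s)",
            direction,
            r,
            E_final,
            n,
            trajectory,
        )
        if n == prev_n or n == 0 or r == cfg.max_null_refinements:
            break
        prev_n = n
        bounds = [
            int(b)
            for col in ("_left_bound", "_right_bound")
            for b in regions[col]
            if int(b) >= 0
        ]
        m_null = refine_null(m_dir, bounds, margin=cfg.refine_margin)
    report["E_final"] = E_final
    report["n_regions"] = len(regions)
    return regions, report


def run_rubic(
    m_raw: CopyNumberMatrix,
    probes: ProbeMap | None = None,
    genes: GeneTable | None = None,
    cfg: CallingConfig | None = None,
    null_cfg: NullConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """End-to-end pipeline: split, call gains and losses, annotate, filter.

    Both directions use the same null seed stream, so running the pipeline on
    negated data swaps the gain and loss calls exactly.  Returns the filtered
    gain and loss region tables and a report with threshold trajectories.
    """
    cfg = cfg or CallingConfig()
    null_cfg = null_cfg or NullConfig()
    if probes is not None and probes is not m_raw.probes:
        if not np.array_equal(probes.pos, m_raw.probes.pos):
            raise InputError("probe map does not match the matrix")
    gains, losses = split_gains_losses(m_raw)
    out = {}
    report: dict = {}
    for m_dir in (gains, losses):
        direction = _direction_label(m_dir.sign_mode)
        regions, dir_report = run_direction(m_dir, cfg, null_cfg)
        regions = _annotate_genes(regions, genes)
        n_before = len(regions)
        regions = filter_regions(
            regions,
            max_width=cfg.max_region_width,
            require_gene_overlap=cfg.require_gene_overlap and genes is not None,
        )
        dir_report["n_regions_filtered"] = len(regions)
        dir_report["n_regions_prefilter"] = n_before
        out[direction] = regions
        report[direction] = dir_report
    return out["gain"], out["loss"], report
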