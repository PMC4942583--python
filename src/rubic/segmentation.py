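"""Agglomerative segmentation of the aggregate profile.

Starting from one segment per probe, adjacent segments are merged greedily:
at every step the boundary with the largest (least significant) expected
Euler characteristic is removed, where a boundary's significance is evaluated
at its jump height with the two adjacent segment widths as the scale pair.
Merging stops when every remaining boundary is significant at the global
threshold ``E``, so the surviving jump discontinuities are exactly the
recurrent breaks.  Chromosomes are segmented independently.

Ties in significance are broken towards the leftmost boundary; the heap uses
lazy deletion with version stamps, keeping the run in ``P log P`` time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from rubic import _kernels
from rubic.break_stats import AggregateProfile, EulerCurveTable
from rubic.data_io import InputError, ProbeMap

__all__ = ["Segment", "SegmentationResult", "segment_chromosome", "segment_genome"]


@dataclass(frozen=True)
class Segment:
    """A maximal run of probes between recurrent breaks on one chromosome."""

    chrom: str
    start_probe: int  # genome-order index, inclusive
    end_probe: int  # exclusive
    amplitude: float  # mean aggregate value over the segment


@dataclass
class SegmentationResult:
    """Segments tiling every chromosome plus the significance of each break.

    ``bound_pos[i]`` is the genome-order index of the first probe right of
    internal boundary ``i``; ``bound_jump`` is the amplitude of the right
    segment minus the left and ``bound_sig`` its expected Euler
    characteristic at the adjacent segment widths.  All ``bound_sig <= E``.
    """

    probes: ProbeMap
    E: float
    seg_chrom: np.ndarray
    seg_start: np.ndarray
    seg_end: np.ndarray
    amplitude: np.ndarray
    bound_pos: np.ndarray
    bound_jump: np.ndarray
    bound_sig: np.ndarray

    @property
    def n_segments(self) -> int:
        return len(self.seg_start)

    def segments(self) -> list[Segment]:
        return [
            Segment(c, int(s), int(e), float(a))
            for c, s, e, a in zip(self.seg_chrom, self.seg_start, self.seg_end, self.amplitude)
        ]

    def chrom_segments(self, chrom: str) -> list[Segment]:
        return [s for s in self.segments() if s.chrom == chrom]

    def write_bedgraph(self, path) -> Path:
        """Segment amplitudes as bedGraph over the genomic extent of the probes."""
        path = Path(path)
        pos = self.probes.pos
        with open(path, "w") as fh:
            for c, s, e, a in zip(self.seg_chrom, self.seg_start, self.seg_end, self.amplitude):
                sl = self.probes.chrom_slice(c)
                end_bp = pos[e] if e < sl.stop else pos[e - 1] + 1
                fh.write(f"{c}\t{pos[s]}\t{end_bp}\t{a:.6g}\n")
        return path

    def write_boundaries(self, path) -> Path:
        """TSV of internal boundaries: chrom, bp position, jump, significance."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tjump\tsig\n")
            for b, j, s in zip(self.bound_pos, self.bound_jump, self.bound_sig):
                fh.write(f"{self.probes.chrom[b]}\t{self.probes.pos[b]}\t{j:.6g}\t{s:.6g}\n")
        return path


def _run_kernel(values: np.ndarray, chrom_starts: np.ndarray, table: EulerCurveTable, E: float):
    ls, thr, logc, pos_idx, fit_a, fit_b, fit_on = table._packed
    return _kernels.segment_kernel(
        np.ascontiguousarray(values, dtype=np.float64),
        np.asarray(chrom_starts, dtype=np.int64),
        float(E),
        ls,
        thr,
        logc,
        pos_idx,
        fit_a,
        fit_b,
        fit_on,
    )


def segment_genome(agg: AggregateProfile, table: EulerCurveTable, E: float) -> SegmentationResult:
    """Segment the whole aggregate profile at global threshold ``E``."""
    if np.isinf(E) and E > 0:
        # every boundary is significant at an infinite threshold; a huge
        # finite sentinel keeps the compiled kernel happy
        E = 1e300
    if E <= 0:
        raise InputError("threshold E must be positive")
    probes = agg.probes
    n_seg, s_start, s_width, s_amp, n_bnd, b_pos, b_jump, b_sig = _run_kernel(
        agg.values, probes.chrom_starts, table, E
    )
    starts = s_start[:n_seg]
    widths = s_width[:n_seg]
    return SegmentationResult(
        probes=probes,
        E=float(E),
        seg_chrom=probes.chrom[starts].copy(),
        seg_start=starts.copy(),
        seg_end=(starts + widths).copy(),
        amplitude=s_amp[:n_seg].copy(),
        bound_pos=b_pos[:n_bnd].copy(),
        bound_jump=b_jump[:n_bnd].copy(),
        bound_sig=b_sig[:n_bnd].copy(),
    )


def segment_chromosome(
    agg_values: np.ndarray, table: EulerCurveTable, E: float, chrom: str = "chr"
) -> list[Segment]:
    """Segment a single chromosome's slice of the aggregate profile."""
    values = np.asarray(agg_values, dtype=np.float64)
    if len(values) < 1:
        raise InputError("chromosome has no probes")
    if E <= 0:
        raise InputError("threshold E must be positive")
    chrom_starts = np.array([0, len(values)], dtype=np.int64)
    n_seg, s_start, s_width, s_amp, *_ = _run_kernel(values, chrom_starts, table, E)
    return [
        Segment(chrom, int(s), int(s + w), float(a))
        for s, w, a in zip(s_start[:n_seg], s_width[:n_seg], s_amp[:n_seg])
    ]
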