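"""Input/output of copy-number cohorts, marker maps, gene annotation and calls.

Conventions
-----------
* SEG files are the Broad dialect: ``sample, chrom, start, end, n_probes,
  seg_mean`` with **1-based inclusive** coordinates on disk.
* All in-memory coordinates and BED files are **0-based half-open**.
* Probes are kept in *genome order*: chromosomes concatenated in a fixed
  declared order (by default the karyotype order of the names present),
  positions ascending within each chromosome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeMap",
    "CopyNumberMatrix",
    "GeneTable",
    "InputError",
    "REGION_COLUMNS",
    "empty_region_table",
    "karyotype_sort",
    "read_markers",
    "read_seg",
    "read_genes",
    "read_regions",
    "split_gains_losses",
    "write_regions",
]


class InputError(ValueError):
    """Malformed or inconsistent input data."""


_CHROM_NUM = re.compile(r"^(chr)?(\d+)$", re.IGNORECASE)


def _chrom_key(name: str) -> tuple:
    """Karyotype sort key: chr1..chr22 numerically, then X, Y, M, then others."""
    m = _CHROM_NUM.match(name)
    if m:
        return (0, int(m.group(2)), name)
    base = name[3:] if name.lower().startswith("chr") else name
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if base.upper() in special:
        return (0, special[base.upper()], name)
    return (1, 0, name)


def karyotype_sort(names: Sequence[str]) -> list[str]:
    """Sort chromosome names in conventional karyotype order."""
    return sorted(dict.fromkeys(names), key=_chrom_key)


@dataclass(frozen=True)
class ProbeMap:
    """Genome-ordered map of measurement probes.

    ``probe_id``, ``chrom`` and ``pos`` are parallel arrays of length ``P``;
    the array index *is* the genome order.  Positions are 0-based and strictly
    increasing within each chromosome.
    """

    probe_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    chrom_order: tuple[str, ...]
    # start offset of each chromosome in genome order plus final sentinel P
    chrom_starts: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        probe_id = np.asarray(self.probe_id, dtype=object)
        chrom = np.asarray(self.chrom, dtype=object)
        pos = np.asarray(self.pos, dtype=np.int64)
        if len(pos) < 2:
            raise InputError("a probe map needs at least 2 probes")
        if len(probe_id) != len(pos) or len(chrom) != len(pos):
            raise InputError("probe_id, chrom and pos must have equal length")
        starts = [0]
        seen = []
        for name in self.chrom_order:
            mask = chrom == name
            n = int(mask.sum())
            if n == 0:
                continue
            lo = starts[-1]
            if not mask[lo : lo + n].all():
                raise InputError("probes are not grouped by declared chromosome order")
            p = pos[lo : lo + n]
            if n > 1 and not (np.diff(p) > 0).all():
                raise InputError(f"probe positions not strictly increasing on {name}")
            starts.append(lo + n)
            seen.append(name)
        if starts[-1] != len(pos):
            unknown = set(chrom) - set(self.chrom_order)
            raise InputError(f"probes on undeclared chromosomes: {sorted(unknown)}")
        object.__setattr__(self, "probe_id", probe_id)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos", pos)
        object.__setattr__(self, "chrom_order", tuple(seen))
        object.__setattr__(self, "chrom_starts", np.asarray(starts, dtype=np.int64))

    @property
    def n_probes(self) -> int:
        return len(self.pos)

    def chrom_slices(self) -> list[tuple[str, slice]]:
        cs = self.chrom_starts
        return [
            (name, slice(int(cs[i]), int(cs[i + 1])))
            for i, name in enumerate(self.chrom_order)
        ]

    def chrom_slice(self, name: str) -> slice:
        for c, sl in self.chrom_slices():
            if c == name:
                return sl
        raise KeyError(name)


@dataclass
class CopyNumberMatrix:
    """Samples x probes matrix of log2 copy-number ratios.

    Columns follow the genome order of ``probes``.  ``sign_mode`` records
    whether the values are raw log ratios or the non-negative gain/loss halves
    produced by :func:`split_gains_losses`.
    """

    sample_ids: list[str]
    values: np.ndarray
    probes: ProbeMap
    sign_mode: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InputError("values must be 2-D (samples x probes)")
        if self.values.shape != (len(self.sample_ids), self.probes.n_probes):
            raise InputError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.probes.n_probes} probes"
            )
        if np.isnan(self.values).any():
            raise InputError("copy-number matrix contains missing values")
        if self.sign_mode not in ("raw", "gains", "losses"):
            raise InputError(f"unknown sign_mode {self.sign_mode!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class GeneTable:
    """Gene annotation: unique names with 0-based half-open intervals."""

    gene_name: np.ndarray
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        name = np.asarray(self.gene_name, dtype=object)
        chrom = np.asarray(self.chrom, dtype=object)
        start = np.asarray(self.start, dtype=np.int64)
        end = np.asarray(self.end, dtype=np.int64)
        if not (len(name) == len(chrom) == len(start) == len(end)):
            raise InputError("gene table columns must have equal length")
        if (start < 0).any():
            raise InputError("negative gene start")
        if (start >= end).any():
            raise InputError("gene start must be < end")
        if len(set(name)) != len(name):
            raise InputError("gene names must be unique")
        rank = {c: i for i, c in enumerate(karyotype_sort(list(chrom)))}
        order = np.lexsort((start, np.array([rank[c] for c in chrom])))
        object.__setattr__(self, "gene_name", name[order])
        object.__setattr__(self, "chrom", chrom[order])
        object.__setattr__(self, "start", start[order])
        object.__setattr__(self, "end", end[order])

    def __len__(self) -> int:
        return len(self.start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_name": self.gene_name,
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
            }
        )


#: Column schema of a called-region table.
REGION_COLUMNS = [
    "chrom",
    "start",
    "end",
    "direction",
    "amplitude",
    "left_sig",
    "right_sig",
    "genes",
]


def empty_region_table() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        REGION_COLUMNS,
        [object, np.int64, np.int64, object, np.float64, np.float64, np.float64, object],
    )})
    return df


# ---------------------------------------------------------------------------
# readers


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, header=None)


def read_markers(path, chrom_order: Sequence[str] | None = None) -> ProbeMap:
    """Read a marker-position table (TSV: probe_id, chrom, pos).

    A header line is tolerated and detected by a non-integer third field.
    Probes are reordered into genome order, chromosomes following
    ``chrom_order`` (default: karyotype order of the names present).
    Duplicate positions on a chromosome are rejected.
    """
    df = _read_table(path)
    if df.shape[1] < 3:
        raise InputError("marker file needs 3 columns: probe_id, chrom, pos")
    try:
        int(df.iloc[0, 2])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    probe_id = df.iloc[:, 0].to_numpy(dtype=object)
    chrom = df.iloc[:, 1].to_numpy(dtype=object)
    pos = df.iloc[:, 2].astype(np.int64).to_numpy()

    if chrom_order is None:
        chrom_order = karyotype_sort(list(chrom))
    else:
        unknown = set(chrom) - set(chrom_order)
        if unknown:
            raise InputError(f"markers on chromosomes outside declared order: {sorted(unknown)}")

    key = {name: i for i, name in enumerate(chrom_order)}
    order = np.lexsort((pos, np.array([key[c] for c in chrom])))
    probe_id, chrom, pos = probe_id[order], chrom[order], pos[order]
    for name in chrom_order:
        p = pos[chrom == name]
        if len(p) > 1 and (np.diff(p) == 0).any():
            raise InputError(f"duplicate probe position on {name}")
    return ProbeMap(probe_id, chrom, pos, tuple(chrom_order))


def read_seg(path, probes: ProbeMap, impute: str = "error") -> CopyNumberMatrix:
    """Read a Broad-dialect SEG file onto a probe map.

    Each probe takes the ``seg_mean`` of the segment covering it.  Disk
    coordinates are 1-based inclusive; a probe at 0-based position ``p`` is
    covered by a disk segment ``[start, end]`` iff ``start-1 <= p < end``.

    Parameters
    ----------
    impute:
        ``"error"`` (default) rejects probes covered by no segment;
        ``"nearest"`` fills them from the nearest covered probe on the same
        chromosome.  Overlapping segments within one sample are always an
        error.
    """
    if impute not in ("error", "nearest"):
        raise InputError(f"unknown imputation policy {impute!r}")
    df = _read_table(path)
    if df.shape[1] < 6:
        raise InputError("SEG file needs 6 columns: sample, chrom, start, end, n_probes, seg_mean")
    try:
        float(df.iloc[0, 5])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    sample = df.iloc[:, 0].to_numpy(dtype=object)
    chrom = df.iloc[:, 1].to_numpy(dtype=object)
    start = df.iloc[:, 2].astype(np.int64).to_numpy() - 1  # to 0-based half-open
    end = df.iloc[:, 3].astype(np.int64).to_numpy()
    mean = df.iloc[:, 5].astype(np.float64).to_numpy()

    sample_ids = list(dict.fromkeys(sample))
    P = probes.n_probes
    values = np.full((len(sample_ids), P), np.nan)
    srow = {s: i for i, s in enumerate(sample_ids)}

    for name, sl in probes.chrom_slices():
        pos = probes.pos[sl]
        cmask = chrom == name
        for s in sample_ids:
            mask = cmask & (sample == s)
            if not mask.any():
                continue
            st, en, mu = start[mask], end[mask], mean[mask]
            o = np.argsort(st)
            st, en, mu = st[o], en[o], mu[o]
            if (st[1:] < en[:-1]).any():
                raise InputError(f"overlapping segments for sample {s} on {name}")
            idx = np.searchsorted(st, pos, side="right") - 1
            covered = (idx >= 0) & (pos < en[np.clip(idx, 0, None)])
            values[srow[s], sl][covered] = mu[idx[covered]]

    missing = np.isnan(values)
    if missing.any():
        if impute == "error":
            s_i, p_i = np.argwhere(missing)[0]
            raise InputError(
                f"probe {probes.probe_id[p_i]} ({probes.chrom[p_i]}:{probes.pos[p_i]}) "
                f"not covered by any segment of sample {sample_ids[s_i]}"
            )
        for name, sl in probes.chrom_slices():
            block = values[:, sl]
            n = block.shape[1]
            for i in range(block.shape[0]):
                row = block[i]
                bad = np.isnan(row)
                if not bad.any():
                    continue
                if bad.all():
                    raise InputError(
                        f"no covered probe on {name} for sample {sample_ids[i]}: cannot impute"
                    )
                good = np.flatnonzero(~bad)
                nearest = good[
                    np.argmin(np.abs(np.arange(n)[:, None] - good[None, :]), axis=1)
                ]
                row[bad] = row[nearest[bad]]
    return CopyNumberMatrix(sample_ids, values, probes, sign_mode="raw")


def read_genes(path) -> GeneTable:
    """Read gene annotation from BED (>=3 columns, 0-based half-open).

    The 4th column provides gene names; missing names are auto-generated.
    Lines with ``start >= end`` or a negative start are rejected.
    """
    df = _read_table(path)
    if df.shape[1] < 3:
        raise InputError("BED needs at least 3 columns")
    chrom = df.iloc[:, 0].to_numpy(dtype=object)
    start = df.iloc[:, 1].astype(np.int64).to_numpy()
    end = df.iloc[:, 2].astype(np.int64).to_numpy()
    if df.shape[1] >= 4:
        name = df.iloc[:, 3].to_numpy(dtype=object)
    else:
        name = np.array([f"gene_{i + 1}" for i in range(len(chrom))], dtype=object)
    return GeneTable(name, chrom, start, end)


# ---------------------------------------------------------------------------
# transforms


def split_gains_losses(m: CopyNumberMatrix) -> tuple[CopyNumberMatrix, CopyNumberMatrix]:
    """Split raw log ratios into non-negative gain and loss matrices.

    Gains carry ``max(x, 0)`` and losses ``max(-x, 0)``, so the loss half is
    analysed by exactly the same downstream machinery as the gain half.
    """
    if m.sign_mode != "raw":
        raise InputError("split_gains_losses expects sign_mode='raw'")
    gains = replace(m, values=np.maximum(m.values, 0.0), sign_mode="gains")
    losses = replace(m, values=np.maximum(-m.values, 0.0), sign_mode="losses")
    return gains, losses


# ---------------------------------------------------------------------------
# writers

_FLOAT_FMT = "%.6g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def write_regions(regions: pd.DataFrame, out_prefix) -> tuple[Path, Path]:
    """Write called regions to ``<prefix>.tsv`` (all fields) and ``<prefix>.bed``.

    The BED name column is the direction and the score column is
    ``-log10(min(left_sig, right_sig))`` clipped to [0, 1000].  Rows are
    ordered by genome position (karyotype chromosome order).
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = out_prefix.with_suffix(".tsv")
    bed = out_prefix.with_suffix(".bed")

    df = regions.copy()
    if len(df):
        rank = {c: i for i, c in enumerate(karyotype_sort(list(df["chrom"])))}
        key = np.array([rank[c] for c in df["chrom"]])
        df = df.iloc[np.lexsort((df["start"].to_numpy(), key))]
    with open(tsv, "w") as fh:
        fh.write("\t".join(REGION_COLUMNS) + "\n")
        for _, r in df.iterrows():
            genes = ",".join(r["genes"]) if isinstance(r["genes"], (list, tuple)) else str(r["genes"])
            fh.write(
                "\t".join(
                    [
                        str(r["chrom"]),
                        str(int(r["start"])),
                        str(int(r["end"])),
                        str(r["direction"]),
                        _fmt(r["amplitude"]),
                        _fmt(r["left_sig"]),
                        _fmt(r["right_sig"]),
                        genes,
                    ]
                )
                + "\n"
            )
    with open(bed, "w") as fh:
        for _, r in df.iterrows():
            sig = max(min(r["left_sig"], r["right_sig"]), 1e-300)
            score = min(max(-np.log10(sig), 0.0), 1000.0)
            fh.write(
                f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t"
                f"{r['direction']}\t{_fmt(score)}\n"
            )
    return tsv, bed


def read_regions(path) -> pd.DataFrame:
    """Read back a region TSV written by :func:`write_regions`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "direction": str, "genes": str})
    df["genes"] = [
        [] if (not isinstance(g, str) or g == "") else g.split(",") for g in df["genes"]
    ]
    for col in ("start", "end"):
        df[col] = df[col].astype(np.int64)
    return df[REGION_COLUMNS]
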