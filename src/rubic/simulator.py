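"""Clonal copy-number-evolution simulator with known driver genes.

Each tumour sample is grown from a diploid dominant clone by repeated
randomization/selection rounds: every round derives ``descendants`` clones by
adding ``aberrations`` random copy-number events each, scores every clone's
proliferation from the driver genes it has hit, and promotes the highest
scorer to dominant clone.  A driver gene contributes its (normal-drawn)
proliferation coefficient times the gene's average copy-number fold change
``2^(log2 ratio)`` relative to diploid, length-weighted over the gene body;
positive coefficients model oncogenes, negative ones tumour suppressors.
With ``descendants=1`` selection is disabled and the process accumulates
neutral passenger events only.

Aberration widths and magnitudes follow a parametric stand-in for empirical
tumour distributions: a 90/10 mixture of log-uniform focal events (10 kb to
10 Mb) and whole-arm events, exponential |log2 ratio| (mean 0.35) with a fair
gain/loss coin.  All parameters are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from rubic.data_io import CopyNumberMatrix, GeneTable, InputError, ProbeMap

__all__ = [
    "GenomeModel",
    "DriverSet",
    "AberrationModel",
    "CloneProfile",
    "apply_aberration",
    "proliferation_score",
    "simulate_sample",
    "simulate_cohort",
    "random_gene_annotation",
    "write_cohort",
]

# hg38 chromosome lengths (chr1..chr22, chrX), rounded to 0.1 Mb
_HUMAN_LENGTHS_MB = [
    248.9, 242.2, 198.3, 190.2, 181.5, 170.8, 159.3, 145.1, 138.4, 133.8,
    135.1, 133.3, 114.4, 107.0, 102.0, 90.3, 83.3, 80.4, 58.6, 64.4,
    46.7, 50.8, 156.0,
]


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names and lengths plus the probe spacing used for rendering."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    probe_spacing: int = 3000

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths) or not self.names:
            raise InputError("genome needs parallel, non-empty names and lengths")
        if any(l <= 0 for l in self.lengths):
            raise InputError("chromosome lengths must be positive")
        if self.probe_spacing <= 0:
            raise InputError("probe spacing must be positive")

    @classmethod
    def scaled_default(cls, probe_spacing: int = 3000) -> "GenomeModel":
        """Desk-scale genome: three 100 Mb chromosomes."""
        return cls(("chr1", "chr2", "chr3"), (100_000_000,) * 3, probe_spacing)

    @classmethod
    def human(cls, probe_spacing: int = 30_000) -> "GenomeModel":
        """Human-sized genome (hg38 chr1-22, X)."""
        names = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)
        lengths = tuple(int(mb * 1e6) for mb in _HUMAN_LENGTHS_MB)
        return cls(names, lengths, probe_spacing)

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    @property
    def offsets(self) -> np.ndarray:
        """Concatenated-genome start offset of each chromosome (+ sentinel)."""
        return np.concatenate(([0], np.cumsum(np.asarray(self.lengths, dtype=np.int64))))

    def probe_map(self) -> ProbeMap:
        probe_id, chrom, pos = [], [], []
        for name, length in zip(self.names, self.lengths):
            p = np.arange(0, length, self.probe_spacing, dtype=np.int64)
            pos.append(p)
            chrom.extend([name] * len(p))
            probe_id.extend(f"{name}_p{i}" for i in range(len(p)))
        return ProbeMap(
            np.asarray(probe_id, dtype=object),
            np.asarray(chrom, dtype=object),
            np.concatenate(pos),
            tuple(self.names),
        )

    def probe_concat_positions(self) -> np.ndarray:
        off = self.offsets
        parts = [
            off[i] + np.arange(0, length, self.probe_spacing, dtype=np.int64)
            for i, length in enumerate(self.lengths)
        ]
        return np.concatenate(parts)


def _random_intervals(
    genome: GenomeModel, n: int, rng, min_len: int, max_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Intervals with log-uniform lengths placed uniformly, one chromosome each."""
    lengths = np.asarray(genome.lengths, dtype=np.float64)
    chrom_idx = rng.choice(len(lengths), size=n, p=lengths / lengths.sum())
    size = np.exp(rng.uniform(np.log(min_len), np.log(max_len), size=n)).astype(np.int64)
    starts = np.empty(n, dtype=np.int64)
    off = genome.offsets
    for i, (c, w) in enumerate(zip(chrom_idx, size)):
        L = genome.lengths[c]
        w = min(int(w), L - 1)
        size[i] = w
        starts[i] = off[c] + rng.integers(0, L - w)
    return starts, starts + size


def random_gene_annotation(
    genome: GenomeModel,
    n_genes: int,
    rng=None,
    min_len: int = 5_000,
    max_len: int = 500_000,
    prefix: str = "gene",
) -> GeneTable:
    """Synthetic gene annotation: uniformly placed, log-uniform lengths 5-500 kb."""
    rng = np.random.default_rng(rng)
    starts, ends = _random_intervals(genome, n_genes, rng, min_len, max_len)
    off = genome.offsets
    cidx = np.searchsorted(off, starts, side="right") - 1
    return GeneTable(
        np.asarray([f"{prefix}_{i + 1}" for i in range(n_genes)], dtype=object),
        np.asarray([genome.names[c] for c in cidx], dtype=object),
        starts - off[cidx],
        ends - off[cidx],
    )


@dataclass
class DriverSet:
    """Driver genes with proliferation coefficients (one per gene).

    Positive coefficients are oncogenes, negative ones tumour suppressors.
    """

    genes: GeneTable
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.shape != (len(self.genes),):
            raise InputError("need one coefficient per driver gene")

    @classmethod
    def random(
        cls,
        genome: GenomeModel,
        n_drivers: int,
        rng=None,
        coeff_sd: float = 1.0,
        min_len: int = 5_000,
        max_len: int = 500_000,
    ) -> "DriverSet":
        """Drivers on random intervals, coefficients ~ Normal(0, coeff_sd)."""
        rng = np.random.default_rng(rng)
        genes = random_gene_annotation(genome, n_drivers, rng, min_len, max_len, prefix="driver")
        return cls(genes, rng.normal(0.0, coeff_sd, size=n_drivers))

    @classmethod
    def from_genes(
        cls, genes: GeneTable, n_drivers: int, rng=None, coeff_sd: float = 1.0
    ) -> "DriverSet":
        """Sample drivers uniformly from an existing gene annotation."""
        rng = np.random.default_rng(rng)
        if n_drivers > len(genes):
            raise InputError("more drivers requested than genes available")
        idx = np.sort(rng.choice(len(genes), size=n_drivers, replace=False))
        sub = GeneTable(
            genes.gene_name[idx], genes.chrom[idx], genes.start[idx], genes.end[idx]
        )
        return cls(sub, rng.normal(0.0, coeff_sd, size=n_drivers))

    def concat_intervals(self, genome: GenomeModel) -> tuple[np.ndarray, np.ndarray]:
        off_of = {n: o for n, o in zip(genome.names, genome.offsets[:-1])}
        gs = np.array(
            [off_of[c] + s for c, s in zip(self.genes.chrom, self.genes.start)],
            dtype=np.int64,
        )
        ge = np.array(
            [off_of[c] + e for c, e in zip(self.genes.chrom, self.genes.end)],
            dtype=np.int64,
        )
        return gs, ge


@dataclass
class AberrationModel:
    """Width/magnitude model of random copy-number events.

    Focal widths are log-uniform on [focal_min, focal_max]; with probability
    ``1 - p_focal`` an event is arm-level instead: anchored at a telomere and
    reaching to a breakpoint drawn uniformly from the middle ``arm_band`` of
    the chromosome.  The dispersed arm breakpoint mimics the variability of
    real (peri)centromeric boundaries; an exact half-chromosome event in every
    sample would itself be a recurrent break, which a selectively neutral
    passenger process must not contain.  |log2 ratio| is exponential with
    mean ``mean_log2`` and the sign is a ``p_gain`` coin.

    The defaults are calibrated so that a sample accumulating the standard
    200 events on the desk-scale 300 Mb genome alters a realistic fraction of
    its genome (~0.4-0.5, as in breast-cancer SNP6 cohorts) rather than
    covering it several times over; on a genome with human-sized chromosomes
    this means mostly focal events with an occasional arm-level one.
    """

    p_focal: float = 0.99
    focal_min: int = 10_000
    focal_max: int = 3_000_000
    mean_log2: float = 0.35
    p_gain: float = 0.5
    arm_band: tuple[float, float] = (0.3, 0.7)

    def sample(self, genome: GenomeModel, n: int, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Draw ``n`` events: concatenated-coordinate intervals and log2 deltas."""
        if n == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z.copy(), np.empty(0)
        lengths = np.asarray(genome.lengths, dtype=np.float64)
        off = genome.offsets
        chrom_idx = rng.choice(len(lengths), size=n, p=lengths / lengths.sum())
        focal = rng.random(n) < self.p_focal
        starts = np.empty(n, dtype=np.int64)
        ends = np.empty(n, dtype=np.int64)
        widths = np.exp(
            rng.uniform(np.log(self.focal_min), np.log(self.focal_max), size=n)
        ).astype(np.int64)
        arms = rng.random(n) < 0.5  # p-arm (first half) vs q-arm
        for i in range(n):
            c = chrom_idx[i]
            L = int(genome.lengths[c])
            if focal[i]:
                w = min(int(widths[i]), L - 1)
                s = rng.integers(0, L - w)
                starts[i] = off[c] + s
                ends[i] = off[c] + s + w
            else:
                b = int(rng.integers(int(self.arm_band[0] * L), int(self.arm_band[1] * L)))
                if arms[i]:
                    starts[i] = off[c]
                    ends[i] = off[c] + b
                else:
                    starts[i] = off[c] + b
                    ends[i] = off[c] + L
        mag = rng.exponential(self.mean_log2, size=n)
        sign = np.where(rng.random(n) < self.p_gain, 1.0, -1.0)
        return starts, ends, mag * sign


@dataclass
class CloneProfile:
    """Accumulated piecewise-constant log2 profile of one clone.

    Events are additive intervals on the concatenated genome; the profile's
    value at a base is the sum of the deltas of the events covering it.
    """

    genome: GenomeModel
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ends: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    deltas: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.deltas = np.asarray(self.deltas, dtype=np.float64)
        L = self.genome.total_length
        if len(self.starts) and (
            (self.starts < 0).any()
            or (self.ends > L).any()
            or (self.starts >= self.ends).any()
        ):
            raise InputError("aberration interval outside the genome")

    @property
    def n_events(self) -> int:
        return len(self.starts)

    def piecewise(self) -> tuple[np.ndarray, np.ndarray]:
        """Breakpoints (including 0 and L) and the value on each interval."""
        L = self.genome.total_length
        edges = np.unique(np.concatenate(([0, L], self.starts, self.ends)))
        vals = np.zeros(len(edges) - 1)
        for s, e, d in zip(self.starts, self.ends, self.deltas):
            i0 = np.searchsorted(edges, s)
            i1 = np.searchsorted(edges, e)
            vals[i0:i1] += d
        return edges, vals

    def to_probe_values(self, probe_concat_positions: np.ndarray) -> np.ndarray:
        """Render the profile onto probe positions (concatenated coordinates)."""
        row = np.zeros(len(probe_concat_positions))
        for s, e, d in zip(self.starts, self.ends, self.deltas):
            i0 = np.searchsorted(probe_concat_positions, s, side="left")
            i1 = np.searchsorted(probe_concat_positions, e, side="left")
            row[i0:i1] += d
        return row


def apply_aberration(p: CloneProfile, interval: tuple[int, int], delta_log2: float) -> CloneProfile:
    """Return a new clone with ``delta_log2`` added on ``interval`` (bp, concat)."""
    s, e = int(interval[0]), int(interval[1])
    return CloneProfile(
        p.genome,
        np.append(p.starts, s),
        np.append(p.ends, e),
        np.append(p.deltas, float(delta_log2)),
    )


def _gene_fold(starts, ends, deltas, gs: int, ge: int) -> float:
    """Length-weighted mean of 2^log2 over a gene body [gs, ge)."""
    over = (starts < ge) & (ends > gs)
    if not over.any():
        return 1.0
    s = np.clip(starts[over], gs, ge)
    e = np.clip(ends[over], gs, ge)
    d = deltas[over]
    edges = np.unique(np.concatenate(([gs, ge], s, e)))
    acc = np.zeros(len(edges) - 1)
    for si, ei, di in zip(s, e, d):
        i0 = np.searchsorted(edges, si)
        i1 = np.searchsorted(edges, ei)
        acc[i0:i1] += di
    seg_len = np.diff(edges)
    return float((seg_len * np.exp2(acc)).sum() / (ge - gs))


def proliferation_score(p: CloneProfile, d: DriverSet) -> float:
    """Sum over drivers of coefficient x average copy-number fold change."""
    gs, ge = d.concat_intervals(p.genome)
    folds = np.array(
        [_gene_fold(p.starts, p.ends, p.deltas, a, b) for a, b in zip(gs, ge)]
    )
    return float((d.coefficients * folds).sum())


def simulate_sample(
    genome: GenomeModel,
    drivers: DriverSet | None,
    ab_model: AberrationModel | None = None,
    rounds: int = 20,
    descendants: int = 100,
    aberrations: int = 10,
    seed=None,
    return_log: bool = False,
):
    """Evolve one sample's dominant clone through randomization/selection rounds.

    Each round draws ``descendants`` candidate clones (parent plus
    ``aberrations`` fresh random events each) and promotes the candidate with
    the highest proliferation score (ties towards the first drawn).  With
    ``descendants=1`` (or no drivers) there is no selection and the sample
    accumulates passengers neutrally.  ``return_log`` additionally returns
    the per-round candidate scores and the chosen index.
    """
    if rounds < 1 or descendants < 1 or aberrations < 0:
        raise InputError("rounds and descendants must be >= 1, aberrations >= 0")
    ab_model = ab_model or AberrationModel()
    rng = np.random.default_rng(seed)
    n_genes = len(drivers.genes) if drivers is not None else 0
    select = descendants > 1 and n_genes > 0

    ev_s: list[np.ndarray] = []
    ev_e: list[np.ndarray] = []
    ev_d: list[np.ndarray] = []
    if select:
        gs, ge = drivers.concat_intervals(genome)
        coeff = drivers.coefficients
        folds = np.ones(n_genes)
    log = []

    for _ in range(rounds):
        cs, ce, cd = ab_model.sample(genome, descendants * aberrations, rng)
        cs = cs.reshape(descendants, aberrations)
        ce = ce.reshape(descendants, aberrations)
        cd = cd.reshape(descendants, aberrations)
        if not select:
            best = 0
            scores = None
        else:
            p_s = np.concatenate(ev_s) if ev_s else np.empty(0, dtype=np.int64)
            p_e = np.concatenate(ev_e) if ev_e else np.empty(0, dtype=np.int64)
            p_d = np.concatenate(ev_d) if ev_d else np.empty(0)
            base = float((coeff * folds).sum())
            scores = np.empty(descendants)
            cand_folds: list[dict[int, float]] = []
            for k in range(descendants):
                touched: set[int] = set()
                for s, e in zip(cs[k], ce[k]):
                    touched.update(np.flatnonzero((gs < e) & (ge > s)).tolist())
                new = {}
                delta = 0.0
                if touched:
                    all_s = np.concatenate([p_s, cs[k]])
                    all_e = np.concatenate([p_e, ce[k]])
                    all_d = np.concatenate([p_d, cd[k]])
                    for g in touched:
                        f = _gene_fold(all_s, all_e, all_d, int(gs[g]), int(ge[g]))
                        new[g] = f
                        delta += coeff[g] * (f - folds[g])
                cand_folds.append(new)
                scores[k] = base + delta
            best = int(np.argmax(scores))
            for g, f in cand_folds[best].items():
                folds[g] = f
        ev_s.append(cs[best])
        ev_e.append(ce[best])
        ev_d.append(cd[best])
        if return_log:
            log.append(
                {
                    "scores": scores.copy() if scores is not None else None,
                    "chosen": best,
                }
            )

    profile = CloneProfile(
        genome,
        np.concatenate(ev_s) if ev_s else np.empty(0, dtype=np.int64),
        np.concatenate(ev_e) if ev_e else np.empty(0, dtype=np.int64),
        np.concatenate(ev_d) if ev_d else np.empty(0),
    )
    if return_log:
        return profile, log
    return profile


def simulate_cohort(
    n_samples: int,
    genome: GenomeModel | None = None,
    drivers: DriverSet | None = None,
    n_drivers: int = 100,
    ab_model: AberrationModel | None = None,
    rounds: int = 20,
    descendants: int = 100,
    aberrations: int = 10,
    coeff_sd: float = 1.0,
    seed: int = 0,
) -> tuple[CopyNumberMatrix, ProbeMap, DriverSet]:
    """Simulate an independent cohort of samples on the probe grid.

    Drivers default to ``n_drivers`` random genes with Normal(0, coeff_sd)
    coefficients drawn from the seed; pass ``descendants=1`` for a
    passenger-only (selection-free) cohort.  Deterministic per seed.
    """
    if n_samples < 0:
        raise InputError("n_samples must be >= 0")
    genome = genome or GenomeModel.scaled_default()
    ab_model = ab_model or AberrationModel()
    if drivers is None:
        drv_rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        drivers = DriverSet.random(genome, n_drivers, rng=drv_rng, coeff_sd=coeff_sd)
    probes = genome.probe_map()
    pcat = genome.probe_concat_positions()
    values = np.zeros((n_samples, len(pcat)))
    for s in range(n_samples):
        profile = simulate_sample(
            genome,
            drivers,
            ab_model,
            rounds=rounds,
            descendants=descendants,
            aberrations=aberrations,
            seed=np.random.SeedSequence([seed, 1 + s]),
        )
        values[s] = profile.to_probe_values(pcat)
    ids = [f"sample_{s + 1:04d}" for s in range(n_samples)]
    return CopyNumberMatrix(ids, values, probes, sign_mode="raw"), probes, drivers


def write_cohort(
    m: CopyNumberMatrix, drivers: DriverSet, out_dir, float_fmt: str = "%.6g"
) -> dict[str, Path]:
    """Write a simulated cohort as SEG + markers TSV + drivers BED + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probes = m.probes
    paths = {
        "seg": out / "cohort.seg",
        "markers": out / "markers.tsv",
        "drivers": out / "drivers.bed",
        "truth": out / "truth.json",
    }
    with open(paths["markers"], "w") as fh:
        fh.write("probe_id\tchrom\tpos\n")
        for pid, c, p in zip(probes.probe_id, probes.chrom, probes.pos):
            fh.write(f"{pid}\t{c}\t{p}\n")
    with open(paths["seg"], "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tn_probes\tseg_mean\n")
        for i, sid in enumerate(m.sample_ids):
            row = m.values[i]
            for chrom, sl in probes.chrom_slices():
                v = row[sl]
                pos = probes.pos[sl]
                cuts = np.concatenate(
                    ([0], np.flatnonzero(v[1:] != v[:-1]) + 1, [len(v)])
                )
                for a, b in zip(cuts[:-1], cuts[1:]):
                    fh.write(
                        f"{sid}\t{chrom}\t{pos[a] + 1}\t{pos[b - 1] + 1}\t{b - a}\t"
                        + (float_fmt % v[a])
                        + "\n"
                    )
    with open(paths["drivers"], "w") as fh:
        g = drivers.genes
        for name, c, s, e in zip(g.gene_name, g.chrom, g.start, g.end):
            fh.write(f"{c}\t{s}\t{e}\t{name}\n")
    truth = {
        "drivers": [
            {
                "gene": str(n),
                "chrom": str(c),
                "start": int(s),
                "end": int(e),
                "coefficient": float(k),
            }
            for n, c, s, e, k in zip(
                drivers.genes.gene_name,
                drivers.genes.chrom,
                drivers.genes.start,
                drivers.genes.end,
                drivers.coefficients,
            )
        ]
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
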