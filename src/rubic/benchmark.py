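"""End-to-end benchmark: simulate -> call -> evaluate at several sample sizes.

For each (sample size, replicate) pair a fresh gene annotation, driver set
and cohort are drawn, the full calling pipeline is run at the configured FDR,
the standard region filters are applied, and driver-recovery metrics are
computed over both directions combined.  Defaults are desk-scale: a 300 Mb
three-chromosome genome with 3 kb probe spacing, 2,000 genes (human-like
density) of which 20 are drivers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from rubic.break_stats import NullConfig, aggregate, estimate_euler_curves
from rubic.calling import CallingConfig, call_local_maxima, run_rubic
from rubic.data_io import split_gains_losses
from rubic.evaluation import compute_metrics
from rubic.segmentation import segment_genome
from rubic.simulator import (
    AberrationModel,
    DriverSet,
    GenomeModel,
    random_gene_annotation,
    simulate_cohort,
)

__all__ = ["BenchmarkConfig", "benchmark", "passenger_false_positive_counts"]


@dataclass
class BenchmarkConfig:
    """Study conditions of the scaled benchmark."""

    genome: GenomeModel = field(default_factory=GenomeModel.scaled_default)
    n_genes: int = 2000
    n_drivers: int = 20
    coeff_sd: float = 1.0
    rounds: int = 20
    descendants: int = 100
    aberrations: int = 10
    fdr: float = 0.25
    n_perm: int = 50
    calling: CallingConfig | None = None
    ab_model: AberrationModel | None = None


def benchmark(
    sample_sizes: Sequence[int] = (20, 50, 100),
    replicates: int = 3,
    cfg: BenchmarkConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the simulate/call/evaluate loop; one row per cohort.

    Deterministic given ``seed``: every cohort derives its own seed from
    (seed, sample size, replicate), recorded in the output.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    cfg = cfg or BenchmarkConfig()
    calling_cfg = cfg.calling or CallingConfig(fdr=cfg.fdr)
    rows = []
    for n in sample_sizes:
        for rep in range(replicates):
            cohort_seed = int(
                np.random.SeedSequence([seed, int(n), rep]).generate_state(1)[0] % (2**31)
            )
            rng = np.random.default_rng(np.random.SeedSequence([cohort_seed, 17]))
            genes = random_gene_annotation(cfg.genome, cfg.n_genes, rng)
            drivers = DriverSet.from_genes(genes, cfg.n_drivers, rng, cfg.coeff_sd)
            m, probes, _ = simulate_cohort(
                n,
                genome=cfg.genome,
                drivers=drivers,
                ab_model=cfg.ab_model,
                rounds=cfg.rounds,
                descendants=cfg.descendants,
                aberrations=cfg.aberrations,
                seed=cohort_seed,
            )
            null_cfg = NullConfig(n_perm=cfg.n_perm, seed=cohort_seed)
            gains, losses, report = run_rubic(
                m, genes=genes, cfg=calling_cfg, null_cfg=null_cfg
            )
            regions = pd.concat([gains, losses], ignore_index=True)
            metrics = compute_metrics(regions, drivers.genes, genes)
            rows.append(
                {
                    "n_samples": int(n),
                    "replicate": rep,
                    "seed": cohort_seed,
                    "n_gain_regions": len(gains),
                    "n_loss_regions": len(losses),
                    "E_gain": report["gain"]["E_final"],
                    "E_loss": report["loss"]["E_final"],
                    **{k: v for k, v in metrics.to_dict().items()},
                }
            )
    return pd.DataFrame(rows)


def passenger_false_positive_counts(
    n_replicates: int = 500,
    n_samples: int = 20,
    genome: GenomeModel | None = None,
    n_perm: int = 50,
    E: float = 0.5,
    seed: int = 0,
    ab_model: AberrationModel | None = None,
    n_tables: int = 10,
) -> np.ndarray:
    """Called-region counts on passenger-only cohorts at a fixed threshold.

    Calibration experiment for the region-level error bound: on cohorts with
    selection disabled, segmentation plus local-maximum calling of the gain
    half at a fixed ``E`` is compared against the ``E/2`` expected
    false-positive bound.  Estimating a fresh ``n_perm``-permutation
    Euler-curve table for each cohort would dominate the runtime, so
    ``n_tables`` tables are estimated from independent cohorts of the same
    passenger process and rotated across the replicates; averaging over
    several independent tables keeps the Monte-Carlo noise of any single
    table (to which the call count is quite sensitive) from biasing the
    mean.  Returns the per-replicate called-region count.
    """
    genome = genome or GenomeModel.scaled_default()

    def passenger_cohort(s: int):
        m, _, _ = simulate_cohort(
            n_samples,
            genome=genome,
            n_drivers=0,
            ab_model=ab_model,
            descendants=1,
            seed=s,
        )
        return m

    tables = []
    for k in range(max(1, n_tables)):
        table_seed = int(
            np.random.SeedSequence([seed, 999_983, k]).generate_state(1)[0] % (2**31)
        )
        gains0, _ = split_gains_losses(passenger_cohort(table_seed))
        tables.append(
            estimate_euler_curves(gains0, NullConfig(n_perm=n_perm, seed=table_seed))
        )

    counts = np.empty(n_replicates, dtype=np.int64)
    for rep in range(n_replicates):
        rep_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31))
        gains, _ = split_gains_losses(passenger_cohort(rep_seed))
        seg = segment_genome(aggregate(gains), tables[rep % len(tables)], E)
        counts[rep] = len(call_local_maxima(seg, "gain"))
    return counts
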