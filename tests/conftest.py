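import numpy as np
import pytest

import rubic
from rubic.data_io import CopyNumberMatrix, ProbeMap


@pytest.fixture
def probes2() -> ProbeMap:
    """Two chromosomes: 6 + 4 probes at 100 bp spacing."""
    n1, n2 = 6, 4
    return ProbeMap(
        np.array([f"p{i}" for i in range(n1 + n2)], dtype=object),
        np.array(["chr1"] * n1 + ["chr2"] * n2, dtype=object),
        np.concatenate([np.arange(n1) * 100, np.arange(n2) * 100]),
        ("chr1", "chr2"),
    )


def make_probe_map(chrom_sizes: dict[str, int], spacing: int = 100) -> ProbeMap:
    names = list(chrom_sizes)
    chrom, pos, pid = [], [], []
    for name in names:
        n = chrom_sizes[name]
        chrom.extend([name] * n)
        pos.append(np.arange(n) * spacing)
        pid.extend(f"{name}_p{i}" for i in range(n))
    return ProbeMap(
        np.array(pid, dtype=object),
        np.array(chrom, dtype=object),
        np.concatenate(pos),
        tuple(names),
    )


@pytest.fixture(scope="session")
def toy_cohort() -> CopyNumberMatrix:
    """Small raw cohort from the simulator (5 samples, 2 chromosomes, P=50)."""
    genome = rubic.GenomeModel(("chr1", "chr2"), (3_000_000, 2_000_000), probe_spacing=100_000)
    m, _, _ = rubic.simulate_cohort(5, genome=genome, n_drivers=3, seed=1)
    return m


@pytest.fixture(scope="session")
def toy_table(toy_cohort) -> rubic.EulerCurveTable:
    """Euler-curve table estimated from the toy cohort's gain half."""
    gains, _ = rubic.split_gains_losses(toy_cohort)
    return rubic.estimate_euler_curves(gains, rubic.NullConfig(n_perm=10, seed=2))
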