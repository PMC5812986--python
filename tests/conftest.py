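import numpy as np
import pytest

from permdiff import (
    MethylationTable,
    SimulationConfig,
    simulate_annotation,
    simulate_methylome,
)


def make_table(m, t, groups=None, pos=None, chrom=None):
    """Small MethylationTable from (n_samples, n_sites) count arrays."""
    m = np.asarray(m)
    t = np.asarray(t)
    n_samples, n_sites = m.shape
    half = n_samples // 2
    samples = [f"s{i + 1}" for i in range(n_samples)]
    if groups is None:
        groups = {s: ("control" if i < half else "low1C")
                  for i, s in enumerate(samples)}
    if pos is None:
        pos = np.arange(n_sites) * 100
    if chrom is None:
        chrom = np.array(["chr1"] * n_sites)
    return MethylationTable(chrom=chrom, pos=np.asarray(pos), m=m, t=t,
                            samples=samples, groups=groups)


def null_config(seed, **kwargs):
    """Small global-null methylome: one chromosome, ~5,000 CpGs, 6 vs 6."""
    defaults = dict(seed=seed, n_chroms=1, chrom_length=700_000,
                    n_transcripts=40, n_islands=25, n_true_dml=0, n_true_deg=0)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_sim():
    """One default-config simulation shared across read-only tests."""
    cfg = SimulationConfig(seed=11)
    model = simulate_annotation(cfg)
    table, truth = simulate_methylome(model, cfg)
    return cfg, model, table, truth


@pytest.fixture(scope="session")
def small_null_sim():
    cfg = null_config(seed=7)
    model = simulate_annotation(cfg)
    table, truth = simulate_methylome(model, cfg)
    return cfg, model, table, truth
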