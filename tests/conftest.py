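"""Shared fixtures and independent oracles for the test suite."""

from math import comb
from fractions import Fraction

import numpy as np
import pytest

from wgbstiles.simulate import SimulationConfig, simulate_genome


def exact_fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exact integer-arithmetic enumeration.

    Sums hypergeometric point numerators not exceeding the observed one;
    the comparison is exact (integers), so no tolerance is involved.
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return Fraction(1)
    k_lo, k_hi = max(0, r1 + c1 - n), min(r1, c1)
    nums = {k: comb(c1, k) * comb(n - c1, r1 - k) for k in range(k_lo, k_hi + 1)}
    obs = nums[a]
    return Fraction(sum(v for v in nums.values() if v <= obs), comb(n, r1))


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg by the O(m^2) definition: q_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    vals = sorted_p * m / np.arange(1, m + 1)
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(float(vals[i:].min()), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def brute_force_density(positions: np.ndarray, window: int) -> np.ndarray:
    """All-pairs neighbourhood counts: the O(n^2) density oracle."""
    positions = np.asarray(positions)
    return (np.abs(positions[:, None] - positions[None, :]) <= window).sum(axis=1)


@pytest.fixture(scope="session")
def tiny_config():
    """A small but fully structured simulation: all effects enabled."""
    return SimulationConfig(
        chrom_sizes={"chr1": 120_000, "chr2": 80_000, "chrX": 50_000,
                     "chrM": 16_000},
        replicates=2,
        n_dmrs=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_genome(tiny_config):
    return simulate_genome(tiny_config)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config, tmp_path_factory):
    """A complete on-disk synthetic dataset shared across tests."""
    from wgbstiles.simulate import simulate_dataset

    outdir = tmp_path_factory.mktemp("dataset")
    manifest = simulate_dataset(tiny_config, outdir)
    return outdir, manifest, tiny_config
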