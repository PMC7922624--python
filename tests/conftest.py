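import numpy as np
import pytest

import svgblup as sg


@pytest.fixture(scope="session")
def small_dataset() -> sg.SyntheticDataset:
    """A small but structurally complete population shared across tests."""
    cfg = sg.SimConfig(
        n_individuals=150,
        n_snp=600,
        n_sv=40,
        n_chrom=2,
        seed=7,
        n_sire_son_pairs=10,
        n_duplicates=6,
        n_traits=2,
    )
    return sg.simulate_dataset(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def hwe_genotypes(rng, n, m, p_lo=0.1, p_hi=0.9) -> np.ndarray:
    """Independent Hardy-Weinberg markers (no LD), as int8 codes."""
    p = rng.uniform(p_lo, p_hi, m)
    return rng.binomial(2, p, (n, m)).astype(np.int8)


def grm_phenotype(rng, grms, props, n):
    """Draw y = sum_k u_k + e with u_k ~ N(0, prop_k * G_k) exactly at the
    population level (Cholesky of each GRM plus a small jitter)."""
    y = np.zeros(n)
    for g, prop in zip(grms, props[:-1]):
        a = g.matrix if hasattr(g, "matrix") else g
        L = np.linalg.cholesky(a + 1e-8 * np.eye(n))
        y = y + np.sqrt(prop) * (L @ rng.normal(size=n))
    y = y + np.sqrt(props[-1]) * rng.normal(size=n)
    return y
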