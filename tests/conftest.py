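import numpy as np
import pandas as pd
import pytest

from grsm.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with all structural features switched on."""
    cfg = SimConfig(n_samples=500, n_snps=1200, seed=11,
                    frac_hwe_violating=0.02)
    G, samples, truth = simulate_cohort(cfg)
    return cfg, G, samples, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact-integer enumeration over heterozygote counts.

    P(k het | allele counts) ∝ n! / (hom_r! k! hom_c!) · 2^k; all weights are
    exact integers, so ties and comparisons are exact.
    """
    from math import comb
    from fractions import Fraction

    n = n_AA + n_Aa + n_aa
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if rare == 0:
        return 1.0
    weights = {}
    for k in range(rare % 2, rare + 1, 2):
        hom_r = (rare - k) // 2
        hom_c = n - k - hom_r
        weights[k] = comb(n, hom_r) * comb(n - hom_r, k) * (2 ** k)
    w_obs = weights[n_Aa]
    total = sum(weights.values())
    mass = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(mass, total))
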