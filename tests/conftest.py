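import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ipskit",
    deadline=None,
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ipskit")


@pytest.fixture(scope="session")
def detox_table() -> pd.DataFrame:
    from ipskit import datasets

    return datasets.load_detox_domain_counts()


@pytest.fixture
def small_count_matrix():
    """5 species x 4 domains with one clearly enriched focal domain."""
    from ipskit.expansion import DomainCountMatrix

    counts = pd.DataFrame(
        {
            "PF_A": [40, 5, 6, 4, 5],
            "PF_B": [5, 5, 5, 5, 5],
            "PF_C": [0, 0, 0, 0, 0],
            "PF_D": [2, 8, 9, 7, 8],
        },
        index=["focal", "s2", "s3", "s4", "s5"],
    )
    totals = pd.Series([1000, 1000, 1000, 1000, 1000], index=counts.index)
    return DomainCountMatrix(counts=counts, gene_totals=totals)


def n50_oracle(lengths) -> tuple[int, int]:
    """Brute-force N50/L50: descending sort plus cumulative scan."""
    desc = sorted(lengths, reverse=True)
    total = sum(desc)
    cum = 0
    for i, length in enumerate(desc, start=1):
        cum += length
        if cum >= total / 2:
            return length, i
    raise AssertionError("unreachable")


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive two-sided Fisher p via exact integer hypergeometric pmf."""
    from fractions import Fraction
    from math import comb

    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)
    probs = {
        x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    p_obs = probs[a]
    cutoff = p_obs * (Fraction(10**7 + 1, 10**7))
    return float(min(Fraction(1), sum(p for p in probs.values() if p <= cutoff)))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
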