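"""Shared fixtures and independent reference implementations (oracles).

The oracles deliberately avoid the package's own code paths: plain-Python
loops, ``math.log`` and hand-written summation, so they can arbitrate the
vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from polarlabel import DiseaseCountVector, default_spec, generate_cohort


@pytest.fixture
def toy_vector() -> DiseaseCountVector:
    """Seven-patient cohort with counts spanning four orders of magnitude."""
    counts = pd.Series([0, 0, 1, 3, 10, 100, 1000],
                       index=[f"p{i}" for i in range(7)])
    return DiseaseCountVector(counts=counts, target_concept="DX_TOY")


@pytest.fixture(scope="session")
def small_cohort():
    """A 2000-patient asthma-like synthetic cohort shared across tests."""
    return generate_cohort(default_spec("asthma-like", n_patients=2000, seed=0))


# ---------------------------------------------------------------------------
# brute-force references


def brute_force_partition(counts: dict[str, int], alpha: float,
                          low_cutoff: float = 1.0, base: str = "natural",
                          sd_mode: str = "population"):
    """Plain-loop polar partition: recompute log counts and filter directly.

    Returns (positives, negatives, middle) as frozensets of patient ids.
    """
    logf = math.log if base == "natural" else math.log10
    logs = {p: logf(c + 1) for p, c in counts.items()}
    psp = [p for p, c in counts.items() if c >= 1]
    assert psp, "oracle requires at least one nonzero count"
    vals = [logs[p] for p in psp]
    mean = sum(vals) / len(vals)
    denom = len(vals) if sd_mode == "population" else max(len(vals) - 1, 1)
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / denom)
    high = mean + alpha * sd
    pos = frozenset(p for p in counts if logs[p] >= high)
    neg = frozenset(p for p in counts if logs[p] <= low_cutoff and p not in pos)
    mid = frozenset(counts) - pos - neg
    return pos, neg, mid, high


def brute_force_auroc(scores, labels) -> float:
    """Exhaustive Mann-Whitney pair counting, ties as one half."""
    cases = [s for s, y in zip(scores, labels) if y == 1]
    controls = [s for s, y in zip(scores, labels) if y == 0]
    assert cases and controls
    total = 0.0
    for c in cases:
        for k in controls:
            if c > k:
                total += 1.0
            elif c == k:
                total += 0.5
    return total / (len(cases) * len(controls))


def random_zero_inflated_counts(rng: np.random.Generator, n: int,
                                zero_prob: float = 0.5,
                                mu: float = 2.0, sigma: float = 1.2) -> dict[str, int]:
    """Mixed zero-inflated log-normal counts keyed by patient id."""
    zero = rng.random(n) < zero_prob
    draws = np.rint(rng.lognormal(mu, sigma, size=n)).astype(int)
    draws[zero] = 0
    return {f"r{i}": int(c) for i, c in enumerate(draws)}


def as_vector(counts: dict[str, int]) -> DiseaseCountVector:
    return DiseaseCountVector(
        counts=pd.Series(list(counts.values()), index=list(counts.keys())),
        target_concept="DX_RAND",
    )
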