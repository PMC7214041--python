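"""The polar labeling (PL) algorithm.

PL turns a noisy per-patient diagnostic-code count into a silver-standard
training label by exploiting the shape of the count distribution: patients
far out on the high pole of the log count distribution almost certainly
have the disease, patients at the low pole (zero or one code) almost
certainly do not, and the ambiguous middle is discarded. The steps:

1. take each patient's disease diagnostic-code count;
2. log-normalize as ``log(count + 1)`` so zero counts map to 0;
3. patients with count >= 1 are *potential silver positives* (PSP);
4. compute the mean and standard deviation of the log-normalized counts
   over the PSP; the high pole cut-off is ``mean + alpha * sd`` for a
   caller-chosen cut-off factor alpha; the low pole cut-off sits at 1.0
   on the log axis;
5. patients on/right of the high cut-off are silver positive, patients
   on/left of the low cut-off (including every zero count) are silver
   negative;
6. the negative set is subsampled to size
   ``round(|SN| * |SP| / |PSP|)`` so the balanced set's class mix tracks
   the cohort's;
7. the balanced silver set is the union of positives and the subsampled
   negatives;
8. a uniform random subset of a requested *train size* is emitted.

Alpha and train size are the algorithm's only two parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort_model import DiseaseCountVector, SilverStandard
from .errors import CapacityError, ConfigurationError, EmptyPoleError

__all__ = [
    "PolarConfig",
    "PoleCutoffs",
    "PolarPartition",
    "log_normalize",
    "fit_poles",
    "assign_polar_labels",
    "balance_negatives",
    "sample_silver",
    "polar_label",
]

_LOG_BASES = ("natural", "base10")


@dataclass(frozen=True)
class PolarConfig:
    """Parameters of a PL run.

    alpha
        Cut-off factor: multiplier of the PSP standard deviation that sets
        the high pole's stringency. Larger alpha labels fewer, purer
        positives.
    train_size
        Requested size of the emitted silver training set.
    log_base
        "natural" (default) or "base10" for the log normalization.
    low_pole_cutoff
        Position of the low pole on the log-normalized axis (default 1.0).
    seed
        Master seed; the negative-balancing draw and the final subsample
        consume independent sub-streams derived from it.
    strict_train_size
        If True, a train size exceeding the balanced set is an error
        instead of a clamp-with-warning.
    sd_mode
        "population" (divisor n, default) or "sample" (n - 1) for the PSP
        standard deviation.
    """

    alpha: float = 0.5
    train_size: int = 8000
    log_base: str = "natural"
    low_pole_cutoff: float = 1.0
    seed: int = 0
    strict_train_size: bool = False
    sd_mode: str = "population"

    def __post_init__(self) -> None:
        if self.train_size < 1:
            raise ConfigurationError("train_size must be >= 1")
        if self.low_pole_cutoff < 0:
            raise ConfigurationError("low_pole_cutoff must be >= 0")
        if self.log_base not in _LOG_BASES:
            raise ConfigurationError(f"log_base must be one of {_LOG_BASES}")
        if self.sd_mode not in ("population", "sample"):
            raise ConfigurationError("sd_mode must be 'population' or 'sample'")


@dataclass(frozen=True)
class PoleCutoffs:
    """Fitted pole positions on the log-normalized axis."""

    low: float
    high: float
    psp_mean: float
    psp_sd: float
    n_psp: int
    alpha: float

    def __post_init__(self) -> None:
        if self.psp_sd < 0 or self.n_psp < 0:
            raise ValueError("psp_sd and n_psp must be non-negative")


@dataclass(frozen=True)
class PolarPartition:
    """Partition of a cohort into silver positives, silver negatives and the
    unlabeled middle, plus the PSP set the pole statistics came from.

    Patient sets are stored as ordered lists (cohort order) so downstream
    random draws are reproducible.
    """

    silver_positive: list[str]
    silver_negative: list[str]
    unlabeled_middle: list[str]
    potential_silver_positive: list[str]

    def patient_sets(self) -> tuple[set, set, set]:
        return (
            set(self.silver_positive),
            set(self.silver_negative),
            set(self.unlabeled_middle),
        )


def log_normalize(count, log_base: str = "natural"):
    """``log(count + 1)`` in the configured base; 0 maps to 0.

    Accepts a scalar or array of non-negative integers.
    """
    arr = np.asarray(count)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if log_base == "natural":
        out = np.log1p(arr.astype(np.float64))
    elif log_base == "base10":
        out = np.log10(arr.astype(np.float64) + 1.0)
    else:
        raise ConfigurationError(f"log_base must be one of {_LOG_BASES}")
    return float(out) if np.isscalar(count) else out


def fit_poles(counts: DiseaseCountVector, config: PolarConfig) -> PoleCutoffs:
    """Compute the high/low pole cut-offs from the PSP log-count statistics.

    The mean and standard deviation are taken over patients with count >= 1
    only; zero-count patients carry no information about how intensely a
    true case is coded.
    """
    values = counts.counts.to_numpy()
    psp_mask = values >= 1
    n_psp = int(psp_mask.sum())
    if n_psp == 0:
        raise EmptyPoleError(
            f"no patient carries the disease code {counts.target_concept!r}; "
            f"polar labeling is inapplicable to this cohort"
        )
    logs = log_normalize(values[psp_mask], config.log_base)
    mean = float(np.mean(logs))
    ddof = 0 if config.sd_mode == "population" else 1
    if np.all(logs == logs[0]):
        sd = 0.0  # exact zero variance; avoids fp dust shifting the high pole
        mean = float(logs[0])
    elif ddof == 1 and n_psp == 1:
        sd = 0.0
    else:
        sd = float(np.std(logs, ddof=ddof))
    return PoleCutoffs(
        low=config.low_pole_cutoff,
        high=mean + config.alpha * sd,
        psp_mean=mean,
        psp_sd=sd,
        n_psp=n_psp,
        alpha=config.alpha,
    )


def assign_polar_labels(counts: DiseaseCountVector, cutoffs: PoleCutoffs,
                        log_base: str = "natural") -> PolarPartition:
    """Partition the cohort by comparing log-normalized counts to the poles.

    Both comparisons are inclusive (on/right of high is positive, on/left
    of low is negative); when the poles cross (high <= low, possible at
    large negative alpha) positive assignment takes precedence.
    """
    values = counts.counts.to_numpy()
    patients = np.asarray(counts.patients, dtype=object)
    logs = log_normalize(values, log_base)
    pos_mask = logs >= cutoffs.high
    neg_mask = (logs <= cutoffs.low) & ~pos_mask
    mid_mask = ~pos_mask & ~neg_mask
    psp_mask = values >= 1
    return PolarPartition(
        silver_positive=list(patients[pos_mask]),
        silver_negative=list(patients[neg_mask]),
        unlabeled_middle=list(patients[mid_mask]),
        potential_silver_positive=list(patients[psp_mask]),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def balance_negatives(partition: PolarPartition,
                      rng: np.random.Generator | int) -> PolarPartition:
    """Subsample the negative set so the balanced set mirrors the cohort mix.

    The target size is ``round(|SN| * |SP| / |PSP|)`` (half-away-from-zero),
    clamped to at least 1 negative when any are available; the draw is
    uniform without replacement.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n_sp = len(partition.silver_positive)
    n_sn = len(partition.silver_negative)
    n_psp = len(partition.potential_silver_positive)
    if n_sp == 0:
        raise EmptyPoleError("no silver positives: the high pole cut-off excludes every patient")
    if n_psp == 0:
        raise EmptyPoleError("no potential silver positives in partition")
    if n_sn == 0:
        return partition
    y = _round_half_away(n_sn * n_sp / n_psp)
    y = max(1, min(y, n_sn))
    chosen = rng.choice(n_sn, size=y, replace=False)
    kept = [partition.silver_negative[i] for i in sorted(chosen)]
    return replace(partition, silver_negative=kept)


def sample_silver(partition: PolarPartition, config: PolarConfig,
                  cutoffs: PoleCutoffs, counts: DiseaseCountVector,
                  rng: np.random.Generator | int | None = None) -> SilverStandard:
    """Emit a uniform random subset of the balanced silver set.

    ``partition`` must already be balanced. If the requested train size
    exceeds the balanced set, the full set is returned and flagged
    (``clamped``), unless ``strict_train_size`` makes it an error.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    pool = [(p, 1, "high") for p in partition.silver_positive]
    pool += [(p, 0, "low") for p in partition.silver_negative]
    n_pool = len(pool)
    clamped = False
    if config.train_size > n_pool:
        if config.strict_train_size:
            raise CapacityError(config.train_size, n_pool)
        warnings.warn(
            f"train size {config.train_size} exceeds balanced silver set of "
            f"{n_pool}; returning the full set",
            stacklevel=2,
        )
        take = n_pool
        clamped = True
    else:
        take = config.train_size
    idx = sorted(rng.choice(n_pool, size=take, replace=False))
    chosen = [pool[i] for i in idx]
    patients = [p for p, _, _ in chosen]
    raw = counts.counts.loc[patients].to_numpy()
    records = pd.DataFrame(
        {
            "silver_label": np.array([lab for _, lab, _ in chosen], dtype=np.int64),
            "disease_count": raw.astype(np.int64),
            "log_count": log_normalize(raw, config.log_base),
            "pole": [pole for _, _, pole in chosen],
        },
        index=patients,
    )
    return SilverStandard(
        records=records, cutoffs_used=cutoffs, seed_used=config.seed, clamped=clamped
    )


def polar_label(counts: DiseaseCountVector, config: PolarConfig) -> SilverStandard:
    """Run PL end to end: fit poles, partition, balance, subsample.

    The master seed drives two independent sub-streams, one for the
    negative-balancing draw and one for the final train-size subsample, so
    changing the train size does not perturb which negatives survive
    balancing.
    """
    cutoffs = fit_poles(counts, config)
    partition = assign_polar_labels(counts, cutoffs, config.log_base)
    balance_ss, sample_ss = np.random.SeedSequence(config.seed).spawn(2)
    balanced = balance_negatives(partition, np.random.default_rng(balance_ss))
    return sample_silver(balanced, config, cutoffs, counts,
                         rng=np.random.default_rng(sample_ss))
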