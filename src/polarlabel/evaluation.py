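"""Gold-vs-silver evaluation harness.

The experiment: the chart-reviewed (gold) patients are split randomly and
equally into a development half and a validation half, repeated ``n_runs``
times. In every run a *gold-ML* model is trained on the development half,
a *silver-ML* model is trained on a silver standard regenerated from the
unlabeled remainder of the cohort, and both — plus the dx-code presence
baseline — are scored on the validation half. Per-run AUROCs are averaged
and the gold-vs-silver difference is tested with a paired t-test.

AUROC here is the Mann–Whitney probability: the chance a random case
outscores a random control, ties counted one half.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cohort_model import ConceptCountTable, GoldStandard
from .errors import CohortSizeError, DegenerateLabelsError
from .feature_extraction import build_feature_matrix
from .model_training import dx_code_baseline, train_model
from .polar_labeling import PolarConfig, polar_label

__all__ = [
    "SplitPlan",
    "TTestResult",
    "EvaluationReport",
    "auroc",
    "make_splits",
    "t_test_auroc",
    "run_comparison",
]


@dataclass(frozen=True)
class SplitPlan:
    """One random equal split of the gold Y/N patients."""

    run_index: int
    development: list[str]
    validation: list[str]


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    mean_diff: float
    degenerate: bool = False
    paired: bool = True


@dataclass
class EvaluationReport:
    """Per-run AUROCs for every arm plus summary statistics.

    ``runs`` maps arm name ("gold_rf", "silver_lr", "baseline", ...) to the
    list of per-run AUROCs; ``t_tests`` maps model kind to the gold-vs-
    silver paired t-test.
    """

    runs: dict[str, list[float]]
    n_runs: int
    t_tests: dict[str, TTestResult | None]
    config_echo: dict

    def mean(self, arm: str) -> float:
        return float(np.mean(self.runs[arm]))

    def sd(self, arm: str) -> float:
        return float(np.std(self.runs[arm], ddof=1)) if self.n_runs > 1 else 0.0

    def summary(self) -> pd.DataFrame:
        rows = [
            {"arm": arm, "mean_auroc": self.mean(arm), "sd_auroc": self.sd(arm)}
            for arm in self.runs
        ]
        return pd.DataFrame(rows).set_index("arm")

    def to_dict(self) -> dict:
        out = {
            "n_runs": self.n_runs,
            "runs": self.runs,
            "summary": {
                arm: {"mean": self.mean(arm), "sd": self.sd(arm)} for arm in self.runs
            },
            "t_tests": {
                kind: (None if tt is None else {
                    "t": tt.t, "p": tt.p, "df": tt.df,
                    "mean_diff": tt.mean_diff, "degenerate": tt.degenerate,
                    "paired": tt.paired,
                })
                for kind, tt in self.t_tests.items()
            },
            "config": self.config_echo,
        }
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve of ``scores`` against binary ``labels``.

    Equals the fraction of (case, control) pairs in which the case outscores
    the control, counting exact ties as one half.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelsError("AUROC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def make_splits(gold: GoldStandard, n_runs: int, seed: int,
                max_redraws: int = 100) -> list[SplitPlan]:
    """Draw ``n_runs`` independent random equal splits of the gold Y/N set.

    P/U labels are dropped before splitting. Halves differ in size by at
    most one. A draw leaving either half single-class is redrawn (bounded);
    a cohort whose minority class cannot populate both halves errors.
    """
    certain = gold.certain()
    y = certain.binary()
    patients = np.asarray(certain.patients, dtype=object)
    n = len(patients)
    counts = y.value_counts()
    if n < 4 or len(counts) < 2 or counts.min() < 2:
        raise CohortSizeError(
            f"gold Y/N cohort too small for equal splitting: n={n}, "
            f"class counts={counts.to_dict()}"
        )
    rng = np.random.default_rng(seed)
    labels = y.to_numpy()
    plans: list[SplitPlan] = []
    n_dev = n // 2
    for run in range(1, n_runs + 1):
        for _ in range(max_redraws):
            perm = rng.permutation(n)
            dev, val = perm[:n_dev], perm[n_dev:]
            if len(np.unique(labels[dev])) == 2 and len(np.unique(labels[val])) == 2:
                plans.append(SplitPlan(run, list(patients[dev]), list(patients[val])))
                break
        else:
            raise CohortSizeError(
                f"could not draw a split with both classes in both halves "
                f"after {max_redraws} attempts (run {run})"
            )
    return plans


def t_test_auroc(runs_a: Sequence[float], runs_b: Sequence[float],
                 paired: bool = True) -> TTestResult:
    """Two-sided t-test on per-run AUROCs (paired across runs by default).

    Degenerate zero-variance paired differences yield p=1 when the mean
    difference is 0 and p=0 otherwise, flagged as degenerate.
    """
    a = np.asarray(runs_a, dtype=np.float64)
    b = np.asarray(runs_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"run vectors differ in length: {a.shape} vs {b.shape}")
    if len(a) < 2:
        raise ValueError("t-test needs at least 2 paired observations")
    if paired:
        diff = a - b
        mean_diff = float(diff.mean())
        if np.allclose(diff.std(ddof=1), 0.0):
            p = 1.0 if np.isclose(mean_diff, 0.0) else 0.0
            t = 0.0 if np.isclose(mean_diff, 0.0) else np.inf * np.sign(mean_diff)
            return TTestResult(float(t), p, len(a) - 1, mean_diff, degenerate=True)
        res = stats.ttest_rel(a, b)
        return TTestResult(float(res.statistic), float(res.pvalue), len(a) - 1, mean_diff)
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(res.statistic), float(res.pvalue),
                       int(res.df) if hasattr(res, "df") else len(a) - 1,
                       float(a.mean() - b.mean()), paired=False)


def _run_seed(master: int, run: int) -> int:
    # deterministic per-run sub-seed below 2**31
    child = np.random.SeedSequence(entropy=master, spawn_key=(run,))
    return int(child.generate_state(1)[0] % (2**31))


def run_comparison(table: ConceptCountTable, gold: GoldStandard,
                   concept_list: Sequence[str], disease_concept: str,
                   polar_config: PolarConfig, n_runs: int = 15,
                   model_kinds: Sequence[str] = ("rf", "lr"),
                   seed: int = 0, rf_n_estimators: int = 1000,
                   paired_ttest: bool = True) -> EvaluationReport:
    """Run the full repeated-split gold-vs-silver comparison.

    Patients in the gold standard must all appear in the count table; the
    unlabeled set is every table patient outside the gold standard. The
    silver standard is regenerated from the unlabeled set each run with a
    run-derived seed, so the reported averages also reflect PL's own
    sampling variability.
    """
    missing = set(gold.patients) - set(table.patients)
    if missing:
        raise ValueError(
            f"{len(missing)} gold patients absent from the count table, "
            f"e.g. {sorted(missing)[:3]}"
        )
    certain = gold.certain()
    gold_binary = certain.binary()
    unlabeled = [p for p in table.patients if p not in set(gold.patients)]

    features = build_feature_matrix(table, concept_list)
    disease = table.disease_counts(disease_concept)
    splits = make_splits(certain, n_runs, seed=_run_seed(seed, 0))

    arms: dict[str, list[float]] = {}
    for kind in model_kinds:
        arms[f"gold_{kind}"] = []
        arms[f"silver_{kind}"] = []
    arms["baseline"] = []

    unlabeled_counts = disease.counts.loc[unlabeled]
    unlabeled_vector = replace(disease, counts=unlabeled_counts)

    for plan in splits:
        run_seed = _run_seed(seed, plan.run_index)
        silver = polar_label(unlabeled_vector, replace(polar_config, seed=run_seed))

        val_labels = gold_binary.loc[plan.validation].to_numpy()
        dev_labels = gold_binary.loc[plan.development].to_numpy()

        dev_X = _subset_features(features, plan.development)
        val_X = _subset_features(features, plan.validation)
        silver_X = _subset_features(features, silver.patients)

        for kind in model_kinds:
            try:
                gold_model = train_model(kind, dev_X, dev_labels, run_seed,
                                         "gold", rf_n_estimators)
                silver_model = train_model(kind, silver_X,
                                           silver.labels.to_numpy(),
                                           run_seed, "silver", rf_n_estimators)
            except Exception as exc:
                raise type(exc)(f"run {plan.run_index} ({kind}): {exc}") from exc
            arms[f"gold_{kind}"].append(auroc(gold_model.score(val_X), val_labels))
            arms[f"silver_{kind}"].append(auroc(silver_model.score(val_X), val_labels))

        base_scores = dx_code_baseline(
            replace(disease, counts=disease.counts.loc[plan.validation])
        )
        arms["baseline"].append(auroc(base_scores, val_labels))

    t_tests: dict[str, TTestResult | None] = {}
    for kind in model_kinds:
        if n_runs >= 2:
            t_tests[kind] = t_test_auroc(arms[f"gold_{kind}"], arms[f"silver_{kind}"],
                                         paired=paired_ttest)
        else:
            t_tests[kind] = None  # not computable from a single run

    concept_hash = hashlib.sha256(",".join(concept_list).encode()).hexdigest()[:16]
    echo = {
        "polar_config": {
            "alpha": polar_config.alpha,
            "train_size": polar_config.train_size,
            "log_base": polar_config.log_base,
            "low_pole_cutoff": polar_config.low_pole_cutoff,
            "sd_mode": polar_config.sd_mode,
        },
        "disease_concept": disease_concept,
        "concept_list_sha256_16": concept_hash,
        "n_runs": n_runs,
        "model_kinds": list(model_kinds),
        "seed": seed,
        "rf_n_estimators": rf_n_estimators,
        "significance_threshold": 0.05,  # reporting metadata only
    }
    return EvaluationReport(runs=arms, n_runs=n_runs, t_tests=t_tests, config_echo=echo)


def _subset_features(features, patients):
    from .feature_extraction import FeatureMatrix

    return FeatureMatrix(features.data.loc[list(patients)])
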