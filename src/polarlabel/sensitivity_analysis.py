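"""Parameter sensitivity sweep over the PL cut-off factor and train size.

For each (alpha, train size) grid cell, a silver standard is generated from
the unlabeled set, a model is trained on it, and AUROC is measured against
the entire gold Y/N labeled set (no development/validation split — the gold
set serves purely as fixed evaluation labels here, which is intentionally
different from the repeated-split comparison harness). Each cell is
averaged over ``n_reps`` repetitions with deterministic per-cell seeds, so
any cell can be recomputed in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_model import ConceptCountTable, GoldStandard
from .errors import CapacityError, ConfigurationError, DomainError, EmptyPoleError
from .evaluation import auroc
from .feature_extraction import FeatureMatrix, build_feature_matrix
from .model_training import train_model
from .polar_labeling import PolarConfig, polar_label

__all__ = ["SensitivityGrid", "sensitivity_grid", "default_alpha_grid", "DEFAULT_TRAIN_SIZES"]

DEFAULT_TRAIN_SIZES = (300, 1000, 2000, 4000, 8000)


def default_alpha_grid() -> list[float]:
    """The sweep's canonical cut-off grid: -3.0 to +3.0 in 0.5 steps."""
    return [round(a, 1) for a in np.arange(-3.0, 3.01, 0.5)]


@dataclass
class SensitivityGrid:
    """Long-format sweep results plus per-cell summaries.

    ``cells`` has one row per (alpha, train_size, rep) with the achieved
    AUROC, or NaN plus a ``failure`` reason for infeasible cells (e.g. an
    empty high pole at large alpha).
    """

    cells: pd.DataFrame  # columns: alpha, train_size, rep, auroc, clamped, failure
    alphas: list[float]
    train_sizes: list[int]
    n_reps: int

    def cell_mean(self, alpha: float, train_size: int) -> float:
        sel = self.cells[(self.cells["alpha"] == alpha)
                         & (self.cells["train_size"] == train_size)]
        ok = sel["auroc"].dropna()
        return float(ok.mean()) if len(ok) else float("nan")

    def summary(self) -> pd.DataFrame:
        """Per-cell mean AUROC, completed-rep count and failure reason."""
        rows = []
        for a in self.alphas:
            for s in self.train_sizes:
                sel = self.cells[(self.cells["alpha"] == a)
                                 & (self.cells["train_size"] == s)]
                ok = sel["auroc"].dropna()
                failures = sel["failure"].dropna()
                rows.append({
                    "alpha": a,
                    "train_size": s,
                    "mean_auroc": float(ok.mean()) if len(ok) else float("nan"),
                    "n_completed": int(len(ok)),
                    "failure": failures.iloc[0] if len(failures) else "",
                })
        return pd.DataFrame(rows)

    def heatmap(self, ax=None):
        """Mean-AUROC heatmap (train size x alpha); needs matplotlib."""
        import matplotlib.pyplot as plt

        pivot = self.summary().pivot(index="train_size", columns="alpha",
                                     values="mean_auroc")
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(pivot.to_numpy(), aspect="auto", origin="lower")
        ax.set_xticks(range(len(pivot.columns)), [f"{a:g}" for a in pivot.columns])
        ax.set_yticks(range(len(pivot.index)), [str(s) for s in pivot.index])
        ax.set_xlabel("cut-off factor alpha")
        ax.set_ylabel("train size")
        ax.figure.colorbar(im, ax=ax, label="mean AUROC")
        return ax


def _cell_seed(master: int, ai: int, si: int, rep: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(ai, si, rep))
    return int(ss.generate_state(1)[0] % (2**31))


def sensitivity_grid(table: ConceptCountTable, gold: GoldStandard,
                     concept_list: Sequence[str], disease_concept: str,
                     alphas: Sequence[float] | None = None,
                     train_sizes: Sequence[int] | None = None,
                     n_reps: int = 5, model_kind: str = "lr",
                     seed: int = 0, base_config: PolarConfig | None = None,
                     rf_n_estimators: int = 1000) -> SensitivityGrid:
    """Sweep PL parameters and measure silver-trained model AUROC.

    The gold Y/N patients are the fixed evaluation set; the silver standard
    comes from the remaining (unlabeled) patients. Cells where PL raises a
    domain error (empty pole, strict capacity) are marked infeasible with
    the reason recorded, never a fabricated number.
    """
    alphas = list(alphas) if alphas is not None else default_alpha_grid()
    train_sizes = list(train_sizes) if train_sizes is not None else list(DEFAULT_TRAIN_SIZES)
    if not alphas or not train_sizes or n_reps < 1:
        raise ConfigurationError("alphas, train_sizes and n_reps must be non-empty/positive")
    base = base_config if base_config is not None else PolarConfig()

    certain = gold.certain()
    gold_binary = certain.binary()
    eval_patients = list(gold_binary.index)
    unlabeled = [p for p in table.patients if p not in set(gold.patients)]

    features = build_feature_matrix(table, concept_list)
    eval_X = FeatureMatrix(features.data.loc[eval_patients])
    eval_y = gold_binary.to_numpy()
    disease = table.disease_counts(disease_concept)
    unlabeled_vector = replace(disease, counts=disease.counts.loc[unlabeled])

    rows = []
    for ai, a in enumerate(alphas):
        for si, s in enumerate(train_sizes):
            for rep in range(n_reps):
                cell_seed = _cell_seed(seed, ai, si, rep)
                cfg = replace(base, alpha=a, train_size=s, seed=cell_seed)
                row = {"alpha": a, "train_size": s, "rep": rep,
                       "auroc": np.nan, "clamped": False, "failure": None}
                try:
                    silver = polar_label(unlabeled_vector, cfg)
                    silver_X = FeatureMatrix(features.data.loc[silver.patients])
                    model = train_model(model_kind, silver_X,
                                        silver.labels.to_numpy(), cell_seed,
                                        "silver", rf_n_estimators)
                    row["auroc"] = auroc(model.score(eval_X), eval_y)
                    row["clamped"] = silver.clamped
                except (EmptyPoleError, CapacityError, DomainError) as exc:
                    row["failure"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
    cells = pd.DataFrame(rows)
    return SensitivityGrid(cells=cells, alphas=alphas, train_sizes=train_sizes,
                           n_reps=n_reps)
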