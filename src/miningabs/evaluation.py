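"""Reciprocal evaluation of mined panels on a held-out dataset.

One dataset is held out; the panel is mined on the remaining (training)
datasets; the held-out dataset then scores the panel by leave-one-out
cross-validation: for every sample, the panel is resolved onto the test
platform, coefficients are refitted on the other N−1 samples, and the
held-out sample is classified at probability threshold 0.5. Accuracy is

    (TP + TN) / (TP + TN + FP + FN).

Coefficients are refitted per fold because they are dataset-specific by
design (each dataset gets its own sibling fit); only the panel — the
identifiers — transfers. A ``refit=False`` mode instead transfers the
average of the training sibling models' standardised coefficients and
applies it to the standardised test predictors, for the alternative reading
in which the trained model itself is carried over.

The defective-model ablation removes one panel member at a time and
re-scores the k reduced panels, quantifying how much each member contributes
to the joint signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .clm import CLM
from .ga_search import GAConfig, GAResult, identifier_universe, run_ga
from .io_formats import ExpressionDataset, Identifier, Platform
from .logit import LogitFit, fit_lm, predict_prob
from .mapping import resolve_panel
from .similarity import SimilarityMatrix

__all__ = [
    "ConfusionCounts",
    "LoocvResult",
    "ReciprocalResult",
    "accuracy",
    "loocv_accuracy",
    "reciprocal_test",
    "defective_test",
]


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def add(self, y_true: int, y_pred: int) -> None:
        if y_true == 1:
            if y_pred == 1:
                self.TP += 1
            else:
                self.FN += 1
        else:
            if y_pred == 1:
                self.FP += 1
            else:
                self.TN += 1


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise ValueError("no evaluated samples")
    return (c.TP + c.TN) / c.total


@dataclass
class LoocvResult:
    dataset_id: str
    confusion: ConfusionCounts
    accuracy: float
    predictions: list[dict] = field(default_factory=list)
    n_folds: int = 0
    n_skipped: int = 0


@dataclass
class ReciprocalResult:
    held_out_dataset_id: str
    clm: CLM
    confusion: ConfusionCounts
    accuracy: float
    predictions: list[dict]
    ga_result: GAResult | None = None

    def to_dict(self) -> dict:
        return {
            "held_out_dataset_id": self.held_out_dataset_id,
            "accuracy": self.accuracy,
            "confusion": {
                "TP": self.confusion.TP, "TN": self.confusion.TN,
                "FP": self.confusion.FP, "FN": self.confusion.FN,
            },
            "clm": self.clm.to_dict(),
            "predictions": self.predictions,
        }


def _transfer_fit(clm: CLM, X: np.ndarray) -> LogitFit:
    """Average the training sibling coefficients on the standardised scale.

    Yields a fixed (not refitted) model applicable to standardised test
    predictors; used by the no-refit evaluation mode.
    """
    b0 = float(np.mean([sk.fit.beta0_std for sk in clm.sk_lms]))
    betas_std = np.mean([sk.fit.betas_std for sk in clm.sk_lms], axis=0)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    betas = betas_std / sd
    beta0 = b0 - float(np.sum(betas_std * mu / sd))
    return LogitFit(
        beta0=beta0, betas=betas, llv=0.0, converged=True,
        beta0_std=b0, betas_std=betas_std,
    )


def loocv_accuracy(
    test_dataset: ExpressionDataset,
    EI: Sequence[Identifier],
    M: SimilarityMatrix,
    platforms: Mapping[str, Platform],
    refit: bool = True,
    trained_clm: CLM | None = None,
) -> LoocvResult:
    """Leave-one-out accuracy of a fixed panel on one dataset.

    The panel is resolved onto the test platform once (resolution does not
    depend on the fold). With ``refit=True`` each fold refits coefficients
    on the remaining samples; a fold whose training half loses one class
    entirely is skipped with a warning and counted in ``n_skipped``.
    """
    y = test_dataset.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError(
            f"dataset {test_dataset.dataset_id!r} needs >= 2 samples per class "
            f"for leave-one-out evaluation (got {counts.tolist()})"
        )
    platform = platforms[test_dataset.platform_id]
    resolved = resolve_panel(EI, platform, M)
    probe_rows = [platform.probe_index(r.target.probe_id) for r in resolved]
    X = test_dataset.predictor_matrix(probe_rows)
    n = test_dataset.n_samples

    fixed_fit = None
    if not refit:
        if trained_clm is None:
            raise ValueError("refit=False requires the trained model")
        fixed_fit = _transfer_fit(trained_clm, X)

    confusion = ConfusionCounts()
    predictions: list[dict] = []
    n_folds = n_skipped = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if refit:
            if len(np.unique(y[mask])) < 2:
                warnings.warn(
                    f"fold {i}: removing sample {test_dataset.sample_ids[i]!r} "
                    "leaves a single class; fold skipped"
                )
                n_skipped += 1
                continue
            fit = fit_lm(X[mask], y[mask])
        else:
            fit = fixed_fit
        p = float(predict_prob(fit, X[i:i + 1])[0])
        y_pred = 1 if p >= 0.5 else 0
        confusion.add(int(y[i]), y_pred)
        predictions.append(
            {
                "sample_id": test_dataset.sample_ids[i],
                "label": int(y[i]),
                "probability": p,
                "predicted": y_pred,
            }
        )
        n_folds += 1
    return LoocvResult(
        dataset_id=test_dataset.dataset_id,
        confusion=confusion,
        accuracy=accuracy(confusion),
        predictions=predictions,
        n_folds=n_folds,
        n_skipped=n_skipped,
    )


def reciprocal_test(
    datasets: Sequence[ExpressionDataset],
    M: SimilarityMatrix,
    config: GAConfig,
    held_out_id: str,
    platforms: Mapping[str, Platform],
    IDF: Sequence[Identifier] | None = None,
    refit: bool = True,
) -> ReciprocalResult:
    """Mine a panel on all datasets except one; score it on the held-out one."""
    if len(datasets) < 2:
        raise ValueError("reciprocal test needs at least two datasets")
    training = [d for d in datasets if d.dataset_id != held_out_id]
    held_out = [d for d in datasets if d.dataset_id == held_out_id]
    if not held_out:
        raise ValueError(f"held-out dataset {held_out_id!r} not found")
    if len(training) == len(datasets):
        raise ValueError(f"held-out dataset {held_out_id!r} not found")
    test_dataset = held_out[0]
    if IDF is None:
        training_platforms = {
            d.platform_id: platforms[d.platform_id] for d in training
        }
        IDF = identifier_universe(training_platforms)
    ga_result = run_ga(training, M, IDF, config, platforms)
    loocv = loocv_accuracy(
        test_dataset, ga_result.clm.EI, M, platforms,
        refit=refit, trained_clm=ga_result.clm,
    )
    return ReciprocalResult(
        held_out_dataset_id=held_out_id,
        clm=ga_result.clm,
        confusion=loocv.confusion,
        accuracy=loocv.accuracy,
        predictions=loocv.predictions,
        ga_result=ga_result,
    )


def defective_test(
    clm: CLM,
    datasets: Sequence[ExpressionDataset],
    M: SimilarityMatrix,
    held_out_id: str,
    platforms: Mapping[str, Platform],
) -> dict:
    """Leave-one-member-out ablation of a mined panel on the held-out dataset.

    Returns the improved (full-panel) accuracy and, for each of the k panel
    members, the accuracy of the reduced panel without it. Coefficients are
    always refitted per fold: a reduced panel has no meaningful transferred
    coefficient vector.
    """
    if clm.k < 2:
        raise ValueError("defective test needs a panel of size >= 2")
    held_out = [d for d in datasets if d.dataset_id == held_out_id]
    if not held_out:
        raise ValueError(f"held-out dataset {held_out_id!r} not found")
    test_dataset = held_out[0]
    improved = loocv_accuracy(test_dataset, clm.EI, M, platforms)
    defective: list[dict] = []
    for i, removed in enumerate(clm.EI):
        panel = clm.EI[:i] + clm.EI[i + 1:]
        res = loocv_accuracy(test_dataset, panel, M, platforms)
        defective.append({"removed": removed, "accuracy": res.accuracy})
    return {
        "improved_accuracy": improved.accuracy,
        "defective": defective,
        "mean_defective_accuracy": float(
            np.mean([d["accuracy"] for d in defective])
        ),
    }
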