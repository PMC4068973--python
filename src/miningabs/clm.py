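"""Common logit models: one candidate panel, one sibling fit per dataset.

A candidate panel ``EI`` (k identifiers with pairwise-distinct genes) is
scored against a collection of datasets as follows:

1. resolve the full panel onto each dataset's platform (identity resolution
   where the identifier already lives on that platform);
2. fit a *sibling-like* logit model (sk-LM) on each dataset with the
   resolved probes' intensity rows as predictors;
3. the common model's score is the arithmetic mean of the sk-LM log
   likelihoods.

The mean is unweighted even though datasets differ in sample count: each
dataset contributes one sibling model, and the score ranks panels, not
samples. Fitting is always within one dataset, so no cross-platform
intensity normalisation is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import ExpressionDataset, Identifier, Platform
from .logit import LogitFit, fit_lm
from .mapping import ResolvedIdentifier, resolve_panel
from .similarity import SimilarityMatrix

__all__ = ["SkLM", "CLM", "build_sk_lm", "identify_clm"]


@dataclass
class SkLM:
    """Per-dataset instantiation of a panel: resolved probes plus the fit."""

    dataset_id: str
    resolved: list[ResolvedIdentifier]
    fit: LogitFit

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "resolved": [
                {
                    "source": str(r.source),
                    "target": str(r.target),
                    "mode": r.mode,
                    "similarity": r.similarity,
                }
                for r in self.resolved
            ],
            "beta0": self.fit.beta0,
            "betas": list(self.fit.betas),
            "llv": self.fit.llv,
            "converged": self.fit.converged,
            "separated": self.fit.separated,
        }


@dataclass
class CLM:
    """A candidate panel with its sibling fits and averaged log likelihood."""

    EI: tuple[Identifier, ...]
    sk_lms: list[SkLM]
    llv: float

    @property
    def k(self) -> int:
        return len(self.EI)

    def mean_abs_beta(self) -> dict[Identifier, float]:
        """Mean |standardised coefficient| per panel locus across sibling fits.

        Used by the search to spot loci that carry little signal anywhere.
        """
        stacked = np.array(
            [np.abs(sk.fit.betas_std) for sk in self.sk_lms]
        )  # (n_datasets, k)
        means = stacked.mean(axis=0)
        return {ident: float(m) for ident, m in zip(self.EI, means)}

    def to_dict(self) -> dict:
        return {
            "EI": [str(i) for i in self.EI],
            "llv": self.llv,
            "sk_lms": [sk.to_dict() for sk in self.sk_lms],
        }


def _check_distinct_genes(EI: Sequence[Identifier]) -> None:
    genes = [i.gene_id for i in EI]
    if len(set(genes)) != len(genes):
        raise ValueError(f"panel genes must be pairwise distinct, got {genes!r}")


def build_sk_lm(
    dataset: ExpressionDataset,
    EI: Sequence[Identifier],
    M: SimilarityMatrix,
    platforms: Mapping[str, Platform],
) -> SkLM:
    """Resolve ``EI`` onto the dataset's platform and fit its sibling model."""
    if not EI:
        raise ValueError("EI must be non-empty")
    platform = platforms[dataset.platform_id]
    resolved = resolve_panel(EI, platform, M)
    probe_rows = [platform.probe_index(r.target.probe_id) for r in resolved]
    X = dataset.predictor_matrix(probe_rows)
    if len(np.unique(dataset.labels)) < 2:
        raise ValueError(
            f"dataset {dataset.dataset_id!r} has a single class; cannot fit"
        )
    fit = fit_lm(X, dataset.labels)
    return SkLM(dataset_id=dataset.dataset_id, resolved=resolved, fit=fit)


def identify_clm(
    datasets: Sequence[ExpressionDataset],
    M: SimilarityMatrix,
    EI: Sequence[Identifier],
    platforms: Mapping[str, Platform],
) -> CLM:
    """Build one sk-LM per dataset and average their log likelihoods."""
    if not datasets:
        raise ValueError("at least one dataset is required")
    _check_distinct_genes(EI)
    sk_lms = [build_sk_lm(ds, EI, M, platforms) for ds in datasets]
    mean_llv = float(np.mean([sk.fit.llv for sk in sk_lms]))
    return CLM(EI=tuple(EI), sk_lms=sk_lms, llv=mean_llv)
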