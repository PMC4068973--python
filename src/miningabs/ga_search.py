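"""Genetic-algorithm search for high-likelihood biomarker panels.

Exhaustively testing every k-gene panel is hopeless at platform scale —
C(30000, 8) is about 1.6e31 combinations, roughly 1e24 years at two seconds
per evaluation — so panels are improved heuristically:

1. start from ``PS`` random panels (k identifiers, pairwise-distinct genes);
2. fitness of a panel is its common-model mean log likelihood;
3. roulette-wheel selection keeps fitter panels with higher probability;
4. kept panels are paired and swap identifiers locus-by-locus with
   probability ``TXR``; each panel's weakest locus (smallest mean
   |standardised coefficient| across its sibling fits — i.e. least
   associated with the clinical outcome anywhere) may then be replaced by a
   fresh identifier;
5. the best panel ever seen (the elite) is tracked and returned, so the
   reported optimum never degrades.

The search stops after ``MG`` generations, or earlier if the elite's log
likelihood reaches ``TLC`` (the default ``TLC = 0`` effectively disables
early stopping, since log likelihoods are negative).

Fitness evaluations are cached on the panel's identifier set: swapped-back
and re-visited panels are not refitted.

:func:`exhaustive_search` is the brute-force counterpart for small
instances; it doubles as an independent optimum oracle for the search.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .clm import CLM, identify_clm
from .io_formats import ExpressionDataset, Identifier, Platform
from .similarity import SimilarityMatrix

__all__ = [
    "GAConfig",
    "Population",
    "GAResult",
    "count_combinations",
    "brute_force_years",
    "identifier_universe",
    "init_population",
    "roulette_select",
    "crossover_and_replace",
    "run_ga",
    "exhaustive_search",
]

#: default cap on panels enumerable by exhaustive_search
EXHAUSTIVE_GUARD = 100_000


@dataclass(frozen=True)
class GAConfig:
    """Control surface of the search.

    ``PS``: population size; ``MG``: max generations; ``TXR``: per-locus
    crossover (swap) probability; ``TLC``: log-likelihood stopping threshold
    (0 = disabled in practice); ``k``: panel size; ``replace_prob``:
    probability that an individual's weakest locus is replaced each
    generation.
    """

    k: int
    PS: int = 300
    MG: int = 50
    TXR: float = 0.5
    TLC: float = 0.0
    seed: int = 0
    replace_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.PS < 1:
            raise ValueError("PS must be >= 1")
        if self.MG < 0:
            raise ValueError("MG must be >= 0")
        if not 0.0 <= self.TXR <= 1.0:
            raise ValueError("TXR must be in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.replace_prob <= 1.0:
            raise ValueError("replace_prob must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "k": self.k, "PS": self.PS, "MG": self.MG, "TXR": self.TXR,
            "TLC": self.TLC, "seed": self.seed, "replace_prob": self.replace_prob,
        }


def count_combinations(n: int, k: int) -> int:
    """Exact C(n, k) with big-integer arithmetic."""
    if k < 0 or n < 0:
        raise ValueError("n and k must be non-negative")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    return math.comb(n, k)


def brute_force_years(n: int, k: int, seconds_per_test: float = 2.0) -> float:
    """Wall time, in years, to test every C(n, k) panel sequentially."""
    return count_combinations(n, k) * seconds_per_test / (365.0 * 24 * 3600)


def identifier_universe(
    platforms: Mapping[str, Platform] | Sequence[Platform],
) -> list[Identifier]:
    """All identifiers of the given platforms, in canonical platform/probe order."""
    if isinstance(platforms, Mapping):
        platforms = list(platforms.values())
    out: list[Identifier] = []
    for pf in platforms:
        out.extend(pf.identifiers())
    return out


class _FitnessCache:
    """identify_clm memoised on the panel's identifier set (order-free)."""

    def __init__(self, datasets, M, platforms):
        self._datasets = datasets
        self._M = M
        self._platforms = platforms
        self._cache: dict[frozenset[Identifier], CLM] = {}
        self.n_evaluations = 0

    def __call__(self, panel: tuple[Identifier, ...]) -> CLM:
        key = frozenset(panel)
        clm = self._cache.get(key)
        if clm is None:
            clm = identify_clm(self._datasets, self._M, panel, self._platforms)
            self._cache[key] = clm
            self.n_evaluations += 1
        return clm


@dataclass
class Population:
    individuals: list[tuple[Identifier, ...]]
    fitness: list[CLM]
    elite: CLM

    def best(self) -> CLM:
        return max(self.fitness, key=lambda c: c.llv)


@dataclass
class GAResult:
    """Outcome of a search run: the elite model plus its trajectory."""

    clm: CLM
    elite_history: list[float] = field(default_factory=list)
    n_generations: int = 0
    n_evaluations: int = 0


def _sample_panel(
    IDF: Sequence[Identifier], k: int, rng: np.random.Generator
) -> tuple[Identifier, ...]:
    """k identifiers drawn uniformly without replacement, genes pairwise distinct."""
    order = rng.permutation(len(IDF))
    panel: list[Identifier] = []
    genes: set[str] = set()
    for idx in order:
        ident = IDF[idx]
        if ident.gene_id not in genes:
            panel.append(ident)
            genes.add(ident.gene_id)
            if len(panel) == k:
                return tuple(panel)
    raise ValueError(f"identifier universe has fewer than k={k} distinct genes")


def init_population(
    IDF: Sequence[Identifier],
    config: GAConfig,
    rng: np.random.Generator,
    evaluate: "_FitnessCache",
) -> Population:
    """PS random distinct-gene panels, fitness evaluated."""
    n_genes = len({i.gene_id for i in IDF})
    if n_genes < config.k:
        raise ValueError(
            f"identifier universe has {n_genes} distinct genes < k={config.k}"
        )
    individuals = [_sample_panel(IDF, config.k, rng) for _ in range(config.PS)]
    fitness = [evaluate(ind) for ind in individuals]
    elite = max(fitness, key=lambda c: c.llv)
    return Population(individuals=individuals, fitness=fitness, elite=elite)


def selection_weights(llvs: Sequence[float]) -> np.ndarray:
    """Roulette weights: min-shifted log likelihoods plus a small floor.

    The shift maps the worst individual near zero weight; the floor
    ``eps = 1e-6 * (max - min + 1)`` keeps it selectable and preserves
    strict monotonicity of selection probability in the log likelihood.
    """
    llvs = np.asarray(llvs, dtype=float)
    lo, hi = llvs.min(), llvs.max()
    eps = 1e-6 * (hi - lo + 1.0)
    return (llvs - lo) + eps


def roulette_select(
    pop: Population, rng: np.random.Generator
) -> list[tuple[Identifier, ...]]:
    """PS fitness-proportional draws with replacement."""
    w = selection_weights([c.llv for c in pop.fitness])
    p = w / w.sum()
    picks = rng.choice(len(pop.individuals), size=len(pop.individuals), p=p)
    return [pop.individuals[i] for i in picks]


def _swap_ok(
    a: tuple[Identifier, ...], b: tuple[Identifier, ...], locus: int
) -> bool:
    """Would swapping this locus keep genes pairwise distinct in both panels?"""
    ga = {x.gene_id for i, x in enumerate(a) if i != locus}
    gb = {x.gene_id for i, x in enumerate(b) if i != locus}
    return b[locus].gene_id not in ga and a[locus].gene_id not in gb


def crossover_and_replace(
    kept: list[tuple[Identifier, ...]],
    IDF: Sequence[Identifier],
    config: GAConfig,
    rng: np.random.Generator,
    evaluate: "_FitnessCache",
    elite: CLM,
) -> Population:
    """One generation of variation: locus swaps, then weakest-locus replacement.

    Individuals are paired sequentially (1-2, 3-4, ...); within a pair each
    locus position is swapped with probability ``TXR`` (skipping swaps that
    would duplicate a gene within a panel). Then, with probability
    ``replace_prob``, the locus with the smallest mean |standardised
    coefficient| across the individual's sibling fits is replaced by a fresh
    uniformly drawn identifier whose gene is not already in the panel.
    """
    nxt = [list(ind) for ind in kept]
    for a_idx in range(0, len(nxt) - 1, 2):
        a, b = nxt[a_idx], nxt[a_idx + 1]
        for locus in range(config.k):
            if rng.random() < config.TXR and _swap_ok(tuple(a), tuple(b), locus):
                a[locus], b[locus] = b[locus], a[locus]

    individuals: list[tuple[Identifier, ...]] = []
    fitness: list[CLM] = []
    for ind in nxt:
        panel = tuple(ind)
        clm = evaluate(panel)
        if config.replace_prob > 0 and rng.random() < config.replace_prob:
            weights = clm.mean_abs_beta()
            weakest = min(
                range(config.k), key=lambda i: (weights[panel[i]], i)
            )
            other_genes = {
                x.gene_id for i, x in enumerate(panel) if i != weakest
            }
            candidates = [
                i for i in IDF
                if i.gene_id not in other_genes and i != panel[weakest]
            ]
            if candidates:
                new_ident = candidates[rng.integers(len(candidates))]
                panel = panel[:weakest] + (new_ident,) + panel[weakest + 1:]
                clm = evaluate(panel)
        individuals.append(panel)
        fitness.append(clm)

    best = max(fitness, key=lambda c: c.llv)
    new_elite = best if best.llv > elite.llv else elite
    return Population(individuals=individuals, fitness=fitness, elite=new_elite)


def run_ga(
    datasets: Sequence[ExpressionDataset],
    M: SimilarityMatrix,
    IDF: Sequence[Identifier],
    config: GAConfig,
    platforms: Mapping[str, Platform],
) -> GAResult:
    """Run the full search and return the elite model with its trajectory."""
    if not datasets:
        raise ValueError("at least one dataset is required")
    rng = np.random.default_rng(config.seed)
    evaluate = _FitnessCache(datasets, M, platforms)
    pop = init_population(IDF, config, rng, evaluate)
    history = [pop.elite.llv]
    gen = 0
    for gen in range(1, config.MG + 1):
        if pop.elite.llv >= config.TLC:
            gen -= 1
            break
        kept = roulette_select(pop, rng)
        pop = crossover_and_replace(kept, IDF, config, rng, evaluate, pop.elite)
        history.append(pop.elite.llv)
    return GAResult(
        clm=pop.elite,
        elite_history=history,
        n_generations=gen,
        n_evaluations=evaluate.n_evaluations,
    )


def exhaustive_search(
    datasets: Sequence[ExpressionDataset],
    M: SimilarityMatrix,
    IDF: Sequence[Identifier],
    k: int,
    platforms: Mapping[str, Platform],
    guard: int = EXHAUSTIVE_GUARD,
) -> CLM:
    """Evaluate every distinct-gene panel of size k; return the best model.

    Each gene is represented by its first identifier in canonical universe
    order, so the enumeration covers C(n_genes, k) panels. Ties go to the
    lexicographically smallest panel. Intended for small oracle instances;
    raises when the enumeration would exceed ``guard`` panels.
    """
    canonical: dict[str, Identifier] = {}
    for ident in IDF:
        canonical.setdefault(ident.gene_id, ident)
    genes = sorted(canonical)
    if k > len(genes):
        raise ValueError(f"k={k} exceeds {len(genes)} distinct genes")
    n_panels = count_combinations(len(genes), k)
    if n_panels > guard:
        raise ValueError(
            f"{n_panels} panels exceed the exhaustive guard ({guard}); "
            "use run_ga instead"
        )
    best: CLM | None = None
    for combo in itertools.combinations(genes, k):
        panel = tuple(canonical[g] for g in combo)
        clm = identify_clm(datasets, M, panel, platforms)
        if best is None or clm.llv > best.llv:
            best = clm
    assert best is not None
    return best
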