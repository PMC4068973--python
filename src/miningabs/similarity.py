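"""Probe-sequence similarity: the bridge that connects microarray platforms.

The similarity of two probe sequences is ``1 - d``, where ``d`` is the
two-sequence maximum-likelihood evolutionary distance clamped into
``[0, 1]``. Under the Jukes–Cantor (JC69) substitution model the ML branch
length of a two-leaf tree has the closed form

    d = -(3/4) * ln(1 - (4/3) * p)

with ``p`` the mismatch proportion over aligned (non-gap) columns. JC69 is
used because it is the simplest model with the required clamped behaviour
and because the closed form makes the implementation directly testable.

Probe sequences on different platforms have very different lengths (60-mer
spotted oligos versus 250–440 bp target regions). The pairwise alignment is
global (Needleman–Wunsch) with affine gap penalties applied to end gaps as
well: because the length difference must appear as gaps somewhere, their
cost is constant across placements and a short probe still aligns against
its best window inside a long one — but no sequence can escape into a tiny
perfect overlap, which unpenalised end gaps would allow and which would
award any two random sequences a spurious similarity of 1.0, destroying the
intra-/inter-gene discrimination the bridge relies on. The distance itself
is computed only on aligned (non-gap) columns, so the end-gap bookkeeping
never contaminates the mismatch proportion. Scoring: match +1, mismatch −1,
gap open −2, gap extend −1; ``N`` never matches anything, including another
``N``.

Saturated pairs (``p >= 0.75``, where the JC log is undefined) and pairs
with no aligned overlap get distance 1.0, i.e. similarity 0.0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align.substitution_matrices import Array as _SubstArray

from .io_formats import Platform

__all__ = [
    "AlignedPair",
    "SimilarityMatrix",
    "SimilaritySummary",
    "align_pair",
    "evolutionary_distance",
    "similarity",
    "build_similarity_matrix",
    "summarize_similarity",
]

#: mismatch proportion at which the JC69 distance saturates
JC_SATURATION = 0.75


def _make_aligner() -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    matrix = _SubstArray(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            matrix[a, b] = 1.0 if (a == b and a != "N") else -1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class AlignedPair:
    """Aligned non-gap columns of a pairwise alignment, with match counts."""

    columns: tuple[tuple[int, int], ...]
    matches: int
    mismatches: int

    @property
    def overlap(self) -> int:
        return len(self.columns)

    @property
    def mismatch_proportion(self) -> float:
        if not self.columns:
            raise ValueError("no aligned overlap")
        return self.mismatches / self.overlap


def align_pair(seq_a: str, seq_b: str) -> AlignedPair:
    """Globally align two sequences (affine gap costs, end gaps included).

    Returns the aligned non-gap column index pairs — ``(i, j)`` positions in
    ``seq_a`` and ``seq_b`` respectively — together with match and mismatch
    counts (``N`` counts as a mismatch against everything). A pair whose
    optimal alignment has no overlapping columns yields an empty ``columns``
    tuple, which downstream code treats as maximal distance.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    columns: list[tuple[int, int]] = []
    matches = 0
    for (ta, tb), (qa, qb) in zip(*aln.aligned):
        for i, j in zip(range(ta, tb), range(qa, qb)):
            columns.append((i, j))
            if seq_a[i] == seq_b[j] and seq_a[i] != "N":
                matches += 1
    return AlignedPair(
        columns=tuple(columns), matches=matches, mismatches=len(columns) - matches
    )


def jc69_distance(p: float) -> float:
    """Closed-form JC69 ML distance for mismatch proportion ``p``, clamped to [0, 1]."""
    if p >= JC_SATURATION:
        return 1.0
    d = -0.75 * np.log1p(-(4.0 / 3.0) * p)
    return float(min(max(d, 0.0), 1.0))


def evolutionary_distance(seq_a: str, seq_b: str) -> float:
    """JC69 ML distance between two probe sequences, in [0, 1].

    Computed on the aligned non-gap columns of the free-end-gap global
    alignment; no overlap or a saturated mismatch proportion gives 1.0.
    """
    aligned = align_pair(seq_a, seq_b)
    if aligned.overlap == 0:
        return 1.0
    return jc69_distance(aligned.mismatch_proportion)


def similarity(seq_a: str, seq_b: str) -> float:
    """Probe-sequence similarity ``1 - evolutionary_distance``, in [0, 1]."""
    return 1.0 - evolutionary_distance(seq_a, seq_b)


@dataclass
class SimilarityMatrix:
    """All-pairs probe similarity over the union of platform probes.

    ``index`` lists (platform_id, probe_id) pairs in canonical order;
    ``values`` is the symmetric similarity matrix with unit diagonal.
    """

    index: list[tuple[str, str]]
    values: np.ndarray
    model: str = "JC69"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.index)
        if self.values.shape != (n, n):
            raise ValueError("values shape does not match index length")
        self._pos = {key: i for i, key in enumerate(self.index)}

    def position(self, platform_id: str, probe_id: str) -> int:
        return self._pos[(platform_id, probe_id)]

    def entry(
        self, platform_a: str, probe_a: str, platform_b: str, probe_b: str
    ) -> float:
        return float(
            self.values[self.position(platform_a, probe_a),
                        self.position(platform_b, probe_b)]
        )


def build_similarity_matrix(platforms: Sequence[Platform]) -> SimilarityMatrix:
    """Compute the all-pairs similarity matrix over every probe of every platform."""
    if not platforms:
        raise ValueError("at least one platform is required")
    entries: list[tuple[str, str, str]] = []  # (platform_id, probe_id, sequence)
    for pf in platforms:
        for probe in pf.probes:
            entries.append((pf.platform_id, probe.probe_id, probe.sequence))
    n = len(entries)
    values = np.ones((n, n))
    for i, j in itertools.combinations(range(n), 2):
        s = similarity(entries[i][2], entries[j][2])
        values[i, j] = values[j, i] = s
    return SimilarityMatrix(
        index=[(pf, pid) for pf, pid, _ in entries], values=values
    )


@dataclass
class SimilaritySummary:
    """Per-probe cross-platform similarity statistics for one comparison group.

    ``intra`` compares each probe with other-platform probes that share its
    gene label, ``inter`` with other-platform probes of different genes.
    """

    group: str
    probe_keys: list[tuple[str, str]]
    max_scores: np.ndarray
    mean_scores: np.ndarray
    min_scores: np.ndarray

    @property
    def n_probes(self) -> int:
        return len(self.probe_keys)

    def averages(self) -> dict[str, float]:
        if self.n_probes == 0:
            return {"max": np.nan, "mean": np.nan, "min": np.nan}
        return {
            "max": float(self.max_scores.mean()),
            "mean": float(self.mean_scores.mean()),
            "min": float(self.min_scores.mean()),
        }


def summarize_similarity(
    M: SimilarityMatrix, platforms: Sequence[Platform]
) -> dict[str, object]:
    """Split per-probe cross-platform similarities into intra-/inter-gene groups.

    For every probe, similarities to probes on *other* platforms are collected
    and split by whether the partner shares the probe's gene label (intra) or
    not (inter); each group reports per-probe max/mean/min. Also reported:
    the fraction of gene-sharing probes whose single best cross-platform
    partner is a same-gene probe (``best_partner_same_gene_fraction``), and
    the probes whose gene appears on no other platform (``no_partner``),
    which are excluded from the intra statistics.
    """
    if len(platforms) < 2:
        raise ValueError("need at least two platforms to compare across platforms")
    gene_of: dict[tuple[str, str], str] = {}
    for pf in platforms:
        for probe in pf.probes:
            gene_of[(pf.platform_id, probe.probe_id)] = probe.gene_id

    groups: dict[str, dict[str, list]] = {
        g: {"keys": [], "max": [], "mean": [], "min": []} for g in ("intra", "inter")
    }
    no_partner: list[tuple[str, str]] = []
    n_best_same_gene = 0
    n_with_intra = 0

    for i, key in enumerate(M.index):
        pf_i, _ = key
        gene_i = gene_of[key]
        intra_scores, inter_scores = [], []
        best_j = None
        best_score = -np.inf
        for j, other in enumerate(M.index):
            if other[0] == pf_i:
                continue
            s = M.values[i, j]
            if gene_of[other] == gene_i:
                intra_scores.append(s)
            else:
                inter_scores.append(s)
            if s > best_score:
                best_score, best_j = s, j
        if intra_scores:
            n_with_intra += 1
            if best_j is not None and gene_of[M.index[best_j]] == gene_i:
                n_best_same_gene += 1
            groups["intra"]["keys"].append(key)
            groups["intra"]["max"].append(max(intra_scores))
            groups["intra"]["mean"].append(float(np.mean(intra_scores)))
            groups["intra"]["min"].append(min(intra_scores))
        else:
            no_partner.append(key)
        if inter_scores:
            groups["inter"]["keys"].append(key)
            groups["inter"]["max"].append(max(inter_scores))
            groups["inter"]["mean"].append(float(np.mean(inter_scores)))
            groups["inter"]["min"].append(min(inter_scores))

    summaries = {
        g: SimilaritySummary(
            group=g,
            probe_keys=d["keys"],
            max_scores=np.asarray(d["max"]),
            mean_scores=np.asarray(d["mean"]),
            min_scores=np.asarray(d["min"]),
        )
        for g, d in groups.items()
    }
    return {
        "intra": summaries["intra"],
        "inter": summaries["inter"],
        "no_partner": no_partner,
        "best_partner_same_gene_fraction": (
            n_best_same_gene / n_with_intra if n_with_intra else np.nan
        ),
    }
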