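"""Resolving biomarker identifiers onto a target platform.

A candidate panel is a set of ``PF-P-G`` identifiers that may name probes on
any platform. To fit a model on a particular dataset, each identifier must
be resolved to a probe of that dataset's platform:

* if the target platform carries the identifier's gene, the same-gene probe
  whose sequence is most similar to the source probe is used (``same-gene``);
* otherwise the target-platform probe with maximal similarity to the source
  probe acts as a substitute (``substitute``), on the rationale that
  hybridisation intensities track sequence similarity.

Ties are broken by the smallest canonical probe index, so resolution is
deterministic. No minimum similarity floor is imposed on substitutes: panels
bridged through poor substitutes score badly and are purged by the
downstream search, rather than being filtered up front.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_formats import Identifier, Platform
from .similarity import SimilarityMatrix

__all__ = ["ResolvedIdentifier", "resolve_identifier", "resolve_panel",
           "duplicate_targets"]


@dataclass(frozen=True)
class ResolvedIdentifier:
    source: Identifier
    target: Identifier
    mode: str  # "same-gene" | "substitute"
    similarity: float


def resolve_identifier(
    identifier: Identifier, target_platform: Platform, M: SimilarityMatrix
) -> ResolvedIdentifier:
    """Resolve one identifier onto *target_platform* via the similarity matrix."""
    if len(target_platform) == 0:
        raise ValueError("target platform has no probes")
    same_gene = [
        p for p in target_platform.probes if p.gene_id == identifier.gene_id
    ]
    candidates = same_gene if same_gene else list(target_platform.probes)
    mode = "same-gene" if same_gene else "substitute"

    best_probe = None
    best_score = -1.0
    for probe in candidates:  # canonical order => first win is smallest index
        score = M.entry(
            identifier.platform_id,
            identifier.probe_id,
            target_platform.platform_id,
            probe.probe_id,
        )
        if score > best_score:
            best_score, best_probe = score, probe
    assert best_probe is not None
    return ResolvedIdentifier(
        source=identifier,
        target=Identifier(
            target_platform.platform_id, best_probe.probe_id, best_probe.gene_id
        ),
        mode=mode,
        similarity=best_score,
    )


def resolve_panel(
    panel: Sequence[Identifier], target_platform: Platform, M: SimilarityMatrix
) -> list[ResolvedIdentifier]:
    """Resolve a whole panel element-wise, preserving order.

    Two distinct panel genes may resolve to the same substitute probe; such
    duplicates are permitted (the fit then sees a rank-deficient design) and
    can be inspected with :func:`duplicate_targets`.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    return [resolve_identifier(i, target_platform, M) for i in panel]


def duplicate_targets(resolved: Sequence[ResolvedIdentifier]) -> set[Identifier]:
    """Target identifiers appearing more than once in a resolved panel."""
    seen: set[Identifier] = set()
    dups: set[Identifier] = set()
    for r in resolved:
        if r.target in seen:
            dups.add(r.target)
        seen.add(r.target)
    return dups
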