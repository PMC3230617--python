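"""GO term over-representation of low vs high O/E gene classes (EASE score).

For each GO biological-process term, a gene class (e.g. the low CpG O/E
population) is compared with the background of all annotated genes in a 2x2
table.  The base statistic is the one-sided Fisher exact (hypergeometric
upper tail) probability of seeing at least the observed overlap.  The EASE
score is its conservative jackknifed variant: one gene is removed from the
overlap cell before computing the tail, so single-gene categories can never
score as significant.  Benjamini-Hochberg correction is applied across the
terms tested within each class.

Genes without annotations never enter any margin; a gene counts once per
term regardless of how many times the pair appears in the annotation source.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentInput",
    "EnrichmentResult",
    "fisher_exact_ge",
    "ease_score",
    "bh_adjust",
    "enrich",
]


def _check_marginals(list_hits: int, list_size: int, pop_hits: int, pop_size: int) -> None:
    if min(list_hits, list_size, pop_hits, pop_size) < 0:
        raise ValueError("marginals must be non-negative")
    if list_size > pop_size or pop_hits > pop_size:
        raise ValueError("list/term size exceeds population size")
    if list_hits > min(list_size, pop_hits):
        raise ValueError("overlap exceeds its marginals")
    if list_hits < list_size + pop_hits - pop_size:
        raise ValueError("overlap below its feasible minimum")


def fisher_exact_ge(
    list_hits: int, list_size: int, pop_hits: int, pop_size: int
) -> float:
    """One-sided over-representation probability P(X >= list_hits).

    X is hypergeometric: ``list_size`` draws without replacement from a
    population of ``pop_size`` genes of which ``pop_hits`` carry the term.
    """
    _check_marginals(list_hits, list_size, pop_hits, pop_size)
    if list_hits == 0:
        return 1.0
    return float(hypergeom.sf(list_hits - 1, pop_size, pop_hits, list_size))


def ease_score(
    list_hits: int, list_size: int, pop_hits: int, pop_size: int
) -> float:
    """EASE score: the Fisher tail with one gene jackknifed out of the overlap.

    Equal to ``fisher_exact_ge(max(list_hits - 1, 0), ...)`` with the other
    marginals unchanged; always >= the unmodified Fisher probability.
    """
    _check_marginals(list_hits, list_size, pop_hits, pop_size)
    jack = max(list_hits - 1, 0)
    if jack <= max(0, list_size + pop_hits - pop_size):
        return 1.0  # tail from (or below) the support minimum
    return float(hypergeom.sf(jack - 1, pop_size, pop_hits, list_size))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j>=i} (p_(j) * m / j) over the ascending order, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return [float(q) for q in multipletests(p, method="fdr_bh")[1]]


@dataclass(frozen=True)
class EnrichmentInput:
    """A gene class, its annotated background, and the annotation table."""

    class_genes: frozenset[str]
    background_genes: frozenset[str]
    annotations: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.background_genes:
            raise ValueError("background must be non-empty")
        if not self.class_genes <= self.background_genes:
            raise ValueError("class genes must be a subset of the background")

    @classmethod
    def from_annotations(
        cls, class_genes, annotations: Mapping[str, set[str]]
    ) -> "EnrichmentInput":
        """Build an input whose background is every annotated gene; class
        genes without annotations are dropped (they carry no testable term)."""
        ann = {g: frozenset(t) for g, t in annotations.items() if t}
        background = frozenset(ann)
        return cls(
            class_genes=frozenset(class_genes) & background,
            background_genes=background,
            annotations=ann,
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term 2x2 counts with EASE, Fisher and BH-adjusted probabilities."""

    term: str
    list_hits: int
    list_size: int
    pop_hits: int
    pop_size: int
    ease_p: float
    fisher_p: float
    bh_q: float


def enrich(
    input: EnrichmentInput, min_term_size: int = 2, top: int | None = None
) -> list[EnrichmentResult]:
    """EASE over-representation of every term against the background.

    Terms annotated to fewer than ``min_term_size`` background genes are
    skipped (the jackknife makes singleton terms uninformative anyway).  BH
    adjustment runs across all tested terms of this class.  Results are
    sorted by ascending EASE score, ties broken by term string; ``top``
    optionally trims the sorted list for presentation only.
    """
    if not input.class_genes:
        raise ValueError("empty gene class")
    term_to_genes: dict[str, set[str]] = {}
    for gene, terms in input.annotations.items():
        if gene not in input.background_genes:
            continue
        for t in terms:
            term_to_genes.setdefault(t, set()).add(gene)
    pop_size = len(input.background_genes)
    list_size = len(input.class_genes)

    tested: list[tuple[str, int, int]] = []
    for term, genes in term_to_genes.items():
        pop_hits = len(genes)
        if pop_hits < min_term_size:
            continue
        list_hits = len(genes & input.class_genes)
        tested.append((term, list_hits, pop_hits))
    if not tested:
        return []

    ease_ps = [
        ease_score(lh, list_size, ph, pop_size) for _, lh, ph in tested
    ]
    fisher_ps = [
        fisher_exact_ge(lh, list_size, ph, pop_size) for _, lh, ph in tested
    ]
    qs = bh_adjust(ease_ps)
    results = [
        EnrichmentResult(
            term=term,
            list_hits=lh,
            list_size=list_size,
            pop_hits=ph,
            pop_size=pop_size,
            ease_p=ep,
            fisher_p=fp,
            bh_q=q,
        )
        for (term, lh, ph), ep, fp, q in zip(tested, ease_ps, fisher_ps, qs)
    ]
    results.sort(key=lambda r: (r.ease_p, r.term))
    if top is not None:
        results = results[:top]
    return results
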