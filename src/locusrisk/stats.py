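"""Downstream evaluation statistics.

One-sided Fisher's exact enrichment with Bonferroni correction, binomial
overlap tests against external gene lists, a permutation test for
interactions between novel and established genes, and false-positive-rate
curves against sampled negative gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .datatypes import GeneSet, PosteriorTable

__all__ = [
    "EnrichmentResult",
    "fisher_enrichment",
    "binomial_overlap",
    "permutation_interaction_test",
    "fpr_curve",
]


@dataclass
class EnrichmentResult:
    gene_set: str
    a: int  # foreground in set
    b: int  # foreground not in set
    c: int  # background in set
    d: int  # background not in set
    odds_ratio: float
    pvalue: float
    pvalue_adj: float

    @property
    def significant(self) -> bool:
        return self.pvalue_adj < 0.05


def fisher_enrichment(
    foreground: Iterable[str], background: Iterable[str], sets: Sequence[GeneSet]
) -> list[EnrichmentResult]:
    """One-sided (greater) Fisher's exact enrichment of the foreground in each set.

    The universe is foreground + background (which must be disjoint);
    Bonferroni multiplies by the number of sets actually tested here.
    """
    fg, bg = set(foreground), set(background)
    if not fg:
        raise ValueError("empty foreground")
    if fg & bg:
        raise ValueError("foreground and background overlap")
    if not sets:
        raise ValueError("no gene sets supplied")
    results = []
    for gs in sets:
        a = len(fg & gs.genes)
        b = len(fg) - a
        c = len(bg & gs.genes)
        d = len(bg) - c
        odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
        results.append(
            EnrichmentResult(
                gene_set=gs.name, a=a, b=b, c=c, d=d,
                odds_ratio=float(odds), pvalue=float(p),
                pvalue_adj=min(1.0, float(p) * len(sets)),
            )
        )
    return results


def binomial_overlap(k: int, n_predicted: int, set_size: int, universe: int) -> float:
    """Upper-tail binomial p for observing >= k hits among n_predicted picks.

    Success probability is set_size / universe, the chance a random gene
    falls in the external set.
    """
    if k > n_predicted:
        raise ValueError("overlap cannot exceed the number of predicted genes")
    if universe < set_size:
        raise ValueError("universe smaller than the gene set")
    if k == 0:
        return 1.0
    prob = set_size / universe
    return float(sps.binom.sf(k - 1, n_predicted, prob))


def permutation_interaction_test(
    novel: Sequence[str],
    non_novel: Sequence[str],
    interaction_fn: Callable[[str, str], int],
    universe: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
    exact: bool = False,
) -> tuple[int, float]:
    """Permutation test for novel-to-established gene interactions.

    The observed statistic counts interacting (novel, non-novel) pairs. The
    null redraws |novel| genes uniformly without replacement from the
    universe minus both gene lists and recounts. The empirical p uses the
    add-one estimator (1 + #{null >= observed}) / (n_perm + 1), so it is
    never exactly zero. With ``exact=True`` every complement subset is
    enumerated instead and p = #{null >= observed} / #subsets.
    """
    novel = list(dict.fromkeys(novel))
    non_novel = list(dict.fromkeys(non_novel))
    pool = sorted(set(universe) - set(novel) - set(non_novel))
    if len(pool) < len(novel):
        raise ValueError("universe too small to sample the null from")
    observed = sum(interaction_fn(a, b) for a in novel for b in non_novel)
    if exact:
        from itertools import combinations

        total = exceed = 0
        for draw in combinations(pool, len(novel)):
            stat = sum(interaction_fn(a, b) for a in draw for b in non_novel)
            total += 1
            exceed += stat >= observed
        return observed, exceed / total
    rng = np.random.default_rng(seed)
    pool_arr = np.array(pool)
    exceed = 0
    for _ in range(n_perm):
        draw = rng.choice(pool_arr, size=len(novel), replace=False)
        stat = sum(interaction_fn(a, b) for a in draw for b in non_novel)
        if stat >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return observed, float(p)


def fpr_curve(
    table: PosteriorTable,
    negative_sets: Sequence[frozenset[str] | set[str]],
    top_ranks: Sequence[int] = (1, 2, 3, 4, 5, 6),
) -> dict[int, list[float]]:
    """False-positive rate of top-t per-locus predictions against negative sets.

    For rank t, the prediction is the union over loci of each locus's top-t
    candidates by PP (symbol tie-break); FPR = |prediction ∩ negative| /
    |prediction|, one value per negative set. Empty predictions are
    reported as NaN.
    """
    ranked_per_locus = {
        li: [g for g, _ in sorted(pps.items(), key=lambda kv: (-kv[1], kv[0]))]
        for li, pps in table.per_locus.items()
    }
    out: dict[int, list[float]] = {}
    for t in top_ranks:
        predicted: set[str] = set()
        for ranked in ranked_per_locus.values():
            predicted.update(ranked[:t])
        if not predicted:
            out[t] = [float("nan")] * len(negative_sets)
            continue
        out[t] = [len(predicted & set(neg)) / len(predicted) for neg in negative_sets]
    return out
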