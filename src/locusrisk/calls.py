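"""Calling high-risk genes (HRGs) and low-risk background genes (LBGs).

The HRG of a locus is its candidate with the highest posterior probability.
LBGs are genes whose merged PP falls strictly below the median merged PP of
all candidate genes. When a gene would carry both labels (possible once
many loci are merged), the HRG label wins and the collision is logged.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .datatypes import PosteriorTable

logger = logging.getLogger(__name__)

__all__ = ["call_hrgs", "call_lbgs", "top_fraction", "annotate_labels"]


def call_hrgs(table: PosteriorTable) -> dict[int, str]:
    """Per locus, the candidate with maximal per-locus PP (symbol tie-break)."""
    hrgs: dict[int, str] = {}
    for li, pps in table.per_locus.items():
        if not pps:
            logger.warning("locus %d is empty; skipped", li)
            continue
        best = min(pps.items(), key=lambda kv: (-kv[1], kv[0]))
        ties = [g for g, pp in pps.items() if pp == best[1]]
        if len(ties) > 1:
            logger.info("locus %d: PP tie among %s; chose %s", li, sorted(ties), best[0])
        hrgs[li] = best[0]
    return hrgs


def call_lbgs(table: PosteriorTable) -> set[str]:
    """Genes with merged PP strictly below the median merged PP of all genes."""
    if not table.merged:
        return set()
    values = np.fromiter(table.merged.values(), dtype=float)
    median = float(np.median(values))
    return {g for g, pp in table.merged.items() if pp < median}


def top_fraction(table: PosteriorTable, fraction: float = 0.10) -> list[str]:
    """The ceil(fraction * g) genes with the highest merged PP, stably ordered."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = math.ceil(fraction * len(table.merged))
    ranked = sorted(table.merged.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in ranked[:n]]


def annotate_labels(table: PosteriorTable) -> PosteriorTable:
    """Attach HRG/LBG/other labels to the table in place (HRG wins collisions)."""
    hrg_genes = set(call_hrgs(table).values())
    lbg_genes = call_lbgs(table)
    clash = hrg_genes & lbg_genes
    if clash:
        logger.warning("%d gene(s) met both HRG and LBG rules; HRG label kept: %s",
                       len(clash), sorted(clash)[:5])
    table.labels = {}
    for g in table.merged:
        if g in hrg_genes:
            table.labels[g] = "HRG"
        elif g in lbg_genes:
            table.labels[g] = "LBG"
        else:
            table.labels[g] = "other"
    return table
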