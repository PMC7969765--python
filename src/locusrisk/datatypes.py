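"""Shared domain types.

Coordinate conventions: gene intervals are 0-based half-open (BED);
SNP positions are 1-based (VCF). All internal distance arithmetic
converts the SNP position to 0-based before comparing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "IndexSNP",
    "GeneRecord",
    "Locus",
    "LocusMap",
    "FeatureBundle",
    "GeneNetwork",
    "EvidenceScores",
    "PosteriorTable",
    "GeneSet",
    "ValidationError",
    "FormatError",
]

P_FLOOR = 1e-300  # clamp floor keeping -log(p) finite


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class FormatError(ValueError):
    """Input file does not match the expected layout."""


@dataclass(frozen=True)
class IndexSNP:
    """A lead GWAS SNP defining a locus. Position is 1-based."""

    snp_id: str
    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"SNP {self.snp_id}: position must be >= 1, got {self.position}"
            )


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval, 0-based half-open, with optional strand."""

    symbol: str
    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.symbol}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"gene {self.symbol}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class Locus:
    """An index SNP together with its candidate gene symbols (ordered)."""

    snp: IndexSNP
    candidates: tuple[str, ...]

    @property
    def is_empty(self) -> bool:
        return len(self.candidates) == 0


@dataclass
class LocusMap:
    """Ordered loci with their candidate sets; order is fixed and reproducible."""

    loci: list[Locus]
    window_bp: int = 1_000_000

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    @property
    def nonempty(self) -> list[Locus]:
        return [l for l in self.loci if not l.is_empty]

    def all_candidates(self) -> list[str]:
        """Union of candidate symbols over loci, in first-seen order."""
        seen: dict[str, None] = {}
        for locus in self.loci:
            for g in locus.candidates:
                seen.setdefault(g)
        return list(seen)


@dataclass
class FeatureBundle:
    """Per-gene features split into a p-value category and a continuous category.

    ``pvalues`` is g x n' with entries in [P_FLOOR, 1]; ``continuous`` is the
    g x m matrix fed to the decorrelating (Hotelling) transform. Row order of
    both frames matches ``genes``.
    """

    genes: list[str]
    pvalues: pd.DataFrame
    continuous: pd.DataFrame

    def __post_init__(self) -> None:
        for name, frame in (("pvalues", self.pvalues), ("continuous", self.continuous)):
            if list(frame.index) != list(self.genes):
                raise ValidationError(f"{name} row order does not match genes")
            if frame.shape[1] and frame.isna().any().any():
                raise ValidationError(f"{name} contains NaN after imputation")
        pv = self.pvalues.to_numpy()
        if pv.size and (pv.min() < P_FLOOR or pv.max() > 1.0):
            raise ValidationError("p-value features outside [1e-300, 1]")

    @property
    def n_pvalue_features(self) -> int:
        return self.pvalues.shape[1]

    @property
    def n_continuous_features(self) -> int:
        return self.continuous.shape[1]


@dataclass
class GeneNetwork:
    """A weighted undirected gene graph (no self-loops on input)."""

    name: str
    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v, w in self.graph.edges(data="weight", default=1.0):
            if u == v:
                raise ValidationError(f"network {self.name}: self-loop on {u}")
            if not np.isfinite(w) or w < 0:
                raise ValidationError(
                    f"network {self.name}: bad weight {w!r} on edge {u}-{v}"
                )

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


@dataclass
class EvidenceScores:
    """Per-gene combined evidence, the -ln of the Fisher-combined p-value."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        for g, s in self.scores.items():
            if not np.isfinite(s) or s < 0:
                raise ValidationError(f"evidence for {g} must be finite and >= 0")

    def __getitem__(self, gene: str) -> float:
        return self.scores[gene]

    def get(self, gene: str, default: float = 0.0) -> float:
        return self.scores.get(gene, default)


@dataclass
class PosteriorTable:
    """Posterior selection probabilities per gene, per locus and merged.

    ``per_locus`` maps locus index -> {gene: PP}; within a locus the PPs sum
    to one. ``merged`` maps gene -> max PP over its loci. Labels are assigned
    by the calling layer (HRG/LBG/other).
    """

    per_locus: dict[int, dict[str, float]]
    merged: dict[str, float]
    labels: dict[str, str] = field(default_factory=dict)
    freq_trace: list[np.ndarray] = field(default_factory=list)
    sweeps: tuple[int, int] = (0, 0)
    converged: tuple[bool, bool] = (True, True)

    def locus_pp(self, locus_index: int) -> dict[str, float]:
        return self.per_locus[locus_index]

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: one row per (locus, gene) with PP and rank."""
        rows = []
        for li in sorted(self.per_locus):
            pps = self.per_locus[li]
            ranked = sorted(pps.items(), key=lambda kv: (-kv[1], kv[0]))
            for rank, (gene, pp) in enumerate(ranked, start=1):
                rows.append(
                    {
                        "gene": gene,
                        "locus": li,
                        "pp": pp,
                        "label": self.labels.get(gene, "other"),
                        "rank_in_locus": rank,
                    }
                )
        return pd.DataFrame(rows, columns=["gene", "locus", "pp", "label", "rank_in_locus"])


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (GMT record)."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes
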