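"""Synthetic benchmark instances with known ground truth.

Generates the statistical structure the model assumes: loci with a fixed
number of candidate genes each, one planted risk gene per locus whose
p-value features are enriched near zero (Beta(a, 1) with a < 1) and whose
continuous features are mean-shifted, plus two gene networks — one
block-structured in which the planted genes form a dense module, and one
pure-noise network — so multi-network combination is exercised. Everything
is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    P_FLOOR,
    FeatureBundle,
    GeneNetwork,
    GeneRecord,
    IndexSNP,
    Locus,
    LocusMap,
    PosteriorTable,
)

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_instance", "score_recovery", "write_instance"]

_LOCUS_SPACING = 10_000_000  # bp between index SNPs: windows never overlap
_GENE_LENGTH = 10_000


@dataclass
class SyntheticConfig:
    """Generation parameters; defaults are the benchmark's study conditions."""

    n_loci: int = 20
    candidates_per_locus: int = 10
    planted_effect: float = 0.0  # continuous mean shift, in sd units
    pvalue_signal: float = 1.0  # Beta(a, 1) a for planted p-values; a=1 is null
    module_within_weight: float = 0.05  # edge prob inside the planted module
    background_weight: float = 0.05  # edge prob elsewhere
    n_pvalue_features: int = 3
    n_continuous_features: int = 4
    window_bp: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.candidates_per_locus < 1:
            raise ValueError("need >= 1 locus and >= 1 candidate per locus")
        for name in ("module_within_weight", "background_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.pvalue_signal <= 1.0:
            raise ValueError("pvalue_signal must be in (0, 1]")
        if self.planted_effect < 0:
            raise ValueError("planted_effect must be >= 0")
        span = (self.candidates_per_locus - 1) * self._gene_spacing() + _GENE_LENGTH
        if span > 2 * self.window_bp:
            raise ValueError("window too small for the requested candidate count")

    def _gene_spacing(self) -> int:
        return max(_GENE_LENGTH + 1, (2 * self.window_bp - _GENE_LENGTH) // max(self.candidates_per_locus, 1))


@dataclass
class SyntheticTruth:
    """Planted risk gene per locus, plus an echo of the generating config."""

    planted: dict[int, str]
    config: SyntheticConfig = field(repr=False, default=None)


def generate_instance(
    config: SyntheticConfig,
) -> tuple[LocusMap, FeatureBundle, list[GeneNetwork], SyntheticTruth]:
    """Generate one synthetic instance with known planted risk genes."""
    rng = np.random.default_rng(config.seed)
    k = config.candidates_per_locus
    spacing = config._gene_spacing()

    snps: list[IndexSNP] = []
    genes: list[GeneRecord] = []
    loci: list[Locus] = []
    planted: dict[int, str] = {}
    for li in range(config.n_loci):
        center = (li + 1) * _LOCUS_SPACING  # 1-based SNP position
        snps.append(IndexSNP(f"rs{li + 1}", "chr1", center))
        cands = []
        first = (center - 1) - ((k - 1) * spacing) // 2
        for ci in range(k):
            sym = f"G{li:03d}_{ci:02d}"
            start = first + ci * spacing
            genes.append(GeneRecord(sym, "chr1", start, start + _GENE_LENGTH, "+"))
            cands.append(sym)
        planted_idx = int(rng.integers(k))
        planted[li] = cands[planted_idx]
        loci.append(Locus(snps[-1], tuple(cands)))
    locus_map = LocusMap(loci=loci, window_bp=config.window_bp)
    all_genes = [g.symbol for g in genes]
    g = len(all_genes)
    planted_set = set(planted.values())
    is_planted = np.array([sym in planted_set for sym in all_genes])

    # p-value features: Uniform(0,1) background, Beta(a,1) for planted genes
    pv = rng.uniform(size=(g, config.n_pvalue_features))
    if config.n_pvalue_features:
        pv[is_planted] = rng.beta(
            config.pvalue_signal, 1.0, size=(int(is_planted.sum()), config.n_pvalue_features)
        )
    pv = np.clip(pv, P_FLOOR, 1.0)

    # continuous features: standard normal, planted genes mean-shifted
    cont = rng.normal(size=(g, config.n_continuous_features))
    cont[is_planted] += config.planted_effect

    bundle = FeatureBundle(
        genes=all_genes,
        pvalues=pd.DataFrame(
            pv, index=all_genes,
            columns=[f"pval_{j}" for j in range(config.n_pvalue_features)],
        ),
        continuous=pd.DataFrame(
            cont, index=all_genes,
            columns=[f"cont_{j}" for j in range(config.n_continuous_features)],
        ),
    )

    networks = [
        _planted_partition(all_genes, is_planted, config, rng, name="module"),
        _noise_network(all_genes, config.background_weight, rng, name="noise"),
    ]
    truth = SyntheticTruth(planted=planted, config=config)
    return locus_map, bundle, networks, truth


def _planted_partition(genes, is_planted, config: SyntheticConfig, rng, name: str) -> GeneNetwork:
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            p = (
                config.module_within_weight
                if is_planted[i] and is_planted[j]
                else config.background_weight
            )
            if rng.random() < p:
                graph.add_edge(genes[i], genes[j], weight=1.0)
    return GeneNetwork(name=name, graph=graph)


def _noise_network(genes, density: float, rng, name: str) -> GeneNetwork:
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                graph.add_edge(genes[i], genes[j], weight=1.0)
    return GeneNetwork(name=name, graph=graph)


def score_recovery(truth: SyntheticTruth, table: PosteriorTable) -> float:
    """Fraction of loci whose called HRG equals the planted gene."""
    from .calls import call_hrgs

    hrgs = call_hrgs(table)
    hits = 0
    for li, gene in truth.planted.items():
        if li not in hrgs:
            raise ValueError(f"locus {li} missing from the posterior table")
        hits += hrgs[li] == gene
    return hits / len(truth.planted)


def write_instance(
    locus_map: LocusMap,
    bundle: FeatureBundle,
    networks: list[GeneNetwork],
    truth: SyntheticTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write an instance to TSV/BED files consumable by the run pipeline."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["loci"] = out / "loci.tsv"
    with paths["loci"].open("w") as fh:
        fh.write("snp_id\tchrom\tpos\n")
        for locus in locus_map:
            s = locus.snp
            fh.write(f"{s.snp_id}\t{s.chromosome}\t{s.position}\n")

    paths["genes"] = out / "genes.bed"
    gene_coords: dict[str, GeneRecord] = {}
    # candidate coordinates are reconstructible from the locus layout; regenerate
    cfg = truth.config
    spacing = cfg._gene_spacing()
    with paths["genes"].open("w") as fh:
        for li, locus in enumerate(locus_map):
            center = locus.snp.position
            first = (center - 1) - ((len(locus.candidates) - 1) * spacing) // 2
            for ci, sym in enumerate(locus.candidates):
                start = first + ci * spacing
                fh.write(f"{locus.snp.chromosome}\t{start}\t{start + _GENE_LENGTH}\t{sym}\t0\t+\n")

    paths["features"] = out / "features.tsv"
    feat = pd.concat([bundle.pvalues, bundle.continuous], axis=1)
    feat.insert(0, "gene", bundle.genes)
    feat.to_csv(paths["features"], sep="\t", index=False)

    for net in networks:
        p = out / f"net_{net.name}.tsv"
        paths[f"net_{net.name}"] = p
        with p.open("w") as fh:
            for u, v, w in net.graph.edges(data="weight", default=1.0):
                fh.write(f"{u}\t{v}\t{w}\n")

    paths["truth"] = out / "truth.tsv"
    with paths["truth"].open("w") as fh:
        fh.write("locus\tplanted_gene\n")
        for li in sorted(truth.planted):
            fh.write(f"{li}\t{truth.planted[li]}\n")
    return paths
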