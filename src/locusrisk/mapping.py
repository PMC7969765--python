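"""Candidate-gene assignment around GWAS index SNPs.

A gene is a candidate of a locus when its interval intersects the closed
window [pos - W, pos + W] centred on the index SNP (W defaults to 1 Mb per
side, i.e. a 2 Mb window). Genes are BED 0-based half-open; SNP positions
are 1-based and converted to 0-based before any comparison.
"""

from __future__ import annotations

import logging

from .datatypes import GeneRecord, IndexSNP, Locus, LocusMap

logger = logging.getLogger(__name__)

__all__ = [
    "assign_candidates",
    "gene_locus_multiplicity",
    "distance_to_snp",
    "nearest_gene",
]


def _norm_chrom(chrom: str) -> str:
    c = chrom.strip().lower()
    return c[3:] if c.startswith("chr") else c


def _intersects_window(gene: GeneRecord, snp_pos0: int, window_bp: int) -> bool:
    # gene occupies [start, end); closed window [pos0 - W, pos0 + W]
    lo, hi = snp_pos0 - window_bp, snp_pos0 + window_bp
    return gene.start <= hi and gene.end - 1 >= lo


def assign_candidates(
    snps: list[IndexSNP],
    genes: list[GeneRecord],
    window_bp: int = 1_000_000,
) -> LocusMap:
    """Build a LocusMap: one locus per SNP, candidates by window intersection.

    Loci with zero candidates are retained (and logged) so locus counts stay
    aligned with the input SNP table. A gene may be a candidate of several
    overlapping loci.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(_norm_chrom(g.chromosome), []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.start, g.end, g.symbol))

    loci: list[Locus] = []
    for snp in snps:
        chrom = _norm_chrom(snp.chromosome)
        pos0 = snp.position - 1
        if chrom not in by_chrom:
            logger.warning("SNP %s: chromosome %s has no genes; empty locus", snp.snp_id, snp.chromosome)
            loci.append(Locus(snp, ()))
            continue
        cands = tuple(
            g.symbol for g in by_chrom[chrom] if _intersects_window(g, pos0, window_bp)
        )
        if not cands:
            logger.warning("SNP %s: no genes within +/-%d bp", snp.snp_id, window_bp)
        loci.append(Locus(snp, cands))
    return LocusMap(loci=loci, window_bp=window_bp)


def gene_locus_multiplicity(locus_map: LocusMap) -> dict[str, list[int]]:
    """Map each candidate gene to the indices of the loci it belongs to."""
    out: dict[str, list[int]] = {}
    for i, locus in enumerate(locus_map):
        for g in locus.candidates:
            out.setdefault(g, []).append(i)
    return out


def distance_to_snp(gene: GeneRecord, snp: IndexSNP, mode: str = "interval") -> int:
    """Base-pair distance from an index SNP to a gene.

    mode="interval": 0 when the SNP falls inside the gene body, otherwise the
    distance to the nearer interval end. mode="tss": distance to the
    strand-aware transcription start (gene start on +/unknown strand, end-1
    on -).
    """
    if _norm_chrom(gene.chromosome) != _norm_chrom(snp.chromosome):
        raise ValueError(
            f"gene {gene.symbol} ({gene.chromosome}) and SNP {snp.snp_id} "
            f"({snp.chromosome}) are on different chromosomes"
        )
    pos0 = snp.position - 1
    if mode == "tss":
        tss = gene.end - 1 if gene.strand == "-" else gene.start
        return abs(pos0 - tss)
    if mode != "interval":
        raise ValueError(f"unknown distance mode {mode!r}")
    if gene.start <= pos0 < gene.end:
        return 0
    # distance to the nearer interval coordinate (start or half-open end)
    if pos0 < gene.start:
        return gene.start - pos0
    return pos0 - gene.end


def nearest_gene(
    locus_candidates: list[GeneRecord], snp: IndexSNP, mode: str = "interval"
) -> GeneRecord:
    """The candidate nearest the index SNP; ties broken by symbol."""
    if not locus_candidates:
        raise ValueError("no candidates at locus")
    return min(
        locus_candidates, key=lambda g: (distance_to_snp(g, snp, mode=mode), g.symbol)
    )
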