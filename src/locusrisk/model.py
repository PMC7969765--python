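"""Model/Results surface for risk-gene prioritization.

`RiskGeneModel` holds the data (loci, per-gene features, networks) and the
run configuration; `fit()` integrates the multi-omics evidence, runs the
two-cycle Gibbs sampler and returns a `RiskGeneResults` carrying posterior
probabilities, HRG/LBG calls, convergence diagnostics and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .calls import annotate_labels, call_hrgs, call_lbgs, top_fraction
from .config import RunConfig
from .datatypes import (
    EvidenceScores,
    FeatureBundle,
    GeneNetwork,
    GeneRecord,
    LocusMap,
    PosteriorTable,
)
from .evidence import compute_evidence
from .gibbs import run_gibbs
from .mapping import assign_candidates, distance_to_snp, nearest_gene

__all__ = ["RiskGeneModel", "RiskGeneResults"]


class RiskGeneModel:
    """Bayesian risk-gene prioritization over GWAS loci.

    Parameters
    ----------
    locus_map : loci with their candidate genes.
    features : per-gene p-value and continuous feature matrices.
    networks : weighted gene networks supplying the RWR prior.
    genes : optional gene coordinate records (enables distance reporting).
    config : run configuration; defaults are the documented tool defaults.
    """

    def __init__(
        self,
        locus_map: LocusMap,
        features: FeatureBundle,
        networks: list[GeneNetwork] | None = None,
        genes: list[GeneRecord] | None = None,
        config: RunConfig | None = None,
    ) -> None:
        self.locus_map = locus_map
        self.features = features
        self.networks = networks or []
        self.config = config or RunConfig()
        self.gene_records = {g.symbol: g for g in (genes or [])}
        missing = [g for g in locus_map.all_candidates() if g not in features.genes]
        if missing:
            raise ValueError(
                f"{len(missing)} candidate gene(s) lack feature rows, e.g. {missing[:3]}"
            )

    @classmethod
    def from_files(
        cls,
        loci_path: str | Path,
        genes_path: str | Path,
        features_path: str | Path,
        network_paths: list[str | Path],
        config: RunConfig,
        network_dialect: str = "generic",
    ) -> "RiskGeneModel":
        """Build a model from the standard input files (TSV/BED/edge lists)."""
        snps = lio.read_index_snps(loci_path)
        genes = lio.read_gene_bed(genes_path)
        locus_map = assign_candidates(snps, genes, window_bp=config.window_bp)
        candidates = set(locus_map.all_candidates())
        bundle = lio.read_feature_table(
            features_path, config.pvalue_columns, config.continuous_columns
        )
        # keep only genes that are candidates somewhere, preserving file order
        keep = [g for g in bundle.genes if g in candidates]
        bundle = FeatureBundle(
            genes=keep,
            pvalues=bundle.pvalues.loc[keep],
            continuous=bundle.continuous.loc[keep],
        )
        networks = [lio.read_network(p, dialect=network_dialect) for p in network_paths]
        return cls(locus_map, bundle, networks, genes=genes, config=config)

    def compute_evidence(self) -> EvidenceScores:
        """Integrate the feature bundle into per-gene evidence scores."""
        return compute_evidence(
            self.features,
            n_components=self.config.n_components,
            tail=self.config.tail,
            boxcox_interval=self.config.boxcox_interval,
        )

    def fit(self, seed: int | None = None) -> "RiskGeneResults":
        """Run evidence integration and the Gibbs sampler; return results."""
        cfg = self.config
        sampler_cfg = cfg.sampler()
        if seed is not None:
            sampler_cfg.seed = seed
        evidence = self.compute_evidence()
        table = run_gibbs(self.locus_map, evidence, self.networks, sampler_cfg)
        annotate_labels(table)
        return RiskGeneResults(model=self, evidence=evidence, posterior=table,
                               seed=sampler_cfg.seed)


@dataclass
class RiskGeneResults:
    """Fit artifacts: evidence scores, posterior table, calls and diagnostics."""

    model: RiskGeneModel
    evidence: EvidenceScores
    posterior: PosteriorTable
    seed: int
    _hrgs: dict[int, str] | None = field(default=None, repr=False)

    @property
    def hrgs(self) -> dict[int, str]:
        """Locus index -> called high-risk gene."""
        if self._hrgs is None:
            self._hrgs = call_hrgs(self.posterior)
        return self._hrgs

    @property
    def hrg_genes(self) -> set[str]:
        return set(self.hrgs.values())

    @property
    def lbgs(self) -> set[str]:
        return call_lbgs(self.posterior)

    def top_fraction(self, fraction: float | None = None) -> list[str]:
        return top_fraction(
            self.posterior, fraction or self.model.config.top_fraction
        )

    @property
    def converged(self) -> bool:
        return all(self.posterior.converged)

    def hrg_frame(self) -> pd.DataFrame:
        """Per-locus HRG report with nearest-gene flag and SNP distance."""
        rows = []
        records = self.model.gene_records
        for li, gene in sorted(self.hrgs.items()):
            locus = self.model.locus_map.loci[li]
            row = {
                "locus": li,
                "snp": locus.snp.snp_id,
                "gene": gene,
                "pp": self.posterior.per_locus[li][gene],
            }
            cand_records = [records[g] for g in locus.candidates if g in records]
            if gene in records and cand_records:
                row["distance_bp"] = distance_to_snp(
                    records[gene], locus.snp, mode=self.model.config.distance_mode
                )
                row["is_nearest_gene"] = (
                    nearest_gene(cand_records, locus.snp,
                                 mode=self.model.config.distance_mode).symbol == gene
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary."""
        t = self.posterior
        n_loci = len(t.per_locus)
        g = len(t.merged)
        pps = np.array([t.per_locus[li][h] for li, h in self.hrgs.items()])
        lines = [
            "Risk-gene prioritization results",
            "=" * 40,
            f"loci (non-empty):        {n_loci}",
            f"candidate genes:         {g}",
            f"networks:                {len(self.model.networks)}",
            f"seed:                    {self.seed}",
            f"sweeps (cycle1, cycle2): {t.sweeps}",
            f"converged:               {self.converged}",
            f"HRGs called:             {len(self.hrg_genes)}",
            f"LBGs called:             {len(self.lbgs)}",
            f"median HRG PP:           {np.median(pps):.3f}",
            f"mean HRG PP:             {pps.mean():.3f}",
        ]
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Write posterior.tsv, hrgs.tsv, lbgs.tsv and ranked.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"posterior": out / "posterior.tsv"}
        lio.write_posterior_table(self.posterior, paths["posterior"])
        paths["hrgs"] = out / "hrgs.tsv"
        self.hrg_frame().to_csv(paths["hrgs"], sep="\t", index=False)
        paths["lbgs"] = out / "lbgs.tsv"
        pd.DataFrame({"gene": sorted(self.lbgs)}).assign(
            pp=lambda d: d["gene"].map(self.posterior.merged)
        ).to_csv(paths["lbgs"], sep="\t", index=False)
        paths["ranked"] = out / "ranked.tsv"
        ranked = self.top_fraction(1.0)
        pd.DataFrame(
            {"gene": ranked, "pp": [self.posterior.merged[g] for g in ranked]}
        ).to_csv(paths["ranked"], sep="\t", index=False)
        return paths
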