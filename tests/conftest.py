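import numpy as np
import pandas as pd
import pytest

from locusrisk.datatypes import (
    FeatureBundle,
    GeneNetwork,
    GeneRecord,
    IndexSNP,
    Locus,
    LocusMap,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_bundle(genes, pvalues, continuous, rng=None):
    """Assemble a FeatureBundle from raw arrays."""
    pv = np.atleast_2d(np.asarray(pvalues, dtype=float))
    ct = np.atleast_2d(np.asarray(continuous, dtype=float))
    return FeatureBundle(
        genes=list(genes),
        pvalues=pd.DataFrame(pv, index=list(genes),
                             columns=[f"p{j}" for j in range(pv.shape[1])]),
        continuous=pd.DataFrame(ct, index=list(genes),
                                columns=[f"c{j}" for j in range(ct.shape[1])]),
    )


def make_locus_map(candidate_lists, spacing=10_000_000):
    """LocusMap with the given candidate symbol lists; coordinates synthetic."""
    loci = []
    for i, cands in enumerate(candidate_lists):
        snp = IndexSNP(f"rs{i}", "chr1", (i + 1) * spacing)
        loci.append(Locus(snp, tuple(cands)))
    return LocusMap(loci=loci)


def make_network(edges, name="net", nodes=()):
    """GeneNetwork from (u, v, w) triples."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return GeneNetwork(name=name, graph=g)


@pytest.fixture
def gene_records():
    return [
        GeneRecord("GENE1", "chr1", 100, 200, "+"),
        GeneRecord("GENE2", "chr1", 3_999_999, 4_000_050, "-"),
        GeneRecord("GENE3", "chr1", 6_000_000, 6_000_100, "+"),
    ]
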