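"""Average amino-acid identity (AAI) networks between prophages.

AAI between two prophages is the mean percent identity over their
reciprocal-best-hit protein pairs; prophage pairs at AAI >= 80 are
treated as related at about the genus level.  The module builds the
thresholded relatedness network, reports how often related prophages sit
in hosts that differ at each taxonomic rank, counts shared orthologs
across host phyla, and quantifies how congruent prophage AAI structure
is with host ANI structure within one host genus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .catalog import RANKS, TaxonomyLineage
from .seqcompare import OrfSet, ani, rbh_orthologs

__all__ = [
    "AAINetwork",
    "aai_pair",
    "build_network",
    "fraction_by_rank",
    "shared_ortholog_summary",
    "ani_aai_costructure",
]


@dataclass
class AAINetwork:
    """Thresholded AAI relatedness network.

    Nodes are prophage ids carrying their host lineage; edges carry
    ``aai`` (percent) and ``n_orthologs``.
    """

    graph: nx.Graph
    threshold: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [{"prophage_a": a, "prophage_b": b,
                 "aai": d["aai"], "n_orthologs": d["n_orthologs"]}
                for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows,
                            columns=["prophage_a", "prophage_b", "aai",
                                     "n_orthologs"])


def aai_pair(orfs_a: OrfSet, orfs_b: OrfSet,
             min_identity: float = 0.30,
             min_coverage: float = 0.70) -> tuple[Optional[float], int]:
    """AAI (percent) and ortholog count between two ORF sets.

    AAI is the mean identity over reciprocal-best-hit pairs passing the
    homology filters; (None, 0) when no pair qualifies.
    """
    pairs = rbh_orthologs(orfs_a, orfs_b, min_identity, min_coverage)
    if not pairs:
        return None, 0
    return 100.0 * float(np.mean([ident for _, _, ident in pairs])), len(pairs)


def build_network(
    orfsets: dict[str, OrfSet],
    lineages: dict[str, TaxonomyLineage],
    threshold: float = 80.0,
    restrict_to_connected: bool = True,
) -> AAINetwork:
    """All-vs-all AAI over the given prophages, kept at >= ``threshold``.

    By default only prophages with at least one retained edge appear as
    nodes (the "related set"); with ``restrict_to_connected=False`` every
    input prophage is a node, isolated or not.
    """
    ids = sorted(orfsets)
    if len(ids) < 2:
        raise ValueError("need at least 2 prophages to build a network")
    g = nx.Graph()
    if not restrict_to_connected:
        for pid in ids:
            g.add_node(pid, lineage=lineages.get(pid))
    for a, b in itertools.combinations(ids, 2):
        aai, n_orth = aai_pair(orfsets[a], orfsets[b])
        if aai is not None and aai >= threshold:
            g.add_node(a, lineage=lineages.get(a))
            g.add_node(b, lineage=lineages.get(b))
            g.add_edge(a, b, aai=aai, n_orthologs=n_orth)
    return AAINetwork(g, threshold)


def fraction_by_rank(network: AAINetwork) -> pd.DataFrame:
    """Per rank, the fraction of edges whose endpoint hosts differ there.

    Under a nested taxonomy the differ-at fractions are non-increasing
    from genus to phylum (hosts differing at the phylum necessarily
    differ at the genus).  Also reports the complementary same-rank
    fractions.
    """
    edges = list(network.graph.edges())
    if not edges:
        raise ValueError("network has no edges")
    ranks_out = [r.rstrip("_") for r in RANKS]
    rows = []
    for rank, label in zip(RANKS, ranks_out):
        differ = 0
        for a, b in edges:
            lin_a = network.graph.nodes[a]["lineage"]
            lin_b = network.graph.nodes[b]["lineage"]
            if lin_a is None or lin_b is None:
                raise ValueError("every node needs a host lineage")
            if getattr(lin_a, rank) != getattr(lin_b, rank):
                differ += 1
        rows.append({"rank": label,
                     "fraction_different": differ / len(edges),
                     "fraction_same": 1 - differ / len(edges)})
    return pd.DataFrame(rows)


def shared_ortholog_summary(network: AAINetwork, phylum_a: str,
                            phylum_b: str) -> Optional[float]:
    """Mean ortholog count (2 dp) over edges connecting the two phyla;
    None when no such edge exists."""
    counts = []
    for a, b, data in network.graph.edges(data=True):
        pa = network.graph.nodes[a]["lineage"].phylum
        pb = network.graph.nodes[b]["lineage"].phylum
        if {pa, pb} == {phylum_a, phylum_b}:
            counts.append(data["n_orthologs"])
    if not counts:
        return None
    return round(float(np.mean(counts)), 2)


def _similarity_to_flat_clusters(ids: Sequence[str], sim: np.ndarray,
                                 cut_height: float) -> dict[str, int]:
    """Average-linkage flat clusters of a percent-similarity matrix,
    cut at ``cut_height`` on the 1 - similarity/100 distance scale."""
    dist = 1.0 - sim / 100.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    condensed = squareform(dist, checks=False)
    labels = fcluster(linkage(condensed, method="average"),
                      t=cut_height, criterion="distance")
    return dict(zip(ids, labels.tolist()))


def ani_aai_costructure(
    host_sequences: dict[str, str],
    prophage_orfsets: dict[str, OrfSet],
    host_of: dict[str, str],
    ani_cut: float = 0.05,
    aai_cut: float = 0.20,
    fragment_bp: int = 1000,
) -> dict:
    """Congruence between host ANI structure and prophage AAI structure.

    For hosts of one genus and their prophages: builds the host ANI
    matrix and the prophage AAI matrix, clusters both (average linkage,
    cut at the stated heights on the 1 - similarity scale), and scores
    congruence as the fraction of prophage pairs whose AAI-cluster
    comembership matches their hosts' ANI-cluster comembership.  Pairs
    with no defined ANI/AAI contribute 0 similarity.
    """
    host_ids = sorted(host_sequences)
    pro_ids = sorted(prophage_orfsets)
    if len(host_ids) < 3:
        raise ValueError("need at least 3 hosts")
    for pid in pro_ids:
        if host_of.get(pid) not in host_sequences:
            raise ValueError(f"prophage {pid} has no host sequence")

    ani_mat = np.full((len(host_ids), len(host_ids)), 100.0)
    for i, j in itertools.combinations(range(len(host_ids)), 2):
        value = ani(host_sequences[host_ids[i]], host_sequences[host_ids[j]],
                    fragment_bp=fragment_bp)
        ani_mat[i, j] = ani_mat[j, i] = value if value is not None else 0.0

    aai_mat = np.full((len(pro_ids), len(pro_ids)), 100.0)
    for i, j in itertools.combinations(range(len(pro_ids)), 2):
        value, _ = aai_pair(prophage_orfsets[pro_ids[i]],
                            prophage_orfsets[pro_ids[j]])
        aai_mat[i, j] = aai_mat[j, i] = value if value is not None else 0.0

    host_clusters = _similarity_to_flat_clusters(host_ids, ani_mat, ani_cut)
    pro_clusters = _similarity_to_flat_clusters(pro_ids, aai_mat, aai_cut)

    matches = 0
    total = 0
    mismatched: list[tuple[str, str]] = []
    for a, b in itertools.combinations(pro_ids, 2):
        same_aai = pro_clusters[a] == pro_clusters[b]
        same_host = host_clusters[host_of[a]] == host_clusters[host_of[b]]
        total += 1
        if same_aai == same_host:
            matches += 1
        else:
            mismatched.append((a, b))
    return {
        "ani_matrix": pd.DataFrame(ani_mat, index=host_ids, columns=host_ids),
        "aai_matrix": pd.DataFrame(aai_mat, index=pro_ids, columns=pro_ids),
        "host_clusters": host_clusters,
        "prophage_clusters": pro_clusters,
        "congruence": matches / total if total else None,
        "mismatched_pairs": mismatched,
    }
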