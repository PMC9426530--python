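"""Example data: multi-genus viral clusters from public genome surveys.

A small set of viral-cluster host compositions observed among prophages
of complete public prokaryotic genomes, used in documentation and for
validating the host-range classifier: each entry lists the member hosts
(genus counts with full lineages) of one cluster whose members were
found in more than one host genus.
"""

from __future__ import annotations

from .catalog import TaxonomyLineage
from .clustering import ViralCluster

__all__ = ["example_multi_genus_clusters", "EXAMPLE_LINEAGES"]

EXAMPLE_LINEAGES: dict[str, TaxonomyLineage] = {
    "Salmonella": TaxonomyLineage(
        "Proteobacteria", "Gammaproteobacteria", "Enterobacterales",
        "Enterobacteriaceae", "Salmonella"),
    "Klebsiella": TaxonomyLineage(
        "Proteobacteria", "Gammaproteobacteria", "Enterobacterales",
        "Enterobacteriaceae", "Klebsiella"),
    "Citrobacter": TaxonomyLineage(
        "Proteobacteria", "Gammaproteobacteria", "Enterobacterales",
        "Enterobacteriaceae", "Citrobacter"),
    "Mixta": TaxonomyLineage(
        "Proteobacteria", "Gammaproteobacteria", "Enterobacterales",
        "Erwiniaceae", "Mixta"),
    "Sodalis": TaxonomyLineage(
        "Proteobacteria", "Gammaproteobacteria", "Enterobacterales",
        "Pectobacteriaceae", "Sodalis"),
    "Ralstonia": TaxonomyLineage(
        "Proteobacteria", "Betaproteobacteria", "Burkholderiales",
        "Burkholderiaceae", "Ralstonia"),
    "Streptomyces": TaxonomyLineage(
        "Actinobacteria", "Actinomycetia", "Streptomycetales",
        "Streptomycetaceae", "Streptomyces"),
    "Mycobacteroides": TaxonomyLineage(
        "Actinobacteria", "Actinomycetia", "Mycobacteriales",
        "Mycobacteriaceae", "Mycobacteroides"),
    "Mycolicibacterium": TaxonomyLineage(
        "Actinobacteria", "Actinomycetia", "Mycobacteriales",
        "Mycobacteriaceae", "Mycolicibacterium"),
    "Odoribacter": TaxonomyLineage(
        "Bacteroidetes", "Bacteroidia", "Bacteroidales",
        "Odoribacteraceae", "Odoribacter"),
    "Parabacteroides": TaxonomyLineage(
        "Bacteroidetes", "Bacteroidia", "Bacteroidales",
        "Tannerellaceae", "Parabacteroides"),
}

#: vc_id -> list of (host genus, number of member genomes)
EXAMPLE_COMPOSITIONS: dict[str, list[tuple[str, int]]] = {
    "vOTU_1233": [("Salmonella", 7), ("Klebsiella", 2)],
    "vOTU_94": [("Ralstonia", 3), ("Streptomyces", 1)],
    "vOTU_1254": [("Odoribacter", 2), ("Parabacteroides", 1)],
    "vOTU_1158": [("Mycobacteroides", 1), ("Mycolicibacterium", 1)],
    "vOTU_1237": [("Mycobacteroides", 1), ("Mycolicibacterium", 1)],
    "vOTU_51": [("Mycobacteroides", 1), ("Mycolicibacterium", 1)],
    "vOTU_831": [("Mycobacteroides", 1), ("Mycolicibacterium", 1)],
    "vOTU_1201": [("Mixta", 1), ("Salmonella", 1)],
    "vOTU_1442": [("Sodalis", 1), ("Citrobacter", 1)],
}


def example_multi_genus_clusters() -> list[ViralCluster]:
    """The example compositions as ViralCluster objects (one synthetic
    member/host id per member genome; no sequences attached)."""
    clusters = []
    for vc_id, comp in EXAMPLE_COMPOSITIONS.items():
        members = []
        member_hosts = []
        n = 0
        for genus, count in comp:
            for _ in range(count):
                n += 1
                members.append(f"{vc_id}_p{n}")
                member_hosts.append((f"{vc_id}_g{n}", EXAMPLE_LINEAGES[genus]))
        clusters.append(ViralCluster(
            vc_id=vc_id, representative=members[0], members=members,
            member_hosts=member_hosts))
    return clusters
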