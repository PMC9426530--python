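"""AAI computation, the thresholded relatedness network, per-rank edge
fractions, shared-ortholog accounting, and ANI-AAI co-structure."""

from __future__ import annotations

import numpy as np
import pytest

from prophagekit.aai import (
    AAINetwork,
    aai_pair,
    ani_aai_costructure,
    build_network,
    fraction_by_rank,
    shared_ortholog_summary,
)
from prophagekit.catalog import TaxonomyLineage
from prophagekit.seqcompare import Orf, OrfSet

from conftest import make_lineage, random_seq

AAS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def proteome(rng, n=8, lo=80, hi=250, parent="A") -> OrfSet:
    orfs = [Orf(f"{parent}_orf{i + 1}", 1, 1 + 1000 * i, 1000 * i + 900,
                "".join(rng.choice(AAS, int(rng.integers(lo, hi)))))
            for i in range(n)]
    return OrfSet(parent, orfs)


def mutate_proteome(rng, orfset: OrfSet, divergence: float,
                    parent="B") -> OrfSet:
    orfs = []
    for o in orfset.orfs:
        prot = list(o.protein)
        idx = rng.choice(len(prot), int(round(divergence * len(prot))),
                         replace=False)
        for i in idx:
            prot[i] = str(rng.choice([a for a in AAS if a != prot[i]]))
        orfs.append(Orf(o.orf_id.replace(f"{orfset.parent_id}_", f"{parent}_"),
                        o.frame, o.start, o.end, "".join(prot)))
    return OrfSet(parent, orfs)


class TestAaiPair:
    def test_identical_proteomes(self):
        rng = np.random.default_rng(0)
        a = proteome(rng)
        b = OrfSet("B", [Orf(o.orf_id.replace("A_", "B_"), 1, o.start, o.end,
                             o.protein) for o in a.orfs])
        aai, n = aai_pair(a, b)
        assert aai == pytest.approx(100.0)
        assert n == len(a)

    def test_unrelated_is_undefined(self):
        rng = np.random.default_rng(1)
        aai, n = aai_pair(proteome(rng, parent="A"), proteome(rng, parent="B"))
        assert aai is None and n == 0

    def test_ten_percent_mutated_copy(self):
        """Mutation-mask oracle: 10% planted substitutions per protein
        give AAI 90 up to alignment wobble."""
        rng = np.random.default_rng(2)
        a = proteome(rng, n=10)
        b = mutate_proteome(rng, a, 0.10)
        aai, n = aai_pair(a, b)
        assert n == 10
        assert aai == pytest.approx(90.0, abs=2.0)

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        a = proteome(rng, n=6)
        b = mutate_proteome(rng, a, 0.15)
        assert aai_pair(a, b)[0] == pytest.approx(aai_pair(b, a)[0], abs=1e-9)


def two_family_orfsets(rng, intra=0.05, inter=0.40, per_family=3):
    """Two proteome families; members mutated `intra` off their family
    ancestor, the second ancestor mutated `inter` off the first."""
    anc1 = proteome(rng, n=8, parent="F1")
    anc2 = mutate_proteome(rng, anc1, inter, parent="F2")
    sets = {}
    for fam, anc in (("F1", anc1), ("F2", anc2)):
        for m in range(per_family):
            name = f"{fam}m{m}"
            sets[name] = mutate_proteome(rng, anc, intra, parent=name)
    return sets


class TestNetwork:
    def test_identical_triangle(self):
        rng = np.random.default_rng(4)
        base = proteome(rng, n=6)
        sets, lineages = {}, {}
        for name in ("PA", "PB", "PC"):
            sets[name] = OrfSet(name, [
                Orf(o.orf_id.replace("A_", f"{name}_"), 1, o.start, o.end,
                    o.protein) for o in base.orfs])
            lineages[name] = make_lineage()
        net = build_network(sets, lineages, threshold=80)
        assert net.n_nodes == 3 and net.n_edges == 3
        assert all(d["aai"] == pytest.approx(100.0)
                   for _, _, d in net.graph.edges(data=True))

    def test_two_planted_families_form_two_cliques(self):
        rng = np.random.default_rng(5)
        sets = two_family_orfsets(rng)
        lineages = {name: make_lineage() for name in sets}
        net = build_network(sets, lineages, threshold=80)
        import networkx as nx
        comps = [sorted(c) for c in nx.connected_components(net.graph)]
        assert sorted(map(tuple, comps)) == [
            ("F1m0", "F1m1", "F1m2"), ("F2m0", "F2m1", "F2m2")]
        for comp in comps:  # each component is a complete clique
            sub = net.graph.subgraph(comp)
            assert sub.number_of_edges() == 3

    def test_threshold_above_100_empty(self):
        rng = np.random.default_rng(6)
        sets = two_family_orfsets(rng, per_family=2)
        lineages = {name: make_lineage() for name in sets}
        assert build_network(sets, lineages, threshold=101).n_edges == 0

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        sets = two_family_orfsets(rng, intra=0.10, inter=0.25)
        lineages = {name: make_lineage() for name in sets}
        nets = [build_network(sets, lineages, threshold=t)
                for t in (60, 75, 90)]
        assert nets[0].n_edges >= nets[1].n_edges >= nets[2].n_edges

    def test_common_ancestor_connected_at_80(self):
        rng = np.random.default_rng(8)
        sets = two_family_orfsets(rng, intra=0.07, inter=0.07, per_family=2)
        lineages = {name: make_lineage() for name in sets}
        net = build_network(sets, lineages, threshold=80)
        import networkx as nx
        assert nx.number_connected_components(net.graph) == 1


def hand_network(edge_spec):
    import networkx as nx
    g = nx.Graph()
    for (a, lin_a), (b, lin_b), orth in edge_spec:
        g.add_node(a, lineage=lin_a)
        g.add_node(b, lineage=lin_b)
        g.add_edge(a, b, aai=90.0, n_orthologs=orth)
    return AAINetwork(g, 80.0)


class TestFractions:
    def test_hand_counted_fractions(self):
        same = make_lineage()
        cross_genus = make_lineage(genus="GenusB")           # same family
        cross_phylum = TaxonomyLineage("PhyZ", "ClaZ", "OrdZ", "FamZ", "GenZ")
        net = hand_network([
            (("p1", same), ("p2", same), 1),
            (("p3", same), ("p4", same), 1),
            (("p5", same), ("p6", same), 1),
            (("p7", same), ("p8", cross_genus), 1),
            (("p9", same), ("p10", cross_phylum), 1),
        ])
        fr = fraction_by_rank(net).set_index("rank")["fraction_different"]
        assert fr["genus"] == pytest.approx(2 / 5)
        assert fr["family"] == pytest.approx(1 / 5)
        assert fr["phylum"] == pytest.approx(1 / 5)

    def test_single_genus_all_zero(self):
        lin = make_lineage()
        net = hand_network([(("p1", lin), ("p2", lin), 1)])
        assert (fraction_by_rank(net)["fraction_different"] == 0).all()

    def test_monotone_under_nested_taxonomy(self):
        rng = np.random.default_rng(9)
        # random nested lineages over a 2-level hierarchy
        lineages = []
        for i in range(12):
            p = f"Phy{i % 2}"
            o = f"Ord{i % 4}"
            lineages.append(TaxonomyLineage(p, f"Cla{i % 2}", o,
                                            f"Fam{o}_{i // 4}", f"Gen{i}"))
        edges = []
        for _ in range(20):
            i, j = rng.choice(12, 2, replace=False)
            edges.append(((f"x{i}", lineages[i]), (f"x{j}", lineages[j]), 1))
        fr = fraction_by_rank(hand_network(edges))
        vals = fr.set_index("rank")["fraction_different"]
        assert vals["genus"] >= vals["family"] >= vals["order"] \
               >= vals["class"] >= vals["phylum"]

    def test_empty_network_rejected(self):
        import networkx as nx
        with pytest.raises(ValueError):
            fraction_by_rank(AAINetwork(nx.Graph(), 80.0))


class TestSharedOrthologs:
    def test_mean_over_cross_phylum_edges(self):
        lin_a = make_lineage(phylum="PhyA")
        lin_b = TaxonomyLineage("PhyB", "ClaB", "OrdB", "FamB", "GenB")
        net = hand_network([
            (("p1", lin_a), ("p2", lin_b), 2),
            (("p3", lin_a), ("p4", lin_b), 4),
            (("p5", lin_a), ("p6", lin_a), 50),   # within-phylum, ignored
        ])
        assert shared_ortholog_summary(net, "PhyA", "PhyB") == pytest.approx(3.0)

    def test_no_cross_edge_undefined(self):
        lin_a = make_lineage(phylum="PhyA")
        net = hand_network([(("p1", lin_a), ("p2", lin_a), 3)])
        assert shared_ortholog_summary(net, "PhyA", "PhyB") is None

    def test_planted_exact_count(self):
        rng = np.random.default_rng(10)
        lin_a = make_lineage(phylum="PhyA")
        lin_b = TaxonomyLineage("PhyB", "ClaB", "OrdB", "FamB", "GenB")
        k = 7
        net = hand_network([((f"a{i}", lin_a), (f"b{i}", lin_b), k)
                            for i in range(5)])
        assert shared_ortholog_summary(net, "PhyA", "PhyB") == k


class TestCostructure:
    @staticmethod
    def tracked_setup(rng, mirror=True):
        """Two host subclades with, when mirror, prophage families that
        track them; otherwise prophage families assigned at random."""
        base = random_seq(rng, 6_000)
        arr = np.array(list(base))
        idx = rng.choice(6_000, 1_800, replace=False)
        for i in idx:
            arr[i] = "ACGT"[("ACGT".index(arr[i]) + 1) % 4]
        clade_roots = {"cladeA": base, "cladeB": "".join(arr)}
        hosts, host_of, orfsets = {}, {}, {}
        fam = {"cladeA": proteome(rng, n=6, parent="famA"),
               "cladeB": mutate_proteome(rng, proteome(rng, n=6, parent="x"),
                                         0.0, parent="famB")}
        for c, clade in enumerate(("cladeA", "cladeB")):
            for i in range(3):
                gid = f"{clade}_h{i}"
                root = np.array(list(clade_roots[clade]))
                jdx = rng.choice(6_000, 60, replace=False)
                for j in jdx:
                    root[j] = "ACGT"[("ACGT".index(root[j]) + 1) % 4]
                hosts[gid] = "".join(root)
                pid = f"{clade}_p{i}"
                source = clade if mirror else ("cladeA", "cladeB")[
                    int(rng.integers(2))]
                orfsets[pid] = mutate_proteome(rng, fam[source], 0.02,
                                               parent=pid)
                host_of[pid] = gid
        return hosts, orfsets, host_of

    def test_tracking_prophages_give_full_congruence(self):
        rng = np.random.default_rng(11)
        hosts, orfsets, host_of = self.tracked_setup(rng, mirror=True)
        out = ani_aai_costructure(hosts, orfsets, host_of,
                                  fragment_bp=500)
        assert out["congruence"] == pytest.approx(1.0)
        assert out["mismatched_pairs"] == []

    def test_shuffled_prophages_lose_congruence(self):
        rng = np.random.default_rng(13)
        hosts, orfsets, host_of = self.tracked_setup(rng, mirror=False)
        out = ani_aai_costructure(hosts, orfsets, host_of,
                                  fragment_bp=500)
        assert out["congruence"] < 1.0
        assert len(out["mismatched_pairs"]) > 0

    def test_too_few_hosts_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError):
            ani_aai_costructure({"h1": random_seq(rng, 2_000),
                                 "h2": random_seq(rng, 2_000)}, {}, {})
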