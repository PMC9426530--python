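"""Shared fixtures: small hand-built catalogs and table writers."""

from __future__ import annotations

import numpy as np
import pytest

from prophagekit.catalog import (
    HostGenome,
    ProphageRecord,
    TaxonomyLineage,
    write_host_table,
    write_prophage_table,
)


def make_lineage(genus="GenusA", family="FamA", order="OrdA",
                 class_="ClaA", phylum="PhyA") -> TaxonomyLineage:
    return TaxonomyLineage(phylum, class_, order, family, genus)


def make_host(genome_id, genus="GenusA", size=2_000_000, biosample=None,
              **ranks) -> HostGenome:
    return HostGenome(
        genome_id, [(f"{genome_id}_chr", size)],
        make_lineage(genus=genus, **ranks), biosample or {})


def make_record(pid, genome_id, length=30_000, start=1000, category=1,
                plasmid=False, replicon=None, sequence=None) -> ProphageRecord:
    return ProphageRecord(pid, genome_id, replicon or f"{genome_id}_chr",
                          start, start + length - 1, category, plasmid,
                          sequence)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def small_catalog():
    """3 genomes (2 genera), 5 prophages with mixed categories/flags."""
    hosts = [
        make_host("G1", genus="GenusA", size=3_000_000),
        make_host("G2", genus="GenusA", size=4_000_000),
        make_host("G3", genus="GenusB", family="FamB", size=5_000_000),
    ]
    # G3 additionally carries a small plasmid replicon
    hosts[2] = HostGenome("G3", [("G3_chr", 4_991_000), ("G3_pls", 9_000)],
                          make_lineage(genus="GenusB", family="FamB"))
    records = [
        make_record("P1", "G1", category=1),
        make_record("P2", "G1", category=3, start=200_000),
        make_record("P3", "G2", category=2),
        make_record("P4", "G3", category=1, plasmid=True),
        make_record("P5", "G3", length=5_000, start=1,
                    category=1, replicon="G3_pls"),
    ]
    return hosts, records


@pytest.fixture
def catalog_tables(tmp_path, small_catalog):
    hosts, records = small_catalog
    host_path = tmp_path / "hosts.tsv"
    pro_path = tmp_path / "prophages.tsv"
    write_host_table(hosts, host_path)
    write_prophage_table(records, pro_path)
    return host_path, pro_path
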