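"""Prophage catalog: data model, ingestion, prediction filtering, summaries.

A catalog pairs a table of host genomes (with a genus-complete taxonomy
and per-replicon lengths) with a table of predicted prophages (host
linkage, 1-based inclusive coordinates, predictor confidence category and
a plasmid flag).  Downstream statistics only ever see a catalog that has
been validated here: every prophage resolves to a known replicon, its
coordinates lie inside that replicon, and the taxonomy is nested
(equality at a lower rank implies equality at every higher rank).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "RANKS",
    "TaxonomyLineage",
    "HostGenome",
    "ProphageRecord",
    "CatalogSummary",
    "CatalogError",
    "load_catalog",
    "filter_predictions",
    "per_genome_counts",
    "summarize_catalog",
    "length_distribution",
    "write_host_table",
    "write_prophage_table",
]

#: taxonomic ranks from broadest to narrowest
RANKS = ("phylum", "class_", "order", "family", "genus")

HOST_COLUMNS = [
    "genome_id", "phylum", "class", "order", "family", "genus",
    "genome_size_bp", "replicon_id", "replicon_length_bp", "biosample_json",
]
PROPHAGE_COLUMNS = [
    "prophage_id", "genome_id", "replicon_id", "start", "end",
    "category", "plasmid_flag",
]


class CatalogError(ValueError):
    """Raised for malformed or inconsistent catalog inputs."""


@dataclass(frozen=True)
class TaxonomyLineage:
    """Ordered lineage phylum > class > order > family > genus.

    Higher ranks may be "NA"; the genus is always a real name because the
    catalog only admits genomes assigned at least to the genus level.
    """

    phylum: str
    class_: str
    order: str
    family: str
    genus: str

    def __post_init__(self):
        for rank in RANKS:
            value = getattr(self, rank)
            if not isinstance(value, str) or not value:
                raise CatalogError(f"lineage rank {rank!r} must be a non-empty string")
        if self.genus == "NA":
            raise CatalogError("genus must be assigned (not 'NA')")

    def rank(self, rank: str) -> str:
        return getattr(self, "class_" if rank == "class" else rank)

    def as_tuple(self) -> tuple[str, ...]:
        return tuple(getattr(self, r) for r in RANKS)


@dataclass
class HostGenome:
    genome_id: str
    replicons: list[tuple[str, int]]
    lineage: TaxonomyLineage
    biosample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ids = [r for r, _ in self.replicons]
        if len(set(ids)) != len(ids):
            raise CatalogError(f"duplicate replicon ids in genome {self.genome_id}")
        if self.genome_size < 1:
            raise CatalogError(f"genome {self.genome_id} has size < 1 bp")

    @property
    def genome_size(self) -> int:
        return sum(length for _, length in self.replicons)

    def replicon_length(self, replicon_id: str) -> int:
        for rid, length in self.replicons:
            if rid == replicon_id:
                return length
        raise KeyError(replicon_id)


@dataclass
class ProphageRecord:
    prophage_id: str
    genome_id: str
    replicon_id: str
    start: int
    end: int
    category: int
    plasmid_flag: bool
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise CatalogError(
                f"prophage {self.prophage_id}: invalid coordinates "
                f"{self.start}..{self.end} (1-based inclusive, start <= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CatalogSummary:
    """Descriptive summary of a filtered catalog.

    ``mean_per_lysogen``, ``mode_per_lysogen`` and the coefficient of
    variation are computed over lysogens (hosts with >= 1 prophage) only;
    all three are NaN when there are no lysogens.
    """

    n_genomes: int
    n_lysogens: int
    lysogen_fraction: float
    n_prophages: int
    mean_per_lysogen: float
    mode_per_lysogen: float
    coefficient_of_variation: float  # percent, 100 * sd / mean (sample sd)


def _validate_nestedness(hosts: Sequence[HostGenome]) -> None:
    """Equality at a lower rank must imply equality at all higher ranks."""
    seen: dict[tuple[str, str], tuple[str, ...]] = {}
    for host in hosts:
        lineage = host.lineage.as_tuple()
        for i, rank in enumerate(RANKS[1:], start=1):
            name = lineage[i]
            if name == "NA":
                continue
            key = (rank, name)
            upper = lineage[:i]
            if key in seen and seen[key] != upper:
                raise CatalogError(
                    f"taxonomy not nested: {rank} {name!r} maps to both "
                    f"{seen[key]} and {upper}"
                )
            seen.setdefault(key, upper)


def load_catalog(
    prophage_table: str | Path,
    host_table: str | Path,
    fasta: str | Path | None = None,
) -> tuple[list[HostGenome], list[ProphageRecord]]:
    """Load and cross-validate host and prophage tables.

    The host table has one row per replicon (columns ``genome_id, phylum,
    class, order, family, genus, genome_size_bp, replicon_id,
    replicon_length_bp, biosample_json``); the prophage table has columns
    ``prophage_id, genome_id, replicon_id, start, end, category,
    plasmid_flag``.  When a FASTA path is given, sequences are attached to
    prophages by ``prophage_id``.
    """
    hosts_df = pd.read_csv(host_table, sep="\t", dtype=str)
    missing = set(HOST_COLUMNS) - set(hosts_df.columns)
    if missing:
        raise CatalogError(f"host table missing columns: {sorted(missing)}")
    pro_df = pd.read_csv(prophage_table, sep="\t", dtype=str)
    missing = set(PROPHAGE_COLUMNS) - set(pro_df.columns)
    if missing:
        raise CatalogError(f"prophage table missing columns: {sorted(missing)}")

    hosts: list[HostGenome] = []
    for genome_id, grp in hosts_df.groupby("genome_id", sort=False):
        first = grp.iloc[0]
        lineage = TaxonomyLineage(
            phylum=first["phylum"], class_=first["class"], order=first["order"],
            family=first["family"], genus=first["genus"],
        )
        replicons = [
            (row["replicon_id"], int(row["replicon_length_bp"]))
            for _, row in grp.iterrows()
        ]
        raw = first["biosample_json"]
        biosample = json.loads(raw) if isinstance(raw, str) and raw.strip() else {}
        host = HostGenome(genome_id, replicons, lineage, biosample)
        stated = int(first["genome_size_bp"])
        if stated != host.genome_size:
            raise CatalogError(
                f"genome {genome_id}: genome_size_bp {stated} != sum of "
                f"replicon lengths {host.genome_size}"
            )
        hosts.append(host)
    _validate_nestedness(hosts)
    host_index = {h.genome_id: h for h in hosts}

    records: list[ProphageRecord] = []
    for i, row in pro_df.iterrows():
        gid = row["genome_id"]
        if gid not in host_index:
            raise CatalogError(
                f"prophage table row {i} ({row['prophage_id']}): unknown "
                f"genome_id {gid!r}"
            )
        rec = ProphageRecord(
            prophage_id=row["prophage_id"],
            genome_id=gid,
            replicon_id=row["replicon_id"],
            start=int(row["start"]),
            end=int(row["end"]),
            category=int(row["category"]),
            plasmid_flag=str(row["plasmid_flag"]).strip().lower()
            in ("true", "1", "yes"),
        )
        host = host_index[gid]
        try:
            rep_len = host.replicon_length(rec.replicon_id)
        except KeyError:
            raise CatalogError(
                f"prophage {rec.prophage_id}: replicon {rec.replicon_id!r} "
                f"not found in genome {gid}"
            ) from None
        if rec.end > rep_len:
            raise CatalogError(
                f"prophage {rec.prophage_id}: end {rec.end} exceeds replicon "
                f"length {rep_len}"
            )
        records.append(rec)

    if fasta is not None:
        seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta), "fasta")}
        for rec in records:
            if rec.prophage_id in seqs:
                rec.sequence = seqs[rec.prophage_id]
    return hosts, records


def filter_predictions(
    records: Sequence[ProphageRecord],
    hosts: Sequence[HostGenome],
    min_replicon_bp: int = 10_000,
    keep_categories: Iterable[int] = (1, 2),
    drop_plasmid: bool = True,
) -> list[ProphageRecord]:
    """Apply the prediction-confidence filters.

    Keeps only prophages sitting on replicons of at least
    ``min_replicon_bp``, predicted in one of ``keep_categories`` (the
    high-confidence predictor classes), and — when ``drop_plasmid`` —
    not tagged as plasmids.  Order-preserving and idempotent.
    """
    keep = set(int(c) for c in keep_categories)
    host_index = {h.genome_id: h for h in hosts}
    out = []
    for rec in records:
        host = host_index[rec.genome_id]
        if host.replicon_length(rec.replicon_id) < min_replicon_bp:
            continue
        if rec.category not in keep:
            continue
        if drop_plasmid and rec.plasmid_flag:
            continue
        out.append(rec)
    return out


def per_genome_counts(
    hosts: Sequence[HostGenome], records: Sequence[ProphageRecord]
) -> pd.Series:
    """Prophage count per genome (zeros included), indexed by genome_id."""
    counts = pd.Series(0, index=[h.genome_id for h in hosts], dtype=int)
    for rec in records:
        counts[rec.genome_id] += 1
    return counts


def summarize_catalog(
    hosts: Sequence[HostGenome],
    records: Sequence[ProphageRecord],
    denominator: str = "lysogens",
) -> CatalogSummary:
    """Summarize a (filtered) catalog.

    A lysogen is a host with at least one prophage.  ``denominator``
    selects whether the mean is over lysogens (default) or all genomes.
    """
    if denominator not in ("lysogens", "all"):
        raise ValueError("denominator must be 'lysogens' or 'all'")
    counts = per_genome_counts(hosts, records)
    lys = counts[counts > 0]
    n_genomes = len(hosts)
    n_lysogens = int((counts > 0).sum())
    n_prophages = int(counts.sum())
    if n_lysogens == 0:
        return CatalogSummary(
            n_genomes, 0, 0.0, n_prophages, math.nan, math.nan, math.nan
        )
    denom = n_lysogens if denominator == "lysogens" else n_genomes
    mean = n_prophages / denom
    values, freq = np.unique(lys.to_numpy(), return_counts=True)
    mode = float(values[freq == freq.max()].min())  # smallest on ties
    sd = float(lys.std(ddof=1)) if n_lysogens > 1 else 0.0
    lys_mean = float(lys.mean())
    cv = 100.0 * sd / lys_mean if lys_mean > 0 else math.nan
    return CatalogSummary(
        n_genomes=n_genomes,
        n_lysogens=n_lysogens,
        lysogen_fraction=n_lysogens / n_genomes,
        n_prophages=n_prophages,
        mean_per_lysogen=mean,
        mode_per_lysogen=mode,
        coefficient_of_variation=cv,
    )


def length_distribution(
    records: Sequence[ProphageRecord], bin_kb: float = 5.0
) -> dict:
    """Histogram of prophage lengths plus mean and the modal bins.

    Returns a dict with ``bin_edges`` (bp), ``counts``, ``mean_length``
    and ``modal_bins`` — the centers (bp) of up to the two highest local
    maxima of the histogram, largest count first.  Prophage length
    distributions are typically bimodal (a short and a long population),
    which the modal bins make visible without a formal bimodality test.
    """
    if not records:
        raise ValueError("length_distribution requires at least one record")
    lengths = np.array([r.length for r in records], dtype=float)
    width = bin_kb * 1000.0
    lo = math.floor(lengths.min() / width) * width
    hi = math.ceil(lengths.max() / width) * width
    if hi <= lo:
        hi = lo + width
    edges = np.arange(lo, hi + width / 2, width)
    counts, edges = np.histogram(lengths, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0

    # local maxima, plateau-tolerant: a run of equal counts is a maximum
    # when the nearest differing neighbor on each side (or the boundary)
    # is lower; the run's first bin represents it
    maxima = []
    n = len(counts)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and counts[j + 1] == counts[i]:
            j += 1
        left_ok = i == 0 or counts[i - 1] < counts[i]
        right_ok = j == n - 1 or counts[j + 1] < counts[i]
        if counts[i] > 0 and left_ok and right_ok:
            maxima.append((counts[i], i))
        i = j + 1
    maxima.sort(key=lambda t: (-t[0], t[1]))
    modal_bins = [float(centers[i]) for _, i in maxima[:2]]
    return {
        "bin_edges": edges,
        "counts": counts,
        "mean_length": float(lengths.mean()),
        "modal_bins": modal_bins,
    }


def write_host_table(hosts: Sequence[HostGenome], path: str | Path) -> None:
    rows = []
    for h in hosts:
        lineage = h.lineage
        bios = json.dumps(h.biosample) if h.biosample else ""
        for rid, rlen in h.replicons:
            rows.append({
                "genome_id": h.genome_id,
                "phylum": lineage.phylum, "class": lineage.class_,
                "order": lineage.order, "family": lineage.family,
                "genus": lineage.genus,
                "genome_size_bp": h.genome_size,
                "replicon_id": rid, "replicon_length_bp": rlen,
                "biosample_json": bios,
            })
    pd.DataFrame(rows, columns=HOST_COLUMNS).to_csv(path, sep="\t", index=False)


def write_prophage_table(records: Sequence[ProphageRecord], path: str | Path) -> None:
    rows = [{
        "prophage_id": r.prophage_id, "genome_id": r.genome_id,
        "replicon_id": r.replicon_id, "start": r.start, "end": r.end,
        "category": r.category, "plasmid_flag": r.plasmid_flag,
    } for r in records]
    pd.DataFrame(rows, columns=PROPHAGE_COLUMNS).to_csv(path, sep="\t", index=False)
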