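"""Taxon-level prophage enrichment: size-abundance relations, per-rank
Wilcoxon enrichment with genus subsampling, and bootstrap subsampling.

The central question is whether some host taxa carry more prophages per
genome than the rest of the population.  For each taxon at a rank, its
per-genome prophage counts are compared against the background (all
other retained genomes by default) with a one-sided Wilcoxon rank-sum
test, Bonferroni-corrected across the taxa tested at that rank.  Because
genome databases are badly unbalanced, two guards are applied: taxa with
very many genomes can be randomly downsampled to a cap before testing,
and a bootstrap scheme repeatedly subsamples a fixed number of genomes
per genus and records the per-iteration p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalog import HostGenome, ProphageRecord, per_genome_counts
from .stats import bonferroni, wilcoxon_greater

__all__ = [
    "EnrichmentResult",
    "BootstrapResult",
    "size_abundance",
    "rank_enrichment",
    "bootstrap_enrichment",
    "count_count_correlation",
]

_RANK_COLUMN = {"phylum": "phylum", "class": "class_", "order": "order",
                "family": "family", "genus": "genus"}


@dataclass
class EnrichmentResult:
    taxon: str
    rank: str
    n_genomes: int
    n_prophages: int
    mean_count: float
    p_value: float
    p_adjusted: float
    direction: str = "greater"


@dataclass
class BootstrapResult:
    genus: str
    p_values: np.ndarray  # one entry per iteration

    def quantiles(self, qs=(0.25, 0.5, 0.75)) -> dict[float, float]:
        return {q: float(np.quantile(self.p_values, q)) for q in qs}


def _counts_frame(hosts: Sequence[HostGenome],
                  records: Sequence[ProphageRecord]) -> pd.DataFrame:
    counts = per_genome_counts(hosts, records)
    rows = []
    for h in hosts:
        row = {"genome_id": h.genome_id, "count": int(counts[h.genome_id]),
               "genome_size": h.genome_size}
        for rank, attr in _RANK_COLUMN.items():
            row[rank] = getattr(h.lineage, attr)
        rows.append(row)
    return pd.DataFrame(rows)


def size_abundance(
    hosts: Sequence[HostGenome],
    records: Sequence[ProphageRecord],
    bin_mb: float = 1.0,
    min_length_bp: Optional[int] = 30_000,
) -> dict:
    """Prophage abundance as a function of host genome size.

    Returns per-Mb-bin totals and means of prophage counts — for all
    prophages and for the subset of at least ``min_length_bp`` (the
    conventional cutoff separating likely-functional long prophages from
    degraded short ones) — plus the Spearman correlation between genome
    size and per-genome count.
    """
    df = _counts_frame(hosts, records)
    long_counts = pd.Series(0, index=df["genome_id"], dtype=int)
    if min_length_bp is not None:
        for rec in records:
            if rec.length >= min_length_bp:
                long_counts[rec.genome_id] += 1
    df["count_long"] = long_counts.to_numpy()
    width = bin_mb * 1e6
    df["bin"] = (df["genome_size"] // width).astype(int)
    agg = df.groupby("bin").agg(
        n_genomes=("count", "size"),
        total=("count", "sum"), mean=("count", "mean"),
        total_long=("count_long", "sum"), mean_long=("count_long", "mean"),
    ).reset_index()
    agg["bin_mb"] = agg["bin"] * bin_mb
    out = {"bins": agg.drop(columns="bin")}
    if len(df) < 3:
        out["spearman_rho"] = None
        out["spearman_p"] = None
        out["correlation_defined"] = False
    else:
        rho, p = sps.spearmanr(df["genome_size"], df["count"])
        out["spearman_rho"] = float(rho)
        out["spearman_p"] = float(p)
        out["correlation_defined"] = True
    return out


def rank_enrichment(
    hosts: Sequence[HostGenome],
    records: Sequence[ProphageRecord],
    rank: str = "genus",
    min_genomes: int = 5,
    cap_trigger: Optional[int] = 50,
    cap_sample: int = 10,
    seed: int = 0,
    exclude_taxon: Optional[tuple[str, str]] = None,
    background: str = "exclude_focal",
) -> list[EnrichmentResult]:
    """One-sided Wilcoxon enrichment of every taxon at ``rank``.

    Taxa with fewer than ``min_genomes`` genomes are not tested; taxa
    with more than ``cap_trigger`` genomes are first downsampled to
    ``cap_sample`` genomes (deterministically under ``seed``).  The
    background for each taxon is every other retained genome
    (``background='exclude_focal'``, default) or the entire retained
    population including the focal taxon (``'all'``).  ``exclude_taxon``
    removes a clade — e.g. ``("order", "SomeOrder")`` — from the data
    before any testing, for re-tests without a dominant group.
    """
    if rank not in _RANK_COLUMN:
        raise ValueError(f"unknown rank {rank!r}")
    if background not in ("exclude_focal", "all"):
        raise ValueError("background must be 'exclude_focal' or 'all'")
    df = _counts_frame(hosts, records)
    if exclude_taxon is not None:
        ex_rank, ex_name = exclude_taxon
        if ex_rank not in _RANK_COLUMN:
            raise ValueError(f"unknown rank {ex_rank!r} in exclude_taxon")
        df = df[df[ex_rank] != ex_name]
    if df[rank].nunique() < 2:
        raise ValueError(f"need at least 2 taxa at rank {rank!r}")

    rng = np.random.default_rng(seed)
    # deterministic downsampling of over-represented taxa
    kept_idx: list[np.ndarray] = []
    for taxon in sorted(df[rank].unique()):
        idx = df.index[df[rank] == taxon].to_numpy()
        if cap_trigger is not None and len(idx) > cap_trigger:
            idx = rng.choice(idx, size=cap_sample, replace=False)
        kept_idx.append(idx)
    retained = df.loc[np.sort(np.concatenate(kept_idx))]

    eligible = [t for t in sorted(retained[rank].unique())
                if (retained[rank] == t).sum() >= min_genomes]
    m = len(eligible)
    results = []
    for taxon in eligible:
        mask = retained[rank] == taxon
        focal = retained.loc[mask, "count"].to_numpy()
        bg = (retained.loc[~mask, "count"] if background == "exclude_focal"
              else retained["count"]).to_numpy()
        p = wilcoxon_greater(focal, bg)
        results.append(EnrichmentResult(
            taxon=taxon, rank=rank, n_genomes=int(mask.sum()),
            n_prophages=int(focal.sum()), mean_count=float(focal.mean()),
            p_value=p, p_adjusted=bonferroni(p, m),
        ))
    results.sort(key=lambda r: (r.p_adjusted, r.taxon))
    return results


def bootstrap_enrichment(
    hosts: Sequence[HostGenome],
    records: Sequence[ProphageRecord],
    n_genomes: int = 10,
    n_iter: int = 100,
    min_genus_genomes: int = 50,
    seed: int = 0,
) -> tuple[list[BootstrapResult], list[str]]:
    """Bootstrap subsampling scheme behind per-genus p-value boxplots.

    At each iteration, ``n_genomes`` genomes are drawn without
    replacement from every eligible genus (those with at least
    ``min_genus_genomes`` genomes); each genus's subsample is tested
    against the pooled remainder of that iteration's sample with the
    one-sided Wilcoxon, and the p-value recorded.  Returns the per-genus
    p-value vectors plus the list of genera skipped as too small.
    Deterministic given ``seed`` (one RNG substream per iteration).
    """
    df = _counts_frame(hosts, records)
    sizes = df.groupby("genus").size()
    eligible = sorted(sizes.index[sizes >= max(n_genomes, min_genus_genomes)])
    skipped = sorted(set(sizes.index) - set(eligible))
    if not eligible:
        raise ValueError("no genus has enough genomes for bootstrapping")
    by_genus = {g: df.loc[df["genus"] == g, "count"].to_numpy() for g in eligible}
    pmat = np.empty((len(eligible), n_iter))
    for it in range(n_iter):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7, it]))
        samples = {g: rng.choice(by_genus[g], size=n_genomes, replace=False)
                   for g in eligible}
        for gi, genus in enumerate(eligible):
            rest = np.concatenate([samples[g] for g in eligible if g != genus])
            pmat[gi, it] = wilcoxon_greater(samples[genus], rest)
    return ([BootstrapResult(g, pmat[i]) for i, g in enumerate(eligible)], skipped)


def count_count_correlation(x_counts: Sequence[float],
                            y_counts: Sequence[float]) -> tuple[float, float]:
    """Spearman correlation between two per-genus count vectors
    (e.g. prophages per genus vs genomes sequenced per genus)."""
    x = np.asarray(x_counts, dtype=float)
    y = np.asarray(y_counts, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "taxon": r.taxon, "rank": r.rank, "n_genomes": r.n_genomes,
        "n_prophages": r.n_prophages, "mean_count": r.mean_count,
        "p_value": r.p_value, "p_adjusted": r.p_adjusted,
    } for r in results])


def bootstrap_table(results: Sequence[BootstrapResult]) -> pd.DataFrame:
    """Bootstrap p-matrix, genera as rows and iterations as columns."""
    return pd.DataFrame(
        {r.genus: r.p_values for r in results}
    ).T.rename_axis("genus")
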