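"""Pathogen-vs-unassigned prophage enrichment and leave-one-out analysis.

Hosts are labelled "pathogen" or "unassigned" by keyword matching against
their Biosample free-text fields.  The keyword rule is an explicit,
configurable approximation of manual curation: a host is a pathogen when
any mined field contains a trigger phrase ("pathogen", "pathogenic",
disease-association patterns).  Per-genome prophage counts of the two
groups are compared with a one-sided Wilcoxon; a leave-one-out (LOO)
sweep removes one genus at a time to attribute the signal, and a shared-
genus table compares the two groups within every genus present in both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import HostGenome, ProphageRecord, per_genome_counts
from .stats import bonferroni, wilcoxon_greater

__all__ = [
    "PathogenLabel",
    "LooResult",
    "DEFAULT_FIELDS",
    "DEFAULT_KEYWORDS",
    "classify_pathogen",
    "label_hosts",
    "cap_per_genus",
    "group_enrichment",
    "loo_contribution",
    "shared_genus_comparison",
]

#: Biosample fields mined for pathogen evidence, in fixed iteration order
DEFAULT_FIELDS = (
    "general description",
    "isolation source",
    "isolation site",
    "host",
    "environmental medium",
    "sample type",
)

#: default trigger phrases (case-insensitive substring match)
DEFAULT_KEYWORDS = (
    "pathogen",       # also matches "pathogenic"
    "patient with",
    "diseased",
    "infection",
    "lesion",
    "clinical isolate",
)


@dataclass(frozen=True)
class PathogenLabel:
    genome_id: str
    label: str                       # "pathogen" | "unassigned"
    trigger: str = ""                # "field: phrase" for pathogens

    def __post_init__(self):
        if (self.label == "pathogen") != bool(self.trigger):
            raise ValueError("label is 'pathogen' iff a trigger is recorded")


@dataclass
class LooResult:
    left_out_genus: str
    p_value: float                   # NaN when a removal empties a group
    delta_vs_full: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.p_value)


def classify_pathogen(
    biosample: dict[str, str],
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    fields: Sequence[str] = DEFAULT_FIELDS,
    genome_id: str = "",
) -> PathogenLabel:
    """Label one host from its Biosample field mapping.

    Fields are scanned in the fixed order of ``fields`` and keywords in
    the order of ``keywords``; the first match wins and is recorded as
    the trigger.  An empty mapping is unassigned.
    """
    for field in fields:
        text = biosample.get(field, "")
        if not text:
            continue
        lowered = text.lower()
        for kw in keywords:
            if kw.lower() in lowered:
                return PathogenLabel(genome_id, "pathogen", f"{field}: {kw}")
    return PathogenLabel(genome_id, "unassigned")


def label_hosts(hosts: Sequence[HostGenome],
                keywords: Sequence[str] = DEFAULT_KEYWORDS,
                fields: Sequence[str] = DEFAULT_FIELDS) -> list[PathogenLabel]:
    return [classify_pathogen(h.biosample, keywords, fields, h.genome_id)
            for h in hosts]


def cap_per_genus(hosts: Sequence[HostGenome], cap: int = 100,
                  seed: int = 0) -> list[HostGenome]:
    """Downsample over-represented genera to at most ``cap`` genomes.

    Genera at or below the cap pass through intact; larger genera are
    sampled uniformly without replacement, deterministically under
    ``seed``.  Output preserves the input ordering.
    """
    by_genus: dict[str, list[int]] = {}
    for i, h in enumerate(hosts):
        by_genus.setdefault(h.lineage.genus, []).append(i)
    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    for genus in sorted(by_genus):
        idx = by_genus[genus]
        if len(idx) <= cap:
            keep.update(idx)
        else:
            keep.update(rng.choice(idx, size=cap, replace=False).tolist())
    return [h for i, h in enumerate(hosts) if i in keep]


def group_enrichment(pathogen_counts: Sequence[float],
                     unassigned_counts: Sequence[float]) -> dict:
    """Group means/medians and the one-sided Wilcoxon p-value for
    H1: pathogens carry more prophages than unassigned hosts."""
    x = np.asarray(pathogen_counts, dtype=float)
    y = np.asarray(unassigned_counts, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    return {
        "pathogen_mean": float(x.mean()), "pathogen_median": float(np.median(x)),
        "unassigned_mean": float(y.mean()), "unassigned_median": float(np.median(y)),
        "n_pathogen": int(x.size), "n_unassigned": int(y.size),
        "p_value": wilcoxon_greater(x, y),
    }


def _group_counts(labels: Sequence[PathogenLabel], hosts: Sequence[HostGenome],
                  records: Sequence[ProphageRecord]) -> pd.DataFrame:
    counts = per_genome_counts(hosts, records)
    label_map = {l.genome_id: l.label for l in labels}
    rows = []
    for h in hosts:
        rows.append({
            "genome_id": h.genome_id,
            "genus": h.lineage.genus,
            "label": label_map.get(h.genome_id, "unassigned"),
            "count": int(counts[h.genome_id]),
        })
    return pd.DataFrame(rows)


def loo_contribution(labels: Sequence[PathogenLabel],
                     hosts: Sequence[HostGenome],
                     records: Sequence[ProphageRecord]) -> list[LooResult]:
    """Leave-one-genus-out sweep of the pathogen-vs-unassigned test.

    For every genus present in either group, the comparison is re-run on
    all remaining genomes; the result records the p-value and its change
    from the full-data p.  A removal that empties a group yields an
    undefined (NaN) entry rather than an error.
    """
    df = _group_counts(labels, hosts, records)
    genera = sorted(df["genus"].unique())
    if len(genera) < 2:
        raise ValueError("need at least 2 genera for a LOO sweep")
    full = group_enrichment(df.loc[df["label"] == "pathogen", "count"],
                            df.loc[df["label"] == "unassigned", "count"])
    full_p = full["p_value"]
    out = []
    for genus in genera:
        rest = df[df["genus"] != genus]
        x = rest.loc[rest["label"] == "pathogen", "count"]
        y = rest.loc[rest["label"] == "unassigned", "count"]
        if len(x) == 0 or len(y) == 0:
            out.append(LooResult(genus, math.nan, math.nan))
            continue
        p = group_enrichment(x, y)["p_value"]
        out.append(LooResult(genus, p, p - full_p))
    return out


def shared_genus_comparison(labels: Sequence[PathogenLabel],
                            hosts: Sequence[HostGenome],
                            records: Sequence[ProphageRecord]) -> pd.DataFrame:
    """Per-genus pathogen-vs-unassigned table over the shared genera.

    Only genera with at least one genome in each group are tested; the
    Bonferroni factor is the number of shared genera.  Columns follow
    the shape of a per-genus comparison table: group sizes, prophage
    totals, standard deviations, raw and adjusted p-values.
    """
    df = _group_counts(labels, hosts, records)
    shared = []
    for genus, grp in df.groupby("genus"):
        pat = grp.loc[grp["label"] == "pathogen", "count"].to_numpy()
        una = grp.loc[grp["label"] == "unassigned", "count"].to_numpy()
        if len(pat) >= 1 and len(una) >= 1:
            shared.append((genus, pat, una))
    if not shared:
        raise ValueError("no genus is shared between the two groups")
    m = len(shared)
    rows = []
    for genus, pat, una in shared:
        p = wilcoxon_greater(pat, una)
        rows.append({
            "genus": genus,
            "n_pathogen": len(pat), "n_unassigned": len(una),
            "prophages_pathogen": int(pat.sum()),
            "prophages_unassigned": int(una.sum()),
            "sd_pathogen": float(np.std(pat, ddof=1)) if len(pat) > 1 else 0.0,
            "sd_unassigned": float(np.std(una, ddof=1)) if len(una) > 1 else 0.0,
            "p_value": p,
            "p_adjusted": bonferroni(p, m),
        })
    return pd.DataFrame(rows).sort_values("p_adjusted").reset_index(drop=True)
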