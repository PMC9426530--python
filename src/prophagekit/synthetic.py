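"""Synthetic prophage catalogs with planted, recoverable structure.

Every downstream stage of the package is exercised on data built here:

* a genus-structured host population (phylum > class > order > family >
  genus) with log-normally distributed genome sizes of 1-10 Mb;
* per-genome prophage counts drawn from a negative binomial, with chosen
  genera planted at a fold-enrichment and (optionally) pathogen-labelled
  genomes at a count multiplier;
* prophage lengths from a two-component Gaussian mixture (a short
  population near 30 kb and a long one near 70 kb);
* prophage sequence families generated from ancestors by i.i.d.
  substitution at controlled divergence, so pairwise identities are
  analytically predictable;
* host-like nucleotide composition: each phylum owns an order-1 Markov
  (dinucleotide) transition matrix, host sequence windows are emitted
  from a per-genus mutation ladder off the phylum ancestor (giving
  within-genus ANI structure), and prophage sequences mix their host
  clade's transition matrix with a common phage background at weight
  ``host_weight`` — the signal the k-mer bias stage recovers;
* Biosample-style free text with pathogen trigger phrases planted at a
  configurable fraction.

All output is a deterministic function of the master seed; each
component draws from its own named substream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import (
    HostGenome,
    ProphageRecord,
    TaxonomyLineage,
    write_host_table,
    write_prophage_table,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCatalog",
    "simulate_catalog",
    "simulate_cluster_families",
    "simulate_biosample_text",
    "mutate_sequence",
    "random_transition_matrix",
    "markov_sequence",
    "write_fasta",
]

BASES = np.array(list("ACGT"))

# substream ids for the named RNG streams
_STREAM_TAXONOMY = 1
_STREAM_COUNTS = 2
_STREAM_LENGTHS = 3
_STREAM_SEQS = 4
_STREAM_BIOSAMPLE = 5
_STREAM_FAMILIES = 6


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic named substream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic catalog.

    Defaults describe the study conditions the package is tested under:
    negative-binomial prophage counts with mean 2 and dispersion 1,
    a 70/30 mixture of ~30 kb and ~70 kb prophages, genome sizes
    log-normal around 4 Mb clipped to [1, 10] Mb, and a 0.3 pathogen
    fraction with a 1.5x count multiplier.
    """

    seed: int = 0
    # taxonomy shape (one class per phylum)
    n_phyla: int = 2
    orders_per_phylum: int = 2
    families_per_order: int = 2
    genera_per_family: int = 2
    genomes_per_genus: int = 10
    # genome sizes, log-normal in Mb
    genome_size_log_mean: float = np.log(4.0)
    genome_size_log_sd: float = 0.35
    genome_size_range_mb: tuple[float, float] = (1.0, 10.0)
    # per-genome prophage counts
    nb_mean: float = 2.0
    nb_dispersion: float = 1.0
    enriched_genera: dict[int, float] = field(default_factory=dict)  # genus index -> fold
    # predictor noise, exercised by the filtering stage
    category_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)  # categories 1,2,3
    plasmid_flag_prob: float = 0.03
    plasmid_replicon_prob: float = 0.10
    # prophage length mixture (bp)
    length_weights: tuple[float, float] = (0.7, 0.3)
    length_means: tuple[float, float] = (30_000.0, 70_000.0)
    length_sds: tuple[float, float] = (5_000.0, 10_000.0)
    min_length_bp: int = 5_000
    # pathogen planting
    pathogen_fraction: float = 0.3
    pathogen_count_multiplier: float = 1.5
    # sequence generation
    with_sequences: bool = False
    host_window_bp: int = 20_000
    genus_divergence: float = 0.15   # genus ancestor vs phylum ancestor
    genome_divergence: float = 0.02  # genome window vs genus ancestor
    host_weight: float = 0.8         # w: host-clade share of prophage composition
    composition_strength: float = 1.0
    prophage_seq_bp: Optional[int] = 10_000  # None: use the annotated length
    # sequence families (simulate_cluster_families)
    n_families: int = 2
    members_per_family: int = 5
    family_divergence: tuple[float, ...] = (0.05, 0.05)
    inter_family_divergence: float = 0.30
    indel_rate: float = 0.0

    def __post_init__(self):
        if min(self.n_phyla, self.orders_per_phylum, self.families_per_order,
               self.genera_per_family, self.genomes_per_genus) < 1:
            raise ValueError("taxonomy shape values must all be >= 1")
        if abs(sum(self.length_weights) - 1.0) > 1e-9:
            raise ValueError("length mixture weights must sum to 1")
        if not 0.0 <= self.pathogen_fraction <= 1.0:
            raise ValueError("pathogen_fraction must be in [0, 1]")
        if not 0.0 <= self.host_weight <= 1.0:
            raise ValueError("host_weight must be in [0, 1]")
        for d in self.family_divergence:
            if not 0.0 <= d < 0.5:
                raise ValueError("family divergences must lie in [0, 0.5)")

    @property
    def n_genera(self) -> int:
        return (self.n_phyla * self.orders_per_phylum
                * self.families_per_order * self.genera_per_family)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("length_weights", "length_means", "length_sds",
                    "genome_size_range_mb", "category_probs", "family_divergence"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "enriched_genera" in raw and raw["enriched_genera"] is not None:
            raw["enriched_genera"] = {int(k): float(v)
                                      for k, v in raw["enriched_genera"].items()}
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted structure accompanying a synthetic data set."""

    enriched_genera: dict[str, float] = field(default_factory=dict)
    pathogen_labels: dict[str, bool] = field(default_factory=dict)
    family_membership: dict[str, str] = field(default_factory=dict)
    source_clade: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for genus, fold in self.enriched_genera.items():
            rows.append({"kind": "enriched_genus", "id": genus, "value": fold})
        for gid, flag in self.pathogen_labels.items():
            rows.append({"kind": "pathogen", "id": gid, "value": int(flag)})
        for sid, fam in self.family_membership.items():
            rows.append({"kind": "family", "id": sid, "value": fam})
        for sid, clade in self.source_clade.items():
            rows.append({"kind": "source_clade", "id": sid, "value": clade})
        return pd.DataFrame(rows, columns=["kind", "id", "value"])


# ---------------------------------------------------------------------------
# sequence primitives

def random_transition_matrix(rng: np.random.Generator, strength: float = 1.0) -> np.ndarray:
    """A random 4x4 order-1 Markov transition matrix.

    ``strength`` scales how far rows deviate from uniform; 0 gives the
    uniform i.i.d. model (all k-mer biases ~1).
    """
    raw = 1.0 + strength * rng.random((4, 4))
    return raw / raw.sum(axis=1, keepdims=True)


def markov_sequence(rng: np.random.Generator, length: int,
                    transition: np.ndarray) -> np.ndarray:
    """Sequence of base indices from an order-1 Markov chain."""
    cum = np.cumsum(transition, axis=1)
    u = rng.random(length)
    seq = np.empty(length, dtype=np.int8)
    stationary = transition.mean(axis=0)
    seq[0] = np.searchsorted(np.cumsum(stationary), u[0])
    for i in range(1, length):
        seq[i] = np.searchsorted(cum[seq[i - 1]], u[i])
    return seq


def mutate_sequence(rng: np.random.Generator, seq: np.ndarray,
                    divergence: float, indel_rate: float = 0.0) -> np.ndarray:
    """Substitute exactly round(divergence * L) positions (always to a
    different base), plus optional i.i.d. 1-bp indels."""
    out = seq.copy()
    n_sub = int(round(divergence * len(seq)))
    if n_sub > 0:
        pos = rng.choice(len(seq), size=n_sub, replace=False)
        shift = rng.integers(1, 4, size=n_sub)
        out[pos] = (out[pos] + shift) % 4
    if indel_rate > 0:
        keep = rng.random(len(out)) >= indel_rate / 2
        out = out[keep]
        n_ins = rng.binomial(len(out), indel_rate / 2)
        if n_ins:
            pos = np.sort(rng.choice(len(out) + 1, size=n_ins, replace=True))
            out = np.insert(out, pos, rng.integers(0, 4, size=n_ins))
    return out


def indices_to_str(seq: np.ndarray) -> str:
    return "".join(BASES[seq])


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Biosample text

_PATHOGEN_TEMPLATES = [
    ("isolation source", "blood of patient with sepsis"),
    ("isolation source", "sputum from patient with pneumonia"),
    ("general description", "pathogenic strain of clinical origin"),
    ("host", "diseased tomato plant"),
    ("isolation site", "wound infection, hospital ward"),
    ("sample type", "clinical isolate from urinary tract infection"),
    ("general description", "opportunistic pathogen"),
    ("isolation source", "skin lesion of diseased cattle"),
]

_UNASSIGNED_TEMPLATES = [
    ("isolation source", "forest soil"),
    ("environmental medium", "marine sediment"),
    ("isolation source", "freshwater lake"),
    ("sample type", "rhizosphere sample"),
    ("isolation site", "hot spring mat"),
    ("host", "healthy adult volunteer"),
    ("environmental medium", "activated sludge"),
    ("isolation source", "fermented dairy product"),
]

_NEUTRAL_FILLER = [
    ("general description", "complete genome sequencing project"),
    ("sample type", "pure culture"),
]


def simulate_biosample_text(label: str,
                            seed: int | np.random.Generator) -> dict[str, str]:
    """A Biosample-style field mapping for a pathogen or unassigned host.

    Pathogen mappings contain at least one trigger phrase in one of the
    mined fields; unassigned mappings contain none.
    """
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, _STREAM_BIOSAMPLE)
    if label not in ("pathogen", "unassigned"):
        raise ValueError("label must be 'pathogen' or 'unassigned'")
    templates = _PATHOGEN_TEMPLATES if label == "pathogen" else _UNASSIGNED_TEMPLATES
    fields = dict([templates[rng.integers(len(templates))]])
    for key, text in _NEUTRAL_FILLER:
        if rng.random() < 0.5 and key not in fields:
            fields[key] = text
    return fields


# ---------------------------------------------------------------------------
# catalog simulation

@dataclass
class SyntheticCatalog:
    hosts: list[HostGenome]
    records: list[ProphageRecord]
    sequences: dict[str, str]          # prophage_id and genome_id -> sequence
    ground_truth: GroundTruth
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit host/prophage TSVs, a FASTA and the ground-truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "hosts": outdir / "hosts.tsv",
            "prophages": outdir / "prophages.tsv",
            "fasta": outdir / "sequences.fasta",
            "groundtruth": outdir / "groundtruth.tsv",
        }
        write_host_table(self.hosts, paths["hosts"])
        write_prophage_table(self.records, paths["prophages"])
        write_fasta(self.sequences, paths["fasta"])
        self.ground_truth.to_frame().to_csv(paths["groundtruth"], sep="\t", index=False)
        return paths


def _taxonomy(config: SimulationConfig) -> list[TaxonomyLineage]:
    """One lineage per genus, nested by construction."""
    lineages = []
    g = 0
    for p in range(config.n_phyla):
        for o in range(config.orders_per_phylum):
            for f in range(config.families_per_order):
                for _ in range(config.genera_per_family):
                    lineages.append(TaxonomyLineage(
                        phylum=f"Phylum{p + 1:02d}",
                        class_=f"Class{p + 1:02d}",
                        order=f"Order{p + 1:02d}_{o + 1:02d}",
                        family=f"Family{p + 1:02d}_{o + 1:02d}_{f + 1:02d}",
                        genus=f"Genus{g + 1:03d}",
                    ))
                    g += 1
    return lineages


def _draw_lengths(rng: np.random.Generator, n: int,
                  config: SimulationConfig) -> np.ndarray:
    comp = rng.choice(len(config.length_weights), size=n, p=config.length_weights)
    means = np.asarray(config.length_means)[comp]
    sds = np.asarray(config.length_sds)[comp]
    lengths = rng.normal(means, sds)
    return np.maximum(config.min_length_bp, np.round(lengths)).astype(int)


def simulate_catalog(config: SimulationConfig) -> SyntheticCatalog:
    """Generate a complete synthetic catalog under ``config``.

    Deterministic given ``config.seed``.  Emitted tables satisfy every
    catalog invariant and round-trip through :func:`catalog.load_catalog`.
    """
    lineages = _taxonomy(config)
    n_genomes = config.n_genera * config.genomes_per_genus
    if n_genomes < 1:
        raise ValueError("configuration yields zero genomes")

    rng_tax = _rng(config.seed, _STREAM_TAXONOMY)
    rng_cnt = _rng(config.seed, _STREAM_COUNTS)
    rng_len = _rng(config.seed, _STREAM_LENGTHS)
    rng_bio = _rng(config.seed, _STREAM_BIOSAMPLE)
    rng_seq = _rng(config.seed, _STREAM_SEQS)

    truth = GroundTruth()
    for gi, fold in config.enriched_genera.items():
        if not 0 <= gi < config.n_genera:
            raise ValueError(f"enriched genus index {gi} out of range")
        truth.enriched_genera[lineages[gi].genus] = float(fold)

    # per-phylum composition: transition matrix + phylum ancestor window
    phyla = sorted({lin.phylum for lin in lineages})
    transitions = {ph: random_transition_matrix(rng_seq, config.composition_strength)
                   for ph in phyla}
    background = random_transition_matrix(rng_seq, config.composition_strength)
    phylum_anc: dict[str, np.ndarray] = {}
    genus_anc: dict[str, np.ndarray] = {}
    if config.with_sequences:
        for ph in phyla:
            phylum_anc[ph] = markov_sequence(rng_seq, config.host_window_bp,
                                             transitions[ph])
        for lin in lineages:
            genus_anc[lin.genus] = mutate_sequence(
                rng_seq, phylum_anc[lin.phylum], config.genus_divergence)

    hosts: list[HostGenome] = []
    records: list[ProphageRecord] = []
    sequences: dict[str, str] = {}
    lo_mb, hi_mb = config.genome_size_range_mb
    genome_n = 0
    prophage_n = 0
    for lin in lineages:
        fold = truth.enriched_genera.get(lin.genus, 1.0)
        for _ in range(config.genomes_per_genus):
            genome_n += 1
            gid = f"G{genome_n:05d}"
            size_mb = float(np.clip(
                np.exp(rng_tax.normal(config.genome_size_log_mean,
                                      config.genome_size_log_sd)),
                lo_mb, hi_mb))
            genome_size = int(round(size_mb * 1e6))
            replicons = [(f"{gid}_chr", genome_size)]
            if rng_tax.random() < config.plasmid_replicon_prob:
                plen = int(rng_tax.integers(3_000, 50_000))
                replicons = [(f"{gid}_chr", genome_size - plen),
                             (f"{gid}_pls", plen)]

            is_pathogen = bool(rng_bio.random() < config.pathogen_fraction)
            truth.pathogen_labels[gid] = is_pathogen
            biosample = simulate_biosample_text(
                "pathogen" if is_pathogen else "unassigned", rng_bio)

            host = HostGenome(gid, replicons, lin, biosample)
            hosts.append(host)
            if config.with_sequences:
                window = mutate_sequence(rng_seq, genus_anc[lin.genus],
                                         config.genome_divergence)
                sequences[gid] = indices_to_str(window)

            mean = config.nb_mean * fold
            if is_pathogen:
                mean *= config.pathogen_count_multiplier
            k = config.nb_dispersion
            count = int(rng_cnt.negative_binomial(k, k / (k + mean)))
            if count == 0:
                continue
            lengths = _draw_lengths(rng_len, count, config)
            chrom_id, chrom_len = replicons[0]
            occupied: list[tuple[int, int]] = []
            for length in lengths:
                prophage_n += 1
                pid = f"P{prophage_n:05d}"
                length = int(min(length, max(config.min_length_bp, chrom_len // 2)))
                start = _place(rng_len, chrom_len, length, occupied)
                records.append(ProphageRecord(
                    prophage_id=pid, genome_id=gid, replicon_id=chrom_id,
                    start=start, end=start + length - 1,
                    category=int(rng_cnt.choice((1, 2, 3), p=config.category_probs)),
                    plasmid_flag=bool(rng_cnt.random() < config.plasmid_flag_prob),
                ))
                if config.with_sequences:
                    n_bp = config.prophage_seq_bp or length
                    mix = (config.host_weight * transitions[lin.phylum]
                           + (1 - config.host_weight) * background)
                    sequences[pid] = indices_to_str(
                        markov_sequence(rng_seq, n_bp, mix))
                    truth.source_clade[pid] = lin.phylum
    for rec in records:
        if rec.prophage_id in sequences:
            rec.sequence = sequences[rec.prophage_id]
    return SyntheticCatalog(hosts, records, sequences, truth, config)


def _place(rng: np.random.Generator, replicon_len: int, length: int,
           occupied: list[tuple[int, int]]) -> int:
    """Uniform 1-based start, preferring non-overlap with prior placements."""
    hi = max(1, replicon_len - length + 1)
    for _ in range(50):
        start = int(rng.integers(1, hi + 1))
        end = start + length - 1
        if all(end < s or start > e for s, e in occupied):
            occupied.append((start, end))
            return start
    start = int(rng.integers(1, hi + 1))
    occupied.append((start, start + length - 1))
    return start


def simulate_cluster_families(
    config: SimulationConfig,
) -> tuple[dict[str, str], GroundTruth]:
    """Sequence families at controlled divergence for clustering tests.

    The first family's ancestor is random (length drawn from the length
    mixture); every other family's ancestor diverges from it by
    ``inter_family_divergence``.  Members diverge from their family's
    ancestor by that family's entry in ``family_divergence``
    (substitution-only unless ``indel_rate`` > 0), so member-to-ancestor
    identity is exactly ``1 - divergence``.
    """
    if len(config.family_divergence) < config.n_families:
        raise ValueError("need one divergence level per family")
    rng = _rng(config.seed, _STREAM_FAMILIES)
    length = int(_draw_lengths(rng, 1, config)[0])
    root = rng.integers(0, 4, size=length, dtype=np.int8)
    seqs: dict[str, str] = {}
    truth = GroundTruth()
    for f in range(config.n_families):
        fam = f"FAM{f + 1:02d}"
        anc = root if f == 0 else mutate_sequence(
            rng, root, config.inter_family_divergence)
        div = config.family_divergence[f]
        for m in range(config.members_per_family):
            sid = f"{fam}_M{m + 1:02d}"
            member = mutate_sequence(rng, anc, div, config.indel_rate)
            seqs[sid] = indices_to_str(member)
            truth.family_membership[sid] = fam
    return seqs, truth
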