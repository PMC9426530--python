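"""K-mer usage bias profiles and phage-host co-clustering.

The bias of a k-mer w is B(w) = f_obs(w) / f_exp(w), the observed
frequency normalized by an expectation composed from sub-k-mer
frequencies of the same sequence.  Two expectation models are provided:

* ``markov_max`` (default) — the maximal-order Markov expectation,
  f_exp(w) = prod f((k-1)-mers of w) / prod f(interior (k-2)-mers of w),
  the standard contrast-word statistic; for k=2 it reduces to f(x)f(y)
  and for k=3 to f(xy)f(yz)/f(y);
* ``literal_product`` — the plain product of all (k-1)-mer frequencies.

The two coincide exactly at k=2.  For k=1 no sub-k-mers exist and the
profile stores raw mononucleotide frequencies.  Because phages tend to
share k-mer usage with their hosts, log-bias profiles cluster phages
with candidate hosts and rank hosts by profile distance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

__all__ = [
    "KmerBiasProfile",
    "kmer_frequencies",
    "kmer_bias",
    "merge_profiles",
    "bias_distance",
    "cocluster_profiles",
    "profile_matrix",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


@dataclass
class KmerBiasProfile:
    sequence_id: str
    k: int                                  # 0 marks a merged multi-k profile
    bias: dict[str, float]
    log_bias: dict[str, float]
    undefined: tuple[str, ...] = ()         # observed k-mers with f_exp == 0


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_frequencies(seq: str, k: int, both_strands: bool = False) -> dict[str, float]:
    """Frequencies of overlapping k-mers; windows containing non-ACGT
    symbols are skipped and the denominator reduced accordingly."""
    seq = seq.upper()
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k = {k}")
    counts: dict[str, int] = {}
    total = 0
    for s in ((seq, _revcomp(seq)) if both_strands else (seq,)):
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if set(w) <= _VALID:
                counts[w] = counts.get(w, 0) + 1
                total += 1
    if total == 0:
        raise ValueError("no valid ACGT window of length k")
    return {w: c / total for w, c in sorted(counts.items())}


def kmer_bias(seq: str, k: int, model: str = "markov_max",
              sequence_id: str = "seq", both_strands: bool = False) -> KmerBiasProfile:
    """Bias profile B(w) = f_obs(w) / f_exp(w) for every observed k-mer.

    ``model`` selects the expectation (see module docstring).  K-mers
    whose expectation is zero are reported in ``undefined`` rather than
    silently dropped.  For k=1 the profile stores raw frequencies.
    """
    if model not in ("markov_max", "literal_product"):
        raise ValueError("model must be 'markov_max' or 'literal_product'")
    freq = kmer_frequencies(seq, k, both_strands)
    if k == 1:
        return KmerBiasProfile(
            sequence_id, 1, dict(freq),
            {w: math.log(f) for w, f in freq.items() if f > 0},
        )
    sub1 = kmer_frequencies(seq, k - 1, both_strands)
    sub2 = kmer_frequencies(seq, k - 2, both_strands) if k >= 3 else {}
    bias: dict[str, float] = {}
    log_bias: dict[str, float] = {}
    undefined: list[str] = []
    for w, f_obs in freq.items():
        numer = 1.0
        ok = True
        for i in range(len(w) - (k - 1) + 1):
            numer *= sub1.get(w[i:i + k - 1], 0.0)
        if model == "markov_max" and k >= 3:
            denom = 1.0
            for i in range(1, len(w) - (k - 2)):
                denom *= sub2.get(w[i:i + k - 2], 0.0)
            if denom == 0.0:
                ok = False
            else:
                numer /= denom
        if not ok or numer == 0.0:
            undefined.append(w)
            continue
        b = f_obs / numer
        bias[w] = b
        log_bias[w] = math.log(b)
    return KmerBiasProfile(sequence_id, k, bias, log_bias, tuple(undefined))


def merge_profiles(*profiles: KmerBiasProfile) -> KmerBiasProfile:
    """Concatenate profiles of different k (e.g. di- plus tri-nucleotide)
    into one vector; k-mer keys of different lengths never collide."""
    if not profiles:
        raise ValueError("need at least one profile")
    sid = profiles[0].sequence_id
    bias: dict[str, float] = {}
    log_bias: dict[str, float] = {}
    undefined: list[str] = []
    for p in profiles:
        if p.sequence_id != sid:
            raise ValueError("profiles to merge must describe one sequence")
        bias.update(p.bias)
        log_bias.update(p.log_bias)
        undefined.extend(p.undefined)
    return KmerBiasProfile(sid, 0, bias, log_bias, tuple(undefined))


def bias_distance(p1: KmerBiasProfile, p2: KmerBiasProfile) -> float:
    """Euclidean distance between log-bias vectors over the k-mers
    defined in both profiles."""
    if p1.k != p2.k:
        raise ValueError("profiles must have the same k")
    shared = sorted(set(p1.log_bias) & set(p2.log_bias))
    if not shared:
        raise ValueError("profiles share no defined k-mer")
    diff = np.array([p1.log_bias[w] - p2.log_bias[w] for w in shared])
    return float(np.sqrt((diff ** 2).sum()))


def cocluster_profiles(
    profiles: dict[str, KmerBiasProfile],
    host_ids: Sequence[str] = (),
    linkage: str = "average",
    cut_height: Optional[float] = None,
) -> dict:
    """Hierarchically co-cluster phage and candidate-host bias profiles.

    Returns the scipy linkage matrix, flat cluster labels (cut at
    ``cut_height``, default half the maximum merge height), and — when
    ``host_ids`` is given — each remaining (phage) profile's hosts
    ranked by ascending bias distance.
    """
    ids = sorted(profiles)
    if len(ids) < 3:
        raise ValueError("need at least 3 profiles")
    n = len(ids)
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = bias_distance(profiles[ids[i]], profiles[ids[j]])
        dist[i, j] = dist[j, i] = d
    z = scipy_linkage(squareform(dist, checks=False), method=linkage)
    height = cut_height if cut_height is not None else z[:, 2].max() / 2.0
    labels = fcluster(z, t=height, criterion="distance")
    clusters = dict(zip(ids, labels.tolist()))
    host_ids = [h for h in host_ids if h in profiles]
    nearest: dict[str, list[str]] = {}
    for pid in ids:
        if pid in host_ids:
            continue
        i = ids.index(pid)
        nearest[pid] = sorted(host_ids, key=lambda h: (dist[i, ids.index(h)], h))
    return {"linkage": z, "ids": ids, "clusters": clusters,
            "nearest_hosts": nearest, "distance_matrix":
                pd.DataFrame(dist, index=ids, columns=ids)}


def profile_matrix(profiles: dict[str, KmerBiasProfile]) -> pd.DataFrame:
    """Log-bias matrix (rows = sequences, columns = k-mers, NaN where
    undefined) for export or heatmap drawing."""
    ids = sorted(profiles)
    kmers = sorted({w for p in profiles.values() for w in p.log_bias})
    data = [[profiles[i].log_bias.get(w, np.nan) for w in kmers] for i in ids]
    return pd.DataFrame(data, index=ids, columns=kmers)
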