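"""Pairwise sequence comparison primitives.

Conventions used throughout (documented here once, relied on by the
clustering and AAI stages):

* identity = matches / aligned columns, where aligned columns include
  internal gaps but never terminal gaps (alignments are local);
* coverage = fraction of the SHORTER sequence spanned by the alignment;
* nucleotide scoring: match +2, mismatch -3, gap of length k costs
  5 + 2k (the classic blastn scheme);
* protein scoring: BLOSUM62, gap open 11, extension 1.

Short nucleotide pairs (product of lengths below ~4e6) are aligned with
an exact affine-gap Smith-Waterman; longer pairs are delegated to the
BLAST+ ``blastn`` executable with identical scoring, taking the best
HSP.  Protein alignments are always exact, which keeps reciprocal-best-
hit tie-breaking deterministic.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "AlignmentStats",
    "Orf",
    "OrfSet",
    "pairwise_identity",
    "ani",
    "find_orfs",
    "rbh_orthologs",
    "align_proteins",
]

NT_MATCH = 2.0
NT_MISMATCH = -3.0
NT_GAP_OPEN = 5.0    # cost of opening a gap (length-k gap costs open + k*extend)
NT_GAP_EXTEND = 2.0
EXACT_CELL_LIMIT = 4_000_000  # use exact DP when len_a * len_b is below this

_NT_ALPHABET = set("ACGTN")
_STOPS_TABLE11 = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class AlignmentStats:
    identity: float        # matches / aligned columns (internal gaps counted)
    coverage: float        # aligned span / length of the shorter sequence
    aligned_length: int    # aligned columns

    @property
    def aligned(self) -> bool:
        return self.aligned_length > 0


@dataclass(frozen=True)
class Orf:
    orf_id: str
    frame: int             # +1..+3 forward, -1..-3 reverse
    start: int             # 1-based inclusive on the forward strand
    end: int
    protein: str


@dataclass
class OrfSet:
    parent_id: str
    orfs: list[Orf]

    def __len__(self) -> int:
        return len(self.orfs)

    def __iter__(self):
        return iter(self.orfs)

    def proteins(self) -> dict[str, str]:
        return {o.orf_id: o.protein for o in self.orfs}


def _check_nt(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name} is empty")
    seq = seq.upper()
    if set(seq) - _NT_ALPHABET:
        bad = sorted(set(seq) - _NT_ALPHABET)
        raise ValueError(f"{name} contains non-ACGTN symbols: {bad}")
    return seq


def _nt_aligner() -> PairwiseAligner:
    al = PairwiseAligner(mode="local")
    al.match_score = NT_MATCH
    al.mismatch_score = NT_MISMATCH
    al.open_gap_score = -(NT_GAP_OPEN + NT_GAP_EXTEND)
    al.extend_gap_score = -NT_GAP_EXTEND
    return al


def _stats_from_alignment(alignment, len_row0: int, len_row1: int) -> AlignmentStats:
    counts = alignment.counts()
    cols = counts.gaps + counts.identities + counts.mismatches
    if cols == 0:
        return AlignmentStats(0.0, 0.0, 0)
    coords = alignment.coordinates
    spans = (int(coords[0, -1] - coords[0, 0]), int(coords[1, -1] - coords[1, 0]))
    short_row = 0 if len_row0 <= len_row1 else 1
    len_short = (len_row0, len_row1)[short_row]
    coverage = spans[short_row] / len_short if len_short else 0.0
    return AlignmentStats(
        identity=counts.identities / cols,
        coverage=float(coverage),
        aligned_length=int(cols),
    )


def _blastn_best_hsps(queries: dict[str, str], subject: str,
                      word_size: int = 11) -> dict[str, dict]:
    """Best HSP per query against a single subject, via blastn."""
    if shutil.which("blastn") is None:
        raise RuntimeError("blastn executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "query.fa"
        spath = Path(tmp) / "subject.fa"
        with open(qpath, "w") as fh:
            for name, seq in queries.items():
                fh.write(f">{name}\n{seq}\n")
        spath.write_text(f">subject\n{subject}\n")
        cmd = [
            "blastn", "-task", "blastn", "-query", str(qpath),
            "-subject", str(spath),
            "-reward", str(int(NT_MATCH)), "-penalty", str(int(NT_MISMATCH)),
            "-gapopen", str(int(NT_GAP_OPEN)), "-gapextend", str(int(NT_GAP_EXTEND)),
            "-dust", "no", "-soft_masking", "false",
            "-word_size", str(word_size),
            "-outfmt", "6 qseqid pident length qstart qend sstart send bitscore",
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"blastn failed: {proc.stderr.strip()}")
    best: dict[str, dict] = {}
    for line in proc.stdout.splitlines():
        parts = line.split("\t")
        qid = parts[0]
        hsp = {
            "pident": float(parts[1]), "length": int(parts[2]),
            "qstart": int(parts[3]), "qend": int(parts[4]),
            "bitscore": float(parts[7]),
        }
        if qid not in best or hsp["bitscore"] > best[qid]["bitscore"]:
            best[qid] = hsp
    return best


def pairwise_identity(seq_a: str, seq_b: str) -> AlignmentStats:
    """Local-alignment identity and coverage between two nucleotide
    sequences.  Symmetric in its arguments.  Sequences whose length
    product is below ~4e6 are aligned exactly; longer pairs use blastn
    with the same scoring (best HSP)."""
    seq_a = _check_nt(seq_a, "seq_a")
    seq_b = _check_nt(seq_b, "seq_b")
    # canonical order makes the result symmetric: shorter first
    short, long_ = sorted((seq_a, seq_b), key=lambda s: (len(s), s))
    if len(short) * len(long_) <= EXACT_CELL_LIMIT:
        alignments = _nt_aligner().align(long_, short)
        if len(alignments) == 0:
            return AlignmentStats(0.0, 0.0, 0)
        return _stats_from_alignment(alignments[0], len(long_), len(short))
    best = _blastn_best_hsps({"q": short}, long_)
    if "q" not in best:
        return AlignmentStats(0.0, 0.0, 0)
    hsp = best["q"]
    return AlignmentStats(
        identity=hsp["pident"] / 100.0,
        coverage=(hsp["qend"] - hsp["qstart"] + 1) / len(short),
        aligned_length=hsp["length"],
    )


def ani(genome_a: str, genome_b: str, fragment_bp: int = 1000,
        min_fragment_identity: float = 0.30,
        min_fragment_coverage: float = 0.70) -> Optional[float]:
    """Fragment-based average nucleotide identity, in percent.

    ``genome_a`` is chopped into non-overlapping ``fragment_bp`` windows
    (a trailing remainder shorter than the window is discarded), each
    aligned locally to ``genome_b``; fragments passing the identity and
    fragment-coverage filters contribute their identity to the mean.
    Returns None when no fragment passes.
    """
    genome_a = _check_nt(genome_a, "genome_a")
    genome_b = _check_nt(genome_b, "genome_b")
    if len(genome_a) < fragment_bp or len(genome_b) < fragment_bp:
        raise ValueError(f"both genomes must be at least {fragment_bp} bp")
    frags = {
        f"frag{i}": genome_a[off:off + fragment_bp]
        for i, off in enumerate(range(0, len(genome_a) - fragment_bp + 1, fragment_bp))
    }
    best = _blastn_best_hsps(frags, genome_b)
    identities = []
    for name, frag in frags.items():
        hsp = best.get(name)
        if hsp is None:
            continue
        identity = hsp["pident"] / 100.0
        coverage = (hsp["qend"] - hsp["qstart"] + 1) / len(frag)
        if identity >= min_fragment_identity and coverage >= min_fragment_coverage:
            identities.append(identity)
    if not identities:
        return None
    return 100.0 * float(np.mean(identities))


def find_orfs(seq: str, min_aa: int = 33, genetic_code: int = 11,
              starts: Sequence[str] = ("ATG",), parent_id: str = "seq") -> OrfSet:
    """Six-frame ORF scan: first start codon after each stop, through the
    next in-frame stop, kept when the translated protein has at least
    ``min_aa`` residues.  Deterministic ordering by (frame, start)."""
    seq = _check_nt(seq, "seq")
    starts = {s.upper() for s in starts}
    orfs: list[Orf] = []
    rev = str(Seq(seq).reverse_complement())
    L = len(seq)
    n = 0
    for strand, s in ((1, seq), (-1, rev)):
        for off in range(3):
            frame = strand * (off + 1)
            start_pos: Optional[int] = None
            for i in range(off, L - 2, 3):
                codon = s[i:i + 3]
                if codon in _STOPS_TABLE11:
                    if start_pos is not None:
                        n_aa = (i - start_pos) // 3
                        if n_aa >= min_aa:
                            protein = str(Seq(s[start_pos:i]).translate(
                                table=genetic_code))
                            if strand == 1:
                                fs, fe = start_pos + 1, i + 3
                            else:
                                fs, fe = L - (i + 3) + 1, L - start_pos
                            n += 1
                            orfs.append(Orf(f"{parent_id}_orf{n}", frame,
                                            fs, fe, protein))
                        start_pos = None
                elif start_pos is None and codon in starts:
                    start_pos = i
    orfs.sort(key=lambda o: (-o.frame if o.frame < 0 else o.frame, o.start))
    # renumber in the deterministic order
    renamed = [Orf(f"{parent_id}_orf{i + 1}", o.frame, o.start, o.end, o.protein)
               for i, o in enumerate(orfs)]
    return OrfSet(parent_id, renamed)


_PROT_ALIGNER: Optional[PairwiseAligner] = None


def _prot_aligner() -> PairwiseAligner:
    global _PROT_ALIGNER
    if _PROT_ALIGNER is None:
        al = PairwiseAligner(mode="local")
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -12.0
        al.extend_gap_score = -1.0
        _PROT_ALIGNER = al
    return _PROT_ALIGNER


def align_proteins(prot_a: str, prot_b: str) -> tuple[float, AlignmentStats]:
    """Exact local alignment of two proteins (BLOSUM62, gap 11/1).
    Returns (score, stats)."""
    if not prot_a or not prot_b:
        raise ValueError("proteins must be non-empty")
    alignments = _prot_aligner().align(prot_a, prot_b)
    if len(alignments) == 0 or alignments.score <= 0:
        return 0.0, AlignmentStats(0.0, 0.0, 0)
    aln = alignments[0]
    return float(aln.score), _stats_from_alignment(aln, len(prot_a), len(prot_b))


def rbh_orthologs(orfs_a: OrfSet, orfs_b: OrfSet,
                  min_identity: float = 0.30,
                  min_coverage: float = 0.70) -> list[tuple[str, str, float]]:
    """Reciprocal-best-hit putative orthologs between two ORF sets.

    All-vs-all exact protein alignments; a pair qualifies when each
    protein is the other's best hit by score (ties broken by higher
    identity, then lexicographic orf_id) and the alignment passes the
    identity and shorter-protein coverage thresholds.  Returns
    (orf_a, orf_b, identity) sorted by orf_a id.
    """
    if len(orfs_a) == 0 or len(orfs_b) == 0:
        return []
    ids_a = [o.orf_id for o in orfs_a.orfs]
    ids_b = [o.orf_id for o in orfs_b.orfs]
    prots_a = orfs_a.proteins()
    prots_b = orfs_b.proteins()

    # seed-and-extend: only align protein pairs sharing at least one
    # 4-residue word (any pair passing the 30%/70% homology filters
    # shares many; unrelated pairs almost never share one)
    def words(p: str) -> frozenset:
        return frozenset(p[i:i + 4] for i in range(len(p) - 3))

    words_a = {i: words(prots_a[ia]) for i, ia in enumerate(ids_a)}
    words_b = {j: words(prots_b[jb]) for j, jb in enumerate(ids_b)}
    score = np.zeros((len(ids_a), len(ids_b)))
    ident = np.zeros_like(score)
    cover = np.zeros_like(score)
    for i, ia in enumerate(ids_a):
        for j, jb in enumerate(ids_b):
            if words_a[i].isdisjoint(words_b[j]):
                continue
            s, st = align_proteins(prots_a[ia], prots_b[jb])
            score[i, j] = s
            ident[i, j] = st.identity
            cover[i, j] = st.coverage

    def best(axis_scores, axis_idents, ids):
        order = sorted(
            range(len(axis_scores)),
            key=lambda k: (-axis_scores[k], -axis_idents[k], ids[k]),
        )
        return order[0]

    pairs = []
    for i, ia in enumerate(ids_a):
        if score[i].max() <= 0:
            continue
        j = best(score[i], ident[i], ids_b)
        i_back = best(score[:, j], ident[:, j], ids_a)
        if i_back != i:
            continue
        if ident[i, j] >= min_identity and cover[i, j] >= min_coverage:
            pairs.append((ia, ids_b[j], float(ident[i, j])))
    pairs.sort(key=lambda t: (t[0], t[1]))
    return pairs
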