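"""Pairwise intergenomic similarity, deduplication, and taxon clustering.

Whole-genome similarity between two phages is computed from non-overlapping
aligned fragments as

    similarity = 100 * 2 * (sum of identical bases) / (lenA + lenB)

together with the aligned fraction of each genome (covered length /
genome length).  Species are demarcated at 95% similarity and genera at
70%, by single-linkage clustering (connected components of the graph whose
edges join pairs at or above the threshold).

Fragments can be imported from an external aligner's tabular output, or
produced by the built-in aligner: exact k-mer seeds collected per
diagonal, with maximal ungapped scoring segments (match +2, mismatch -3,
the conventions of short-word BLASTN searches) extracted by the
Ruzzo–Tompa algorithm.  Ungapped alignment is exact for
substitution-diverged genomes; for indel-rich real genomes, import
fragments from an external aligner instead.

Deduplication treats two genomes as identical when they have equal length
and one (or its reverse complement) is a substring of the other's doubled
sequence — this also catches genomes that are 100% identical but
circularly permuted with different start positions, which plain
100%-identity clustering misses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .simulate import reverse_complement

#: Columns of a pairwise fragment table.
FRAGMENT_COLUMNS = [
    "qseqid", "sseqid", "score", "identical", "qstart", "qend", "sstart", "send",
]


@dataclass(frozen=True)
class Fragment:
    """One aligned fragment between a query and a subject genome.

    Coordinates are 1-based inclusive; ``sstart > send`` marks a
    minus-strand fragment.  ``identical`` counts identical base pairs and
    may be fractional after proportional trimming.
    """

    qstart: int
    qend: int
    sstart: int
    send: int
    identical: float
    score: float

    @property
    def q_span(self) -> tuple[int, int]:
        return self.qstart, self.qend

    @property
    def s_span(self) -> tuple[int, int]:
        return (self.sstart, self.send) if self.sstart <= self.send else (self.send, self.sstart)


@dataclass
class SimilarityMatrix:
    """Symmetric intergenomic similarity (percent) and aligned fractions."""

    ids: list[str]
    similarity: pd.DataFrame
    aligned_fraction: pd.DataFrame


@dataclass
class TaxonClusters:
    """A partition of genomes at one similarity threshold."""

    threshold: float
    clusters: list[list[str]]
    rank: str | None = None

    def membership(self) -> dict[str, int]:
        return {gid: i for i, members in enumerate(self.clusters) for gid in members}


# ---------------------------------------------------------------------------
# Deduplication

def dedupe_identical(genomes: Mapping[str, str]) -> tuple[dict[str, str], dict[str, str]]:
    """Collapse genomes identical up to rotation and/or reverse complement.

    Returns ``(representatives, duplicate_map)``: one representative per
    duplicate set (the lexicographically smallest id) and a map from every
    id to its representative.
    """
    ids = sorted(genomes)
    parent = {i: i for i in ids}

    def find(i: str) -> str:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_length: dict[int, list[str]] = {}
    for gid in ids:
        by_length.setdefault(len(genomes[gid]), []).append(gid)

    for group in by_length.values():
        for i, a in enumerate(group):
            doubled = genomes[a] + genomes[a]
            for b in group[i + 1 :]:
                if find(a) == find(b):
                    continue
                s = genomes[b]
                if s in doubled or reverse_complement(s) in doubled:
                    ra, rb = sorted((find(a), find(b)))
                    parent[rb] = ra

    dup_map = {gid: find(gid) for gid in ids}
    reps = {r: genomes[r] for r in sorted(set(dup_map.values()))}
    return reps, dup_map


# ---------------------------------------------------------------------------
# Built-in ungapped aligner

def _ruzzo_tompa(scores: np.ndarray) -> list[tuple[int, int, float]]:
    """All maximal scoring subsequences of a run-score array.

    Returns (start_run, end_run, score) triples over run indices, using
    the linear-time algorithm of maximal scoring subsequence extraction.
    """
    segs: list[list[float]] = []  # [start_run, end_run, Lcum, Rcum]
    cum = 0.0
    for k, s in enumerate(scores):
        left = cum
        cum += s
        if s <= 0:
            continue
        cur = [float(k), float(k), left, cum]
        while True:
            # rightmost existing segment j whose left cumulative is below ours
            j = None
            for t in range(len(segs) - 1, -1, -1):
                if segs[t][2] < cur[2]:
                    j = t
                    break
            if j is None or segs[j][3] >= cur[3]:
                segs.append(cur)
                break
            cur = [segs[j][0], cur[1], segs[j][2], cur[3]]
            del segs[j:]
    return [(int(s[0]), int(s[1]), float(s[3] - s[2])) for s in segs]


def _diagonal_fragments(
    a: np.ndarray, b: np.ndarray, diag: int, match: int, mismatch: int, min_score: float
) -> list[tuple[int, int, int, float]]:
    """Maximal ungapped segments on one diagonal (b_pos = a_pos + diag).

    Returns (qstart0, qend0, identical, score) tuples, 0-based inclusive
    on the query.
    """
    qs = max(0, -diag)
    qe = min(a.size, b.size - diag)
    if qe - qs <= 0:
        return []
    eq = a[qs:qe] == b[qs + diag : qe + diag]
    # run-length encode to keep the scan short
    change = np.flatnonzero(np.diff(eq.view(np.int8))) + 1
    bounds = np.concatenate([[0], change, [eq.size]])
    run_len = np.diff(bounds)
    run_val = eq[bounds[:-1]]
    run_scores = np.where(run_val, match * run_len, mismatch * run_len).astype(float)

    frags = []
    for r0, r1, score in _ruzzo_tompa(run_scores):
        if score < min_score:
            continue
        start = int(bounds[r0])
        end = int(bounds[r1 + 1]) - 1
        ident = int(eq[start : end + 1].sum())
        frags.append((qs + start, qs + end, ident, score))
    return frags


def align_pair(
    seq_a: str,
    seq_b: str,
    k: int = 13,
    match: int = 2,
    mismatch: int = -3,
    min_score: float = 50.0,
    max_kmer_hits: int = 50,
) -> list[Fragment]:
    """Ungapped fragments between two genomes via exact k-mer seeding.

    Both strands of ``seq_b`` are searched; minus-strand fragments carry
    ``sstart > send``.  Fragments below ``min_score`` are dropped, so
    unrelated random genomes yield (nearly always) no fragments.
    """
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    frags: list[Fragment] = []

    index: dict[bytes, list[int]] = {}
    raw = seq_a.encode()
    for i in range(len(raw) - k + 1):
        index.setdefault(raw[i : i + k], []).append(i)

    for strand, bs in (("+", seq_b), ("-", reverse_complement(seq_b))):
        b = np.frombuffer(bs.encode(), dtype=np.uint8)
        braw = bs.encode()
        diags: set[int] = set()
        for j in range(len(braw) - k + 1):
            hits = index.get(braw[j : j + k])
            if hits and len(hits) <= max_kmer_hits:
                for i in hits:
                    diags.add(j - i)
        for diag in sorted(diags):
            for q0, q1, ident, score in _diagonal_fragments(
                a, b, diag, match, mismatch, min_score
            ):
                s0, s1 = q0 + diag, q1 + diag
                if strand == "+":
                    sstart, send = s0 + 1, s1 + 1
                else:
                    sstart, send = len(bs) - s0, len(bs) - s1
                frags.append(Fragment(q0 + 1, q1 + 1, sstart, send, float(ident), score))
    return frags


# ---------------------------------------------------------------------------
# Overlap resolution and the similarity formula

def resolve_overlaps(fragments: list[Fragment], len_a: int, len_b: int) -> list[Fragment]:
    """Greedily admit fragments by descending score, trimming double counting.

    A later fragment only contributes the positions not already covered on
    either genome; its identical-base count is rescaled proportionally to
    the surviving fraction.  Fully redundant fragments are dropped.
    """
    mask_a = np.zeros(len_a, dtype=bool)
    mask_b = np.zeros(len_b, dtype=bool)
    out: list[Fragment] = []
    ordered = sorted(
        fragments, key=lambda f: (-f.score, f.qstart, f.qend, f.sstart, f.send)
    )
    for f in ordered:
        q0, q1 = f.q_span
        s0, s1 = f.s_span
        if q1 > len_a or s1 > len_b or q0 < 1 or s0 < 1:
            raise ValueError(f"fragment {f} outside genome bounds")
        span_q = q1 - q0 + 1
        span_s = s1 - s0 + 1
        new_q = int((~mask_a[q0 - 1 : q1]).sum())
        new_s = int((~mask_b[s0 - 1 : s1]).sum())
        t = min(new_q / span_q, new_s / span_s)
        if t <= 0:
            continue
        mask_a[q0 - 1 : q1] = True
        mask_b[s0 - 1 : s1] = True
        out.append(
            Fragment(f.qstart, f.qend, f.sstart, f.send, f.identical * t, f.score)
        )
    return out


def pairwise_similarity(
    fragments: list[Fragment], len_a: int, len_b: int
) -> tuple[float, float, float]:
    """Intergenomic similarity percent plus per-genome aligned fractions.

    ``fragments`` must already be non-overlapping on both genomes (see
    :func:`resolve_overlaps`).  similarity = 100 * 2*identical/(lenA+lenB).
    """
    if len_a <= 0 or len_b <= 0:
        raise ValueError("genome lengths must be positive")
    if not fragments:
        return 0.0, 0.0, 0.0
    mask_a = np.zeros(len_a, dtype=bool)
    mask_b = np.zeros(len_b, dtype=bool)
    total_ident = 0.0
    for f in fragments:
        q0, q1 = f.q_span
        s0, s1 = f.s_span
        if q1 > len_a or s1 > len_b or q0 < 1 or s0 < 1:
            raise ValueError(f"fragment {f} outside genome bounds")
        mask_a[q0 - 1 : q1] = True
        mask_b[s0 - 1 : s1] = True
        total_ident += f.identical
    sim = 100.0 * 2.0 * total_ident / (len_a + len_b)
    return float(min(sim, 100.0)), float(mask_a.mean()), float(mask_b.mean())


def similarity_matrix(
    genomes: Mapping[str, str],
    aligner: Callable[[str, str], list[Fragment]] | None = None,
    fragments: pd.DataFrame | None = None,
) -> SimilarityMatrix:
    """All-vs-all intergenomic similarity.

    Fragments come either from the built-in aligner (default) or from a
    precomputed table with :data:`FRAGMENT_COLUMNS` (e.g. an external
    aligner's output).  The diagonal is fixed at 100 / aligned fraction 1.
    """
    ids = sorted(genomes)
    n = len(ids)
    sim = pd.DataFrame(np.full((n, n), 0.0), index=ids, columns=ids)
    frac = pd.DataFrame(np.zeros((n, n)), index=ids, columns=ids)
    aligner = aligner or align_pair
    for i, a in enumerate(ids):
        sim.iloc[i, i] = 100.0
        frac.iloc[i, i] = 1.0
        for b in ids[i + 1 :]:
            la, lb = len(genomes[a]), len(genomes[b])
            if fragments is not None:
                pair = fragments[
                    (fragments["qseqid"] == a) & (fragments["sseqid"] == b)
                ]
                raw = [
                    Fragment(r.qstart, r.qend, r.sstart, r.send,
                             float(r.identical), float(r.score))
                    for r in pair.itertuples(index=False)
                ]
            else:
                raw = aligner(genomes[a], genomes[b])
            resolved = resolve_overlaps(raw, la, lb)
            s, fa, fb = pairwise_similarity(resolved, la, lb)
            sim.loc[a, b] = sim.loc[b, a] = s
            frac.loc[a, b] = fa
            frac.loc[b, a] = fb
    return SimilarityMatrix(ids=ids, similarity=sim, aligned_fraction=frac)


def read_fragments(path) -> pd.DataFrame:
    """Read a pairwise fragment TSV with :data:`FRAGMENT_COLUMNS`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing fragment column(s): {', '.join(missing)}")
    return df


# ---------------------------------------------------------------------------
# Clustering

def threshold_clusters(
    similarity: pd.DataFrame, threshold: float, rank: str | None = None
) -> TaxonClusters:
    """Single-linkage clusters: connected components of sim >= threshold.

    ``rank`` defaults to "species" at 95 and "genus" at 70.
    """
    mat = similarity.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-6):
        raise ValueError("similarity matrix must be symmetric")
    if rank is None:
        rank = {95.0: "species", 70.0: "genus"}.get(float(threshold))
    adj = csr_matrix(mat >= threshold)
    n_comp, labels = connected_components(adj, directed=False)
    ids = list(similarity.index)
    clusters: dict[int, list[str]] = {}
    for gid, lab in zip(ids, labels):
        clusters.setdefault(int(lab), []).append(gid)
    ordered = sorted((sorted(members) for members in clusters.values()),
                     key=lambda m: m[0])
    return TaxonClusters(threshold=float(threshold), clusters=ordered, rank=rank)
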