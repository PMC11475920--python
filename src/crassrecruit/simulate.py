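"""Synthetic genomes and viromes with known ground truth.

The simulator emulates the inputs of a fragment-recruitment study: a set of
reference phage genomes (circular dsDNA, ~100 kb in the real system),
divergent relatives obtained by substitution-only mutation, and virome read
sets drawn from those genomes at controlled relative abundances and
per-read identities, mixed with unrelated random background reads.  Because
every read's source, placement, strand and realized identity are recorded,
the ground truth can be converted directly into an alignment table
(standing in for an external aligner) and every downstream statistic can be
checked against planted values.

Model choices: substitutions only (no indels), so truth alignments always
have 100% query coverage; per-read identity is drawn uniformly on the
configured window and realized by an integer number of mismatches; reads
from circular genomes may span the origin and are reported on unwrapped
coordinates (start <= end, end possibly > genome length) with a flag.
Background reads are i.i.d. uniform bases, which with overwhelming
probability admit no full-length high-identity hit, so the truth table is
exact.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ALN_COLUMNS

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")

#: Columns of a ground-truth table (one row per simulated read).
TRUTH_COLUMNS = [
    "read_id", "source", "start", "end", "strand", "identity", "spans_origin",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _stream(seed: int, name: str) -> np.random.Generator:
    """One named, reproducible random stream derived from a global seed."""
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


@dataclass(frozen=True)
class GenomeSpec:
    """Blueprint for one synthetic reference genome.

    length is in bases (>= 1000 to leave room for read placement); gc is the
    expected G+C fraction; circular genomes allow origin-spanning reads.
    """

    id: str
    length: int
    gc: float = 0.5
    circular: bool = True

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise ValueError(f"genome {self.id!r}: length must be >= 1000")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"genome {self.id!r}: gc must be in [0, 1]")


@dataclass(frozen=True)
class ViromeSpec:
    """Blueprint for one synthetic virome (a pooled read set).

    abundances maps genome id -> non-negative sampling weight (normalized
    internally); identity_low/identity_high bound the per-read percent
    identity, drawn uniformly; background_fraction of reads are random
    sequence unrelated to any genome.
    """

    name: str
    abundances: Mapping[str, float]
    n_reads: int
    read_length: int = 150
    identity_low: float = 95.0
    identity_high: float = 100.0
    background_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0 or self.read_length <= 0:
            raise ValueError(f"virome {self.name!r}: n_reads and read_length must be positive")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError(f"virome {self.name!r}: background_fraction outside [0, 1]")
        if not (0.0 <= self.identity_low <= self.identity_high <= 100.0):
            raise ValueError(f"virome {self.name!r}: invalid identity window")
        if any(w < 0 for w in self.abundances.values()):
            raise ValueError(f"virome {self.name!r}: negative abundance weight")
        total = sum(self.abundances.values())
        if total == 0 and self.background_fraction < 1.0:
            raise ValueError(
                f"virome {self.name!r}: needs a positive abundance or background_fraction=1"
            )


def generate_genomes(specs: list[GenomeSpec], seed: int) -> dict[str, str]:
    """Generate random genome sequences with the requested length and GC.

    Deterministic for a fixed seed; each genome draws from its own named
    stream so adding genomes never perturbs existing ones.
    """
    ids = [s.id for s in specs]
    if not specs:
        raise ValueError("no genome specs given")
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ValueError(f"duplicate genome id(s): {', '.join(sorted(dup))}")
    genomes: dict[str, str] = {}
    for spec in specs:
        rng = _stream(seed, f"genome:{spec.id}")
        p_at = (1.0 - spec.gc) / 2.0
        p_gc = spec.gc / 2.0
        idx = rng.choice(4, size=spec.length, p=[p_at, p_gc, p_gc, p_at])
        genomes[spec.id] = _BASES[idx].tobytes().decode()
    return genomes


def mutate_genome(sequence: str, divergence: float, seed: int) -> str:
    """Substitution-only mutated copy at the given expected per-base divergence.

    Every A/C/G/T position is substituted to a *different* base with
    probability ``divergence`` (so divergence 1 leaves no position intact);
    non-ACGT positions are left untouched.  Length is preserved.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence must be in [0, 1], got {divergence}")
    rng = _stream(seed, "mutate")
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    idx = _BASE_INDEX[arr]
    eligible = idx >= 0
    hit = eligible & (rng.random(arr.size) < divergence)
    n = int(hit.sum())
    if n:
        offsets = rng.integers(1, 4, size=n)
        arr[hit] = _BASES[(idx[hit] + offsets) % 4]
    return arr.tobytes().decode()


def simulate_virome(
    genomes: Mapping[str, str], spec: ViromeSpec, circular: bool | Mapping[str, bool] = True
) -> tuple[list[tuple[str, str]], pd.DataFrame, int]:
    """Draw a virome read set from reference genomes plus background.

    Returns ``(reads, truth, dataset_bp)`` where reads is a list of
    ``(read_id, sequence)``, truth is a DataFrame with
    :data:`TRUTH_COLUMNS` (one row per read, background rows carry source
    ``"background"``), and ``dataset_bp`` is the summed read length.
    ``circular`` (bool, or mapping genome id -> bool) controls whether
    reads may span the replication origin.
    """
    for gid in spec.abundances:
        if gid not in genomes:
            raise KeyError(f"virome {spec.name!r}: unknown genome id {gid!r}")
    rl = spec.read_length
    sources = [g for g, w in spec.abundances.items() if w > 0]
    for gid in sources:
        if rl > len(genomes[gid]):
            raise ValueError(
                f"virome {spec.name!r}: read_length {rl} exceeds genome "
                f"{gid!r} length {len(genomes[gid])}"
            )
    weights = np.array([spec.abundances[g] for g in sources], dtype=float)
    probs = np.zeros(len(sources) + 1)
    if weights.sum() > 0:
        probs[: len(sources)] = weights / weights.sum() * (1.0 - spec.background_fraction)
    probs[-1] = spec.background_fraction
    probs = probs / probs.sum()

    rng = _stream(spec.seed, f"virome:{spec.name}")
    choice = rng.choice(len(sources) + 1, size=spec.n_reads, p=probs)
    identities = rng.uniform(spec.identity_low, spec.identity_high, size=spec.n_reads)
    strands = np.where(rng.random(spec.n_reads) < 0.5, "+", "-")

    arrays = {g: np.frombuffer(genomes[g].encode(), dtype=np.uint8) for g in sources}
    reads: list[tuple[str, str]] = []
    truth_rows: list[tuple] = []
    width = max(6, len(str(spec.n_reads)))
    for i in range(spec.n_reads):
        rid = f"{spec.name}_r{i:0{width}d}"
        if choice[i] == len(sources):  # background
            seq = _BASES[rng.integers(0, 4, size=rl)].tobytes().decode()
            reads.append((rid, seq))
            truth_rows.append((rid, "background", 0, 0, ".", np.nan, False))
            continue
        gid = sources[choice[i]]
        arr = arrays[gid]
        L = arr.size
        is_circ = circular.get(gid, True) if isinstance(circular, Mapping) else circular
        start = int(rng.integers(1, L + 1)) if is_circ else int(rng.integers(1, L - rl + 2))
        end = start + rl - 1
        spans = end > L
        if spans:
            seg = np.concatenate([arr[start - 1 :], arr[: end - L]]).copy()
        else:
            seg = arr[start - 1 : end].copy()
        n_mm = int(round((100.0 - identities[i]) * rl / 100.0))
        if n_mm:
            pos = rng.choice(rl, size=n_mm, replace=False)
            offs = rng.integers(1, 4, size=n_mm)
            seg[pos] = _BASES[(_BASE_INDEX[seg[pos]] + offs) % 4]
        realized = 100.0 * (rl - n_mm) / rl
        seq = seg.tobytes().decode()
        if strands[i] == "-":
            seq = reverse_complement(seq)
        reads.append((rid, seq))
        truth_rows.append((rid, gid, start, end, strands[i], realized, spans))

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return reads, truth, spec.n_reads * rl


def truth_to_alignments(truth: pd.DataFrame, genomes: Mapping[str, str]) -> pd.DataFrame:
    """Convert ground truth into a tabular alignment table.

    One full-length record per non-background read (pident = realized
    identity, qstart=1, qend=read length); background reads yield no
    record.  Origin-spanning reads are split into two records at the
    origin, mirroring an aligner running on a linearized reference;
    mismatches are apportioned proportionally to the two pieces.  The
    bitscore is ``2*matches - 3*mismatches`` (monotone in
    matches - mismatches).
    """
    rows: list[list] = []
    for t in truth.itertuples(index=False):
        if t.source == "background":
            continue
        L = len(genomes[t.source])
        rl = t.end - t.start + 1
        n_mm = int(round((100.0 - t.identity) * rl / 100.0))
        if not t.spans_origin:
            rows.append(_aln_row(t.read_id, t.source, rl, n_mm, 1, rl,
                                 t.start, t.end, t.strand, rl))
        else:
            len1 = L - t.start + 1
            len2 = rl - len1
            mm1 = int(round(n_mm * len1 / rl))
            mm2 = n_mm - mm1
            # piece 1 covers subject [start, L]; piece 2 covers [1, end - L]
            if t.strand == "+":
                q1, q2 = (1, len1), (len1 + 1, rl)
            else:
                q1, q2 = (rl - len1 + 1, rl), (1, len2)
            rows.append(_aln_row(t.read_id, t.source, len1, mm1, q1[0], q1[1],
                                 t.start, L, t.strand, rl))
            rows.append(_aln_row(t.read_id, t.source, len2, mm2, q2[0], q2[1],
                                 1, len2, t.strand, rl))
    df = pd.DataFrame(rows, columns=ALN_COLUMNS + ["qlen"])
    if df.empty:
        df = pd.DataFrame(columns=ALN_COLUMNS + ["qlen"])
    return df


def _aln_row(rid, gid, alen, n_mm, qstart, qend, sstart, send, strand, qlen):
    matches = alen - n_mm
    pident = round(100.0 * matches / alen, 2)
    bitscore = float(2 * matches - 3 * n_mm)
    if strand == "-":
        sstart, send = send, sstart
    return [rid, gid, pident, alen, n_mm, 0, qstart, qend, sstart, send,
            1e-30, bitscore, qlen]


@dataclass
class SimulatedStudy:
    """A full synthetic study: genomes, per-virome reads/truth/alignments."""

    genomes: dict[str, str]
    reads: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)
    alignments: pd.DataFrame | None = None
    metadata: pd.DataFrame | None = None


def simulate_study(
    genome_specs: list[GenomeSpec],
    virome_specs: list[ViromeSpec],
    seed: int,
    pools: Mapping[str, str] | None = None,
    countries: Mapping[str, str] | None = None,
) -> SimulatedStudy:
    """Generate genomes and a set of viromes; collect a combined alignment table.

    The returned study holds one alignment DataFrame with an extra
    ``virome`` column and a metadata table (pool defaults to the virome
    name, country empty unless given).
    """
    genomes = generate_genomes(genome_specs, seed)
    study = SimulatedStudy(genomes=genomes)
    aln_parts = []
    meta_rows = []
    for vs in virome_specs:
        vs = ViromeSpec(**{**vs.__dict__, "seed": seed + vs.seed})
        reads, truth, dataset_bp = simulate_virome(genomes, vs)
        aln = truth_to_alignments(truth, genomes)
        aln["virome"] = vs.name
        study.reads[vs.name] = reads
        study.truth[vs.name] = truth
        aln_parts.append(aln)
        meta_rows.append({
            "virome_name": vs.name,
            "pool": (pools or {}).get(vs.name, vs.name),
            "country": (countries or {}).get(vs.name, ""),
            "dataset_bp": dataset_bp,
            "sample_kind": "VLP",
        })
    nonempty = [p for p in aln_parts if len(p)]
    if nonempty:
        study.alignments = pd.concat(nonempty, ignore_index=True)
    elif aln_parts:
        study.alignments = aln_parts[0]
    study.metadata = pd.DataFrame(meta_rows)
    return study
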