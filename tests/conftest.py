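import numpy as np
import pandas as pd
import pytest

from crassrecruit import GenomeSpec, ViromeSpec, generate_genomes, simulate_virome
from crassrecruit.io import ALN_COLUMNS


@pytest.fixture(scope="session")
def small_genomes():
    specs = [
        GenomeSpec("gA", 10000, gc=0.5),
        GenomeSpec("gB", 10000, gc=0.4),
        GenomeSpec("gC", 12000, gc=0.55),
    ]
    return generate_genomes(specs, seed=11)


@pytest.fixture(scope="session")
def simple_virome(small_genomes):
    spec = ViromeSpec(
        "pool1", {"gA": 3.0, "gB": 1.0}, n_reads=4000,
        background_fraction=0.1, seed=5,
    )
    reads, truth, dataset_bp = simulate_virome(small_genomes, spec)
    return spec, reads, truth, dataset_bp


def make_hits(rows, qlen=100):
    """Build an alignment DataFrame from terse (qseqid, sseqid, pident,
    bitscore, sstart, send) tuples; remaining columns get consistent
    defaults."""
    recs = []
    for qseqid, sseqid, pident, bitscore, sstart, send in rows:
        alen = abs(send - sstart) + 1
        mism = round((100 - pident) * alen / 100)
        recs.append([qseqid, sseqid, pident, alen, mism, 0, 1, min(alen, qlen),
                     sstart, send, 1e-30, bitscore])
    df = pd.DataFrame(recs, columns=ALN_COLUMNS)
    df["qlen"] = qlen
    return df


# ---------------------------------------------------------------------------
# Independent brute-force oracles (per-position / per-pair computations)

def oracle_depth(hits, genome_length):
    pile = np.zeros(genome_length)
    for r in hits.itertuples(index=False):
        lo, hi = sorted((r.sstart, r.send))
        pile[lo - 1 : hi] += 1
    return pile.sum() / genome_length


def oracle_coverage(hits, genome_length):
    mask = np.zeros(genome_length, dtype=bool)
    for r in hits.itertuples(index=False):
        lo, hi = sorted((r.sstart, r.send))
        mask[lo - 1 : hi] = True
    return 100.0 * mask.sum() / genome_length


def oracle_anir(hits, weighting="length"):
    if len(hits) == 0:
        return float("nan")
    if weighting == "uniform":
        return float(np.mean(hits["pident"]))
    return float(np.average(hits["pident"], weights=hits["length"]))


def oracle_mwu(x, y):
    """Exact Mann-Whitney by direct pair counting over every labeling."""
    from itertools import combinations

    pooled = list(x) + list(y)
    n = len(x)

    def u_of(xs, ys):
        return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)

    u_x = u_of(x, y)
    u_y = u_of(y, x)
    u_obs = max(u_x, u_y)
    total = ge = 0
    for idx in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        stat = u_of(xs, ys) if u_x >= u_y else u_of(ys, xs)
        if stat >= u_obs - 1e-9:
            ge += 1
    return u_obs, min(1.0, 2.0 * ge / total)
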