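"""Per-genome fragment-recruitment statistics.

Given read-vs-genome alignments, this module applies the hit filters
(query coverage >= 70%, e-value <= 0.1, best hit per read), then computes,
per reference genome and read set:

* ``n_reads`` — recruited reads after filtering,
* ``depth_SD`` — sequencing depth, total aligned subject bases / genome
  length (mean per-base depth, x),
* ``norm_abundance`` — SD normalized by dataset size in Gbp and genome
  length in Kbp (SD/Gbp/Kbp), the unit used for all abundance comparisons,
* ``anir`` — average nucleotide identity of the mapped reads (percent;
  length-weighted by default),
* ``horizontal_coverage`` — percent of genome positions covered by at
  least one read (breadth),
* ``detected`` — whether ``norm_abundance`` reaches the detection limit
  (default 1e-5 SD/Gbp/Kbp).

Note the double length normalization in ``norm_abundance``: SD already
divides by genome length, and SD/Gbp/Kbp divides by Kbp again.  This is
the unit all comparative outputs use; plain SD/Gbp is available via
``normalize_abundance(..., per_kbp=False)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

#: Output columns of a recruitment metrics table.
METRICS_COLUMNS = [
    "genome_id", "virome", "n_reads", "depth_SD", "norm_abundance",
    "anir", "horizontal_coverage", "detected",
]


@dataclass
class FilterConfig:
    """Hit-filtering and detection thresholds.

    min_query_coverage: fraction of the read that must align (boundary
    inclusive).  max_evalue: keep hits with e-value <= this.
    plot_identity_window: percent-identity band shown in recruitment plots
    (metrics are unaffected).  detection_threshold: SD/Gbp/Kbp below which
    a genome is called undetected.  anir_weighting: "length" (identity
    weighted by aligned length, the standard definition) or "uniform"
    (plain mean over reads).
    """

    min_query_coverage: float = 0.70
    max_evalue: float = 0.1
    plot_identity_window: tuple[float, float] = (95.0, 100.0)
    detection_threshold: float = 1e-5
    anir_weighting: str = "length"

    def __post_init__(self) -> None:
        if not 0.0 < self.min_query_coverage <= 1.0:
            raise ValueError("min_query_coverage must be in (0, 1]")
        lo, hi = self.plot_identity_window
        if lo > hi:
            raise ValueError("plot_identity_window low must be <= high")
        if self.anir_weighting not in ("length", "uniform"):
            raise ValueError("anir_weighting must be 'length' or 'uniform'")


def query_coverage(hits: pd.DataFrame) -> pd.Series:
    """Fraction of each query covered by its alignment, clamped to <= 1."""
    if "qlen" not in hits.columns or hits["qlen"].isna().any():
        raise ValueError("query length (qlen) unresolved; cannot compute query coverage")
    cov = (hits["qend"] - hits["qstart"] + 1) / hits["qlen"]
    return cov.clip(upper=1.0)


def filter_hits(hits: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Keep hits with query coverage and e-value inside the cutoffs.

    Both boundaries are inclusive (coverage >= cutoff, e-value <= cutoff);
    row order is preserved.
    """
    cfg = cfg or FilterConfig()
    if hits.empty:
        return hits
    keep = (query_coverage(hits) >= cfg.min_query_coverage) & (
        hits["evalue"] <= cfg.max_evalue
    )
    return hits[keep]


def best_hit(hits: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Keep, per query, the single hit with the highest bitscore.

    Ties break on higher pident, then lexicographically smaller sseqid,
    then subject coordinates, making the result independent of input
    order.  ``by`` defaults to ``["qseqid"]``; pass
    ``["virome", "qseqid"]`` for multi-virome tables.
    """
    if hits.empty:
        return hits
    by = by or ["qseqid"]
    ordered = hits.sort_values(
        by + ["bitscore", "pident", "sseqid", "sstart", "send"],
        ascending=[True] * len(by) + [False, False, True, True, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates(subset=by, keep="first")


def subject_intervals(hits: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(start, end) arrays of subject intervals normalized to start <= end."""
    lo = np.minimum(hits["sstart"].to_numpy(), hits["send"].to_numpy())
    hi = np.maximum(hits["sstart"].to_numpy(), hits["send"].to_numpy())
    return lo, hi


def sequencing_depth(hits: pd.DataFrame, genome_length: int) -> float:
    """Mean per-base depth: summed aligned subject spans / genome length."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if hits.empty:
        return 0.0
    lo, hi = subject_intervals(hits)
    return float((hi - lo + 1).sum() / genome_length)


def normalize_abundance(
    depth_sd: float, dataset_bp: int, genome_length: int, per_kbp: bool = True
) -> float:
    """Normalize SD by dataset size (Gbp) and, by default, genome length (Kbp)."""
    if dataset_bp <= 0:
        raise ValueError("dataset_bp must be positive")
    out = depth_sd / (dataset_bp / 1e9)
    if per_kbp:
        out /= genome_length / 1e3
    return float(out)


def anir(hits: pd.DataFrame, weighting: str = "length") -> float:
    """Average nucleotide identity of mapped reads (percent).

    ``length`` weights each hit's identity by its aligned length (the
    standard ANIr); ``uniform`` is the plain mean over hits.  Returns NaN
    when there are no hits.
    """
    if hits.empty:
        return float("nan")
    pid = hits["pident"].to_numpy(dtype=float)
    if weighting == "uniform":
        return float(pid.mean())
    if weighting == "length":
        w = hits["length"].to_numpy(dtype=float)
        return float((pid * w).sum() / w.sum())
    raise ValueError(f"unknown ANIr weighting {weighting!r}")


def horizontal_coverage(hits: pd.DataFrame, genome_length: int) -> float:
    """Percent of genome positions covered by >= 1 hit (overlaps counted once)."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if hits.empty:
        return 0.0
    lo, hi = subject_intervals(hits)
    if lo.min() < 1 or hi.max() > genome_length:
        raise ValueError(
            "subject interval outside [1, genome_length]; unwrap circular "
            "coordinates upstream"
        )
    order = np.argsort(lo, kind="stable")
    lo, hi = lo[order], hi[order]
    covered = 0
    cur_lo, cur_hi = int(lo[0]), int(hi[0])
    for s, e in zip(lo[1:], hi[1:]):
        if s <= cur_hi + 1:
            cur_hi = max(cur_hi, int(e))
        else:
            covered += cur_hi - cur_lo + 1
            cur_lo, cur_hi = int(s), int(e)
    covered += cur_hi - cur_lo + 1
    return float(100.0 * covered / genome_length)


def recruitment_profile(
    hits: pd.DataFrame,
    genome_length: int,
    window: tuple[float, float] = (95.0, 100.0),
) -> pd.DataFrame:
    """Plot-ready table (subject midpoint vs identity) restricted to a window.

    One row per hit with pident inside the inclusive window; hits outside
    the window are excluded from the plot table only, never from metrics.
    """
    if hits.empty:
        return pd.DataFrame(columns=["position", "pident"])
    lo, hi = subject_intervals(hits)
    mid = (lo + hi) / 2.0
    pid = hits["pident"].to_numpy(dtype=float)
    keep = (pid >= window[0]) & (pid <= window[1])
    return pd.DataFrame({"position": mid[keep], "pident": pid[keep]})


def detection_call(norm_abundance: float, cfg: FilterConfig | None = None) -> bool:
    """Detected iff normalized abundance reaches the detection limit (inclusive)."""
    cfg = cfg or FilterConfig()
    return bool(norm_abundance >= cfg.detection_threshold)


def genome_metrics(
    hits: pd.DataFrame, genome_length: int, dataset_bp: int, cfg: FilterConfig
) -> dict:
    """All per-genome metrics from already filtered, best-hit resolved hits."""
    sd = sequencing_depth(hits, genome_length)
    norm = normalize_abundance(sd, dataset_bp, genome_length)
    return {
        "n_reads": int(len(hits)),
        "depth_SD": sd,
        "norm_abundance": norm,
        "anir": anir(hits, cfg.anir_weighting),
        "horizontal_coverage": horizontal_coverage(hits, genome_length),
        "detected": detection_call(norm, cfg),
    }


def recruitment_table(
    alignments: pd.DataFrame,
    genome_lengths: Mapping[str, int],
    metadata: pd.DataFrame,
    cfg: FilterConfig | None = None,
    group_by: str = "virome",
) -> pd.DataFrame:
    """Per-(genome, group) metrics table from a combined alignment table.

    ``alignments`` must carry a ``virome`` column naming the read set of
    each hit.  ``group_by`` is ``"virome"`` for per-virome metrics or a
    metadata column (``"pool"``, ``"country"``) to pool viromes: pooled
    metrics are recomputed from the concatenated hit set with dataset_bp
    summed, never by averaging per-virome values.  Filtering order is
    coverage/e-value filter, then best hit per read within its virome.
    One row is emitted per genome per group, zero-filled when nothing
    recruited.
    """
    cfg = cfg or FilterConfig()
    if "virome" not in alignments.columns:
        raise ValueError("alignments table needs a 'virome' column")
    meta = metadata.set_index("virome_name")
    if group_by == "virome":
        groups = {v: [v] for v in meta.index}
    else:
        if group_by not in metadata.columns:
            raise ValueError(f"metadata has no column {group_by!r}")
        groups = {
            name: list(sub.index) for name, sub in meta.groupby(group_by) if name != ""
        }

    hits = filter_hits(alignments, cfg)
    hits = best_hit(hits, by=["virome", "qseqid"])

    rows = []
    for gname, members in sorted(groups.items()):
        dataset_bp = int(meta.loc[members, "dataset_bp"].sum())
        ghits = hits[hits["virome"].isin(members)]
        for gid in sorted(genome_lengths):
            sub = ghits[ghits["sseqid"] == gid]
            row = {"genome_id": gid, "virome": gname}
            row.update(genome_metrics(sub, genome_lengths[gid], dataset_bp, cfg))
            rows.append(row)
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def coverage_matrix(metrics: pd.DataFrame) -> pd.DataFrame:
    """Pivot a metrics table into a phage x group horizontal-coverage matrix."""
    return metrics.pivot(
        index="genome_id", columns="virome", values="horizontal_coverage"
    ).rename_axis(index="phage", columns=None)
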