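"""Per-country aggregation of recruitment results.

Viromes are pooled by origin: within each country (or cohort) the hit sets
are concatenated and the dataset sizes summed, and every recruitment
metric is recomputed on the pooled data — never averaged across viromes,
which would reintroduce Simpson-type artifacts.  Each country profile then
reports, per phage, the pooled normalized abundance (SD/Gbp/Kbp), the
within-country share of total detected abundance, and how many of the
country's metagenomes detected at least one phage.

Cohorts from the same country (e.g. two independent USA collections)
should be given distinct labels in the grouping column; they are never
merged by name.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .recruitment import FilterConfig, recruitment_table

logger = logging.getLogger(__name__)

#: Columns of a country-profile table (long format, one row per country x phage).
PROFILE_COLUMNS = [
    "country", "phage", "abundance", "share", "detected",
    "n_metagenomes", "n_metagenomes_with_detection",
]


def pool_by_country(
    alignments: pd.DataFrame,
    metadata: pd.DataFrame,
    genome_lengths: Mapping[str, int],
    cfg: FilterConfig | None = None,
    key: str = "country",
) -> pd.DataFrame:
    """Country profiles from a combined alignment table plus metadata.

    Viromes with an empty value in the grouping column are excluded with a
    logged warning.  Shares are percentages of the summed abundance of
    *detected* phages within the country (phages below the detection
    threshold contribute 0); they sum to 100 per country unless nothing
    was detected, in which case all shares are 0.
    """
    cfg = cfg or FilterConfig()
    missing = metadata[metadata[key].astype(str).str.len() == 0]
    if len(missing):
        logger.warning(
            "%d virome(s) without %s metadata excluded: %s",
            len(missing), key, ", ".join(missing["virome_name"]),
        )
    meta = metadata[metadata[key].astype(str).str.len() > 0]

    pooled = recruitment_table(alignments, genome_lengths, meta, cfg, group_by=key)
    per_virome = recruitment_table(alignments, genome_lengths, meta, cfg, group_by="virome")
    detect_by_virome = (
        per_virome.groupby("virome")["detected"].any().rename("any_detected")
    )
    vmeta = meta.set_index("virome_name")

    rows = []
    for country, sub in pooled.groupby("virome"):
        members = vmeta.index[vmeta[key] == country]
        n_meta = len(members)
        n_det = int(detect_by_virome.reindex(members).fillna(False).sum())
        detected_total = sub.loc[sub["detected"], "norm_abundance"].sum()
        for r in sub.itertuples(index=False):
            share = (
                100.0 * r.norm_abundance / detected_total
                if r.detected and detected_total > 0
                else 0.0
            )
            rows.append({
                "country": country,
                "phage": r.genome_id,
                "abundance": r.norm_abundance,
                "share": share,
                "detected": bool(r.detected),
                "n_metagenomes": n_meta,
                "n_metagenomes_with_detection": n_det,
            })
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def prevalence(per_virome_metrics: pd.DataFrame) -> tuple[float, float, int, int]:
    """Fraction of metagenomes recruiting at least one phage.

    Returns ``(percent_detected, percent_below_detection, n_detected,
    n_total)`` from a per-virome metrics table with ``virome`` and
    ``detected`` columns.
    """
    by_virome = per_virome_metrics.groupby("virome")["detected"].any()
    n_total = int(by_virome.size)
    if n_total == 0:
        return 0.0, 0.0, 0, 0
    n_det = int(by_virome.sum())
    pct = 100.0 * n_det / n_total
    return pct, 100.0 - pct, n_det, n_total


def rank_phages(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Global abundance ranking and per-country top phage.

    The global ranking sums pooled abundances over countries; ties break
    on phage id, so the result is independent of input row order.
    """
    if profiles.empty:
        raise ValueError("no country profiles given")
    glob = (
        profiles.groupby("phage", as_index=False)["abundance"].sum()
        .sort_values(["abundance", "phage"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    glob["rank"] = range(1, len(glob) + 1)

    tops = []
    for country, sub in profiles.groupby("country"):
        sub = sub.sort_values(["abundance", "phage"], ascending=[False, True],
                              kind="mergesort")
        tops.append({
            "country": country,
            "top_phage": sub["phage"].iloc[0],
            "abundance": sub["abundance"].iloc[0],
        })
    return glob, pd.DataFrame(tops)
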