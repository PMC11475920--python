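"""Human-specificity classification and the exact Mann–Whitney U test.

A phage is a *candidate* human marker when its horizontal genome coverage
exceeds a threshold (default 40%) in every designated human pool
(human gut, and human urine when present).  Candidates are then classified
by how many animal pools also show coverage above the threshold:

* ``HIGH`` — above threshold in no animal pool (highly human-specific),
* ``QUITE`` — above threshold in some but not all animal pools,
* ``EXCLUDED`` — above threshold in every animal pool (not human-specific),
* ``NOT_CANDIDATE`` — failed the human-pool threshold.

Threshold semantics follow "more than 40%": strictly greater on both the
human and the animal side, so a value of exactly 40.0 counts as absent.

The module also provides the exact (enumeration-based) Mann–Whitney U test
used to compare fecal-indicator concentrations between high- and
low-fecal-load sample groups; with 4 vs 5 completely separated samples it
gives U = 20.0 and a two-sided P of 2/126 ~= 0.0159.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata

HIGH = "HIGH"
QUITE = "QUITE"
EXCLUDED = "EXCLUDED"
NOT_CANDIDATE = "NOT_CANDIDATE"

#: Output columns of a specificity-call table.
CALL_COLUMNS = ["phage", "call", "n_animal_pools_present"]


def _check_columns(matrix: pd.DataFrame, cols: list[str], kind: str) -> None:
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise KeyError(f"unknown {kind} column(s): {', '.join(missing)}")


def select_candidates(
    matrix: pd.DataFrame, human_cols: list[str], threshold: float = 40.0
) -> list[str]:
    """Phages with coverage strictly above the threshold in every human pool."""
    _check_columns(matrix, human_cols, "human pool")
    mask = (matrix[human_cols] > threshold).all(axis=1)
    return list(matrix.index[mask])


def classify(
    matrix: pd.DataFrame,
    human_cols: list[str],
    animal_cols: list[str],
    threshold: float = 40.0,
) -> pd.DataFrame:
    """Classify each phage of a coverage matrix by human specificity.

    ``matrix`` is a phage x pool table of horizontal-coverage percentages.
    Returns a DataFrame with :data:`CALL_COLUMNS`, in matrix row order.
    """
    if not animal_cols:
        raise ValueError("at least one animal pool column is required")
    _check_columns(matrix, human_cols, "human pool")
    _check_columns(matrix, animal_cols, "animal pool")
    bad = matrix[human_cols + animal_cols]
    if ((bad < 0) | (bad > 100)).any().any():
        raise ValueError("coverage values must be percentages in [0, 100]")

    candidates = set(select_candidates(matrix, human_cols, threshold))
    rows = []
    for phage in matrix.index:
        n_animal = int((matrix.loc[phage, animal_cols] > threshold).sum())
        if phage not in candidates:
            call = NOT_CANDIDATE
        elif n_animal == 0:
            call = HIGH
        elif n_animal == len(animal_cols):
            call = EXCLUDED
        else:
            call = QUITE
        rows.append({"phage": phage, "call": call, "n_animal_pools_present": n_animal})
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Exact Mann–Whitney U test by full enumeration of group labelings.

    ``U`` is the larger of the two one-sided statistics, counting each
    pair (x_i, y_j) as 1 if x_i > y_j and 0.5 on ties.  The two-sided P
    doubles the one-sided tail of the side that attained the maximum:
    ``min(1, 2 * Pr(U' >= U))`` with U' that side's statistic under a
    uniformly random relabeling, enumerated over all C(n+m, n)
    assignments.  Suitable for small groups (both sizes <= 12); with 4 vs
    5 completely separated values this yields U = 20, P = 2/126.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    total = comb(n + m, n)
    if total > 3_000_000:
        raise ValueError(
            f"group sizes {n} vs {m} are outside the exact enumeration regime"
        )

    combined = np.concatenate([x, y])
    ranks = rankdata(combined)  # midranks handle ties as 0.5 per pair
    offset = n * (n + 1) / 2.0
    u_x = float(ranks[:n].sum() - offset)
    u_y = float(n * m - u_x)
    u_obs = max(u_x, u_y)

    x_side = u_x >= u_y  # measure the tail on the side that attained the max
    ge = 0
    for idx in combinations(range(n + m), n):
        u_perm = ranks[list(idx)].sum() - offset
        if not x_side:
            u_perm = n * m - u_perm
        if u_perm >= u_obs - 1e-9:
            ge += 1
    p = min(1.0, 2.0 * ge / total)
    return u_obs, p
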