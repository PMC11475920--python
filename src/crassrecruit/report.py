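"""Reporting helpers: printed percentages and simple figures."""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def percent(k: int, n: int, sig: int = 3) -> float:
    """Percentage k/n rounded to ``sig`` significant figures.

    Matches the convention of printed summary fractions, e.g.
    4/67 -> 5.97, 9/67 -> 13.4, 28/67 -> 41.8.
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    value = 100.0 * k / n
    if value == 0:
        return 0.0
    digits = sig - 1 - math.floor(math.log10(abs(value)))
    return round(value, digits)


def plot_recruitment(
    profile: pd.DataFrame,
    genome_length: int,
    path,
    window: tuple[float, float] = (95.0, 100.0),
    title: str | None = None,
) -> None:
    """Fragment-recruitment plot: read identity vs genome position."""
    fig, ax = plt.subplots(figsize=(8, 2.5))
    ax.scatter(profile["position"], profile["pident"], s=2, c="black", alpha=0.5)
    ax.set_xlim(0, genome_length)
    ax.set_ylim(*window)
    ax.set_xlabel("genome position (bp)")
    ax.set_ylabel("read identity (%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_abundance(profiles: pd.DataFrame, path) -> None:
    """Bar chart of normalized abundance per phage, one panel per country."""
    countries = sorted(profiles["country"].unique())
    fig, axes = plt.subplots(
        len(countries), 1, figsize=(8, 2.2 * max(1, len(countries))), squeeze=False
    )
    for ax, country in zip(axes[:, 0], countries):
        sub = profiles[profiles["country"] == country]
        ax.bar(sub["phage"], sub["abundance"], color="steelblue")
        ax.set_ylabel("SD/Gbp/Kbp")
        ax.set_title(country)
        ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
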