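"""Small bundled example datasets.

The example coverage matrix lists horizontal genome coverage (%) for 13
human-associated crAss-like phages — the isolated phages crAssBcn3,
crAss001, crAss002, DAC15 and DAC17 plus eight uncultured genomes — across
four pooled viromes: human gut, urban wastewater, and poultry feces from
Spain and from China.  It is the canonical worked example for the
human-specificity decision rule: at the 40% threshold, with the human-gut
pool as the human column and the two poultry pools as animal columns, it
yields exactly four HIGH and nine QUITE calls.
"""

from __future__ import annotations

import pandas as pd

HUMAN_COLS = ["human_gut"]
ANIMAL_COLS = ["poultry_spain", "poultry_china"]

_COVERAGE_ROWS = [
    # phage, human_gut, urban_ww, poultry_spain, poultry_china
    ("crAssBcn3", 74.0, 69.0, 26.2, 67.8),
    ("crAss001", 67.3, 67.1, 26.4, 64.7),
    ("crAss002", 90.3, 9.8, 88.2, 7.0),
    ("DAC15", 70.1, 6.0, 2.8, 2.3),
    ("DAC17", 71.4, 6.1, 2.4, 2.3),
    ("cr112", 49.1, 51.2, 23.4, 48.1),
    ("cr53", 66.7, 27.8, 79.2, 12.3),
    ("cr50", 47.6, 19.9, 82.0, 16.6),
    ("cr85", 98.1, 38.9, 24.1, 4.6),
    ("cr6", 90.9, 24.4, 96.2, 13.7),
    ("cr12", 91.9, 25.6, 98.0, 16.8),
    ("cr107", 90.2, 9.0, 78.1, 7.9),
    ("cr17", 93.5, 7.0, 11.6, 0.9),
]


def example_coverage_matrix() -> pd.DataFrame:
    """Phage x pool horizontal-coverage matrix for 13 human crAss-like phages."""
    df = pd.DataFrame(
        _COVERAGE_ROWS,
        columns=["phage", "human_gut", "urban_ww", "poultry_spain", "poultry_china"],
    )
    return df.set_index("phage")
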