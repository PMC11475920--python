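"""Apply the human-specificity decision rule and the fecal-indicator test.

Classifies the bundled 13-phage horizontal-coverage matrix (human gut +
two poultry pools, 40% threshold) and runs the exact Mann-Whitney U test
comparing fecal-indicator concentrations between high- and low-fecal-load
sample groups.
"""

from crassrecruit import classify, mann_whitney_exact
from crassrecruit.datasets import ANIMAL_COLS, HUMAN_COLS, example_coverage_matrix

matrix = example_coverage_matrix()
calls = classify(matrix, HUMAN_COLS, ANIMAL_COLS, threshold=40.0)
print(calls.to_string(index=False))
print()
print("Call counts:", calls["call"].value_counts().to_dict())
print(
    "HIGH phages exceed 40% genome coverage in the human gut but in neither\n"
    "poultry virome; QUITE phages exceed it in exactly one poultry virome."
)

# E. coli concentrations (log CFU-like units): 4 high- vs 5 low-load samples
high_load = [6.2, 5.8, 6.9, 5.5]   # human gut, urine, two wastewater pools
low_load = [1.1, 0.8, 1.9, 0.4, 1.5]  # soil, meat, fish, vegetable, dairy
u, p = mann_whitney_exact(high_load, low_load)
print(f"\nMann-Whitney U = {u:.1f}, two-sided exact p = {p:.5f}")
print(
    "Complete separation of 4 vs 5 samples gives the maximal U of 20 and\n"
    "p = 2/126 ~= 0.0159: the fecal loads differ significantly."
)
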