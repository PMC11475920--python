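# crassrecruit

Fragment-recruitment analysis of crAss-like phages (order *Crassvirales*)
in viromes: who is present, how abundant, and how human-specific.

crAss-like phages are ~100 kb circular dsDNA bacteriophages of
*Bacteroides* that dominate the human gut virome, which makes them
attractive markers for tracking human fecal pollution — but only the
members that are genuinely human-specific. `crassrecruit` implements the
complete analysis chain used to find them:

1. **Recruitment statistics.** Metagenomic reads aligned against complete
   phage genomes are filtered (query coverage ≥ 70%, e-value ≤ 0.1, best
   hit per read), then summarized per genome and read set as sequencing
   depth `SD = Σ aligned bases / L`, normalized abundance
   `SD/Gbp/Kbp = SD / (dataset_bp/10⁹) / (L/10³)`, ANIr (average
   nucleotide identity of mapped reads, length-weighted), and horizontal
   coverage (percent of genome positions hit at least once). A genome
   counts as detected at ≥ 10⁻⁵ SD/Gbp/Kbp.
2. **Human-specificity rule.** From a phage × pool coverage matrix,
   phages with > 40% horizontal coverage in every human pool are
   candidates; candidates above 40% in no animal pool are `HIGH`
   (highly human-specific), in some but not all animal pools `QUITE`, in
   all animal pools `EXCLUDED`. An exact (enumeration-based) Mann–Whitney
   U test compares fecal-indicator concentrations between sample groups.
3. **Intergenomic taxonomy.** Pairwise whole-genome similarity
   `100 · 2·(identical bases) / (L_A + L_B)` from non-overlapping aligned
   fragments, duplicate removal that catches circularly permuted
   identical genomes, and single-linkage clustering at the 95% species /
   70% genus demarcations.
4. **Biogeography.** Per-country pooling (hits concatenated, dataset
   sizes summed — never averaged), abundance shares, prevalence, and
   phage rankings.
5. **Synthetic data.** A simulator generates reference genomes, divergent
   relatives, and virome read sets with planted abundances, identities
   (e.g. uniform on 95–100%), strands, origin-spanning reads and random
   background, together with ground-truth alignments — so the whole
   pipeline runs and is validated offline without an external aligner.

## Worked example

```python
from crassrecruit import classify, mann_whitney_exact
from crassrecruit.datasets import example_coverage_matrix, HUMAN_COLS, ANIMAL_COLS

calls = classify(example_coverage_matrix(), HUMAN_COLS, ANIMAL_COLS, threshold=40.0)
print(calls["call"].value_counts().to_dict())
u, p = mann_whitney_exact([6.2, 5.8, 6.9, 5.5], [1.1, 0.8, 1.9, 0.4, 1.5])
print(u, round(p, 5))
```

prints

```
{'QUITE': 9, 'HIGH': 4}
20.0 0.01587
```

Of the 13 bundled human-associated phages, exactly four (DAC15, DAC17,
cr85, cr17) exceed 40% genome coverage in the human gut while staying
below it in both poultry viromes (`HIGH`); the other nine are above 40%
in exactly one poultry virome (`QUITE`). The Mann–Whitney example shows 4
high- vs 5 low-fecal-load samples with complete separation: U is maximal
at 4·5 = 20 and the exact two-sided P is 2/126 ≈ 0.0159.

The `examples/` directory holds one narrative script per capability
(simulation + recruitment, specificity, intergenomic clustering,
biogeography); each prints its results with a short interpretation. A
thin CLI (`crassrecruit --config run.yaml simulate|recruit|classify|
similarity|biogeo|report`) orchestrates the same functions over files on
disk, writing TSV tables, a checksum manifest, and figures.

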