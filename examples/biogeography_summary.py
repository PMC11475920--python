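"""Country-pooled abundance, prevalence, and phage rankings.

Simulates gut viromes from two countries with different planted phage
mixtures, pools the recruitment per country, and prints abundance shares,
the fraction of metagenomes with any detection, and the global ranking.
"""

from crassrecruit import (
    GenomeSpec, ViromeSpec, percent, pool_by_country, prevalence,
    rank_phages, recruitment_table, simulate_study,
)

specs = [GenomeSpec(p, 10000) for p in ("cr_x", "cr_y", "cr_z")]
viromes = [
    ViromeSpec("ES_1", {"cr_x": 5.0, "cr_y": 1.0}, 4000, seed=0),
    ViromeSpec("ES_2", {"cr_x": 4.0, "cr_y": 2.0}, 4000, seed=1),
    ViromeSpec("IE_1", {"cr_y": 3.0, "cr_z": 1.0}, 4000, seed=2),
    ViromeSpec("IE_2", {}, 4000, background_fraction=1.0, seed=3),  # no phages
]
countries = {"ES_1": "Spain", "ES_2": "Spain", "IE_1": "Ireland", "IE_2": "Ireland"}
study = simulate_study(specs, viromes, seed=11, countries=countries)
lengths = {g: 10000 for g in study.genomes}

profiles = pool_by_country(study.alignments, study.metadata, lengths)
print(profiles.round(3).to_string(index=False))

per_virome = recruitment_table(study.alignments, lengths, study.metadata)
pct, below, n_det, n_total = prevalence(per_virome)
print(f"\nprevalence: {n_det}/{n_total} metagenomes with >=1 phage "
      f"({percent(n_det, n_total)}%), {below:.1f}% below detection")

glob, tops = rank_phages(profiles)
print("\nglobal abundance ranking:")
print(glob.round(3).to_string(index=False))
print("\ntop phage per country:")
print(tops.round(3).to_string(index=False))
print(
    "\nShares sum to 100% within each country over detected phages; the\n"
    "background-only virome contributes to the metagenome count but not\n"
    "to detections, so prevalence is below 100%."
)
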