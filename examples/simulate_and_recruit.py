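"""Simulate a small virome study and compute recruitment metrics.

Two reference phages are planted in a human-gut virome at a 3:1 abundance
ratio with 10% unrelated background reads; the per-genome metrics table
shows how read counts translate into sequencing depth (SD), normalized
abundance (SD/Gbp/Kbp), ANIr and horizontal coverage.
"""

from crassrecruit import (
    FilterConfig, GenomeSpec, ViromeSpec, recruitment_table, simulate_study,
)

study = simulate_study(
    genome_specs=[GenomeSpec("phageA", 20000), GenomeSpec("phageB", 20000)],
    virome_specs=[
        ViromeSpec(
            "human_gut", {"phageA": 3.0, "phageB": 1.0}, n_reads=8000,
            background_fraction=0.1,
        )
    ],
    seed=7,
)

lengths = {gid: len(seq) for gid, seq in study.genomes.items()}
metrics = recruitment_table(study.alignments, lengths, study.metadata, FilterConfig())
print(metrics.round(4).to_string(index=False))
print()
print(
    "phageA was planted 3x more abundant than phageB: its depth_SD and\n"
    "norm_abundance are ~3x higher, both genomes are fully covered\n"
    "(horizontal_coverage ~100%), and ANIr sits near 97.5, the midpoint of\n"
    "the simulated 95-100% read-identity window."
)
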