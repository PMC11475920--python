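# Methods

## Recruitment model

The unit of observation is one local alignment of a virome read against a
complete phage genome (the standard 12-column tabular dialect, 1-based
inclusive coordinates, `sstart > send` marking the minus strand). Three
filters are applied, in this order, before any statistic is computed:

1. **Query-length resolution.** The 12-column dialect does not carry the
   read length, which the coverage filter needs; a 13th column, a lookup
   into the reads FASTA/FASTQ, or a constant supplies it, and an
   unresolvable read is an error rather than a silent pass.
2. **Coverage / e-value filter.** Keep hits with
   `(qend − qstart + 1)/qlen ≥ 0.70` and `e-value ≤ 0.1`, both boundaries
   inclusive. The e-value cutoff is interpreted as an upper bound; a
   filter keeping only *poor* hits would discard exactly the alignments
   the analysis is about. Both thresholds are configurable.
3. **Best hit.** Per read, the hit with the highest bitscore survives;
   ties break on higher identity, then lexicographically smaller subject
   id, then subject coordinates, so the result is independent of input
   order.

Per genome and read set the package reports:

* **Sequencing depth** `SD = Σ |send − sstart| + 1 / L` — mean per-base
  depth. Spans are measured on the subject; gap columns are ignored.
* **Normalized abundance** `SD/Gbp/Kbp = SD / (dataset_bp/10⁹) / (L/10³)`.
  This double length normalization (SD already divides by `L`) is kept
  exactly as stated because it is the unit in which all comparative
  results are expressed; `normalize_abundance(per_kbp=False)` exposes
  plain SD/Gbp.
* **ANIr** — identity of the mapped reads, length-weighted by default
  (the standard definition; each aligned base votes once). A uniform
  per-read mean is available since the field's verbal definition
  ("average identity of mapped reads") is ambiguous between the two; on
  fixed-length reads they coincide.
* **Horizontal coverage** — percent of genome positions covered at least
  once (interval union, overlaps counted once). Intervals beyond the
  genome end are an error: circular coordinates must be unwrapped
  upstream, which the simulator's alignment export does by splitting
  origin-spanning reads into two records.
* **Detection** at `norm_abundance ≥ 10⁻⁵` SD/Gbp/Kbp (inclusive).

Pooled metrics (per sample pool or per country) are always recomputed
from the concatenated hit set with dataset sizes summed. Averaging
per-virome values would weight small datasets as heavily as large ones
and break the linearity of SD in aligned bases. Coverage matrices fed to
the specificity classifier are produced from pooled recruitment.

## Specificity rule

"Present" means horizontal coverage strictly above the threshold
(default 40%); 40.0 exactly counts as absent, matching the strict
reading of "more than 40%". The 40% default is deliberately stringent
for ~100 kb genomes: a single conserved gene can cover ~10% of a phage
genome, so low-breadth recruitment does not establish presence. When a
human-urine column is designated alongside human gut, both must pass;
with only a gut column, gut alone decides. Classification counts animal
pools above the threshold: none → `HIGH`, all → `EXCLUDED`, otherwise
`QUITE`; non-candidates are `NOT_CANDIDATE` regardless of animal columns.

The Mann–Whitney U test is exact: `U` is the larger one-sided statistic
(ties count 0.5 per pair) and the two-sided P doubles the tail of the
side that attained the maximum, enumerated over all `C(n+m, n)`
labelings and capped at 1. Doubling the attained side's tail (rather
than the tail of a fixed group) keeps P in (0, 1] under asymmetric ties
and reduces to the textbook doubled one-sided tail whenever there are no
ties. The enumeration is limited to group sizes whose labeling count
stays around 3·10⁶ (both groups ≤ 12); larger samples should use an
asymptotic test, which is out of scope here.

## Intergenomic similarity and clustering

Similarity between genomes A and B is
`100 · 2·(Σ identical bases) / (L_A + L_B)` over fragments that are
non-overlapping on both genomes, with per-genome aligned fractions from
the coverage union. Overlap resolution is greedy by descending fragment
score; a later fragment contributes only its uncovered positions and its
identical-base count is rescaled by the surviving fraction — an
approximation that is exact when identities are uniform along the
fragment. Two full-length genomes at substitution divergence *d* get
similarity ≈ 100·(1 − d), which is what makes the 95%/70% demarcations
behave like ~5%/~30% divergence cutoffs.

The built-in pairwise aligner is deliberately simple and exact for the
substitution-only world of the simulator: shared k-mers (k = 13, skipping
seeds occurring > 50 times) nominate diagonals; on each diagonal the
match/mismatch profile is run-length encoded and all maximal scoring
segments (match +2, mismatch −3, minimum score 50) are extracted with the
Ruzzo–Tompa algorithm; both strands are searched. It does not model
gaps — real, indel-containing genome pairs should be compared with an
external aligner whose fragments are imported through the fragment-table
route (`similarity_matrix(..., fragments=...)`), which is the supported
path for faithful runs on real genomes.

Duplicate genomes are collapsed before clustering: equal length and one
sequence (or its reverse complement) being a substring of the other's
doubled sequence means the two are the same circular genome written from
different start positions. Clustering is single-linkage (connected
components at the threshold); chaining can in principle merge borderline
species, which mirrors the behavior of threshold-based intergenomic
clustering tools. Cluster sets at a higher threshold always nest inside
those at a lower one.

## Synthetic data: what it emulates and what it does not

The simulator emulates pooled viromes as mixtures of fixed-length reads
drawn from reference genomes at planted relative weights, with per-read
identity uniform on a configured window (default 95–100%, realized by an
integer mismatch count and re-reported exactly), random strand, circular
placement with origin-spanning reads unwrapped in truth coordinates, and
i.i.d.-uniform background reads that cannot produce full-length
high-identity hits. Defaults: 150 bp reads (public gut viromes mix many
platforms and no single read-length distribution is canonical; a fixed
length keeps per-read coverage oracles exact), identity window 95–100%
matching the identity band displayed in recruitment plots, detection
limit 10⁻⁵ SD/Gbp/Kbp, thresholds 70% coverage / 0.1 e-value / 40%
breadth / 95 and 70% demarcation.

Not modeled: indels (so truth alignments always have 100% query
coverage), chimeras, duplicate reads, quality-score error profiles,
paired ends, and amplification (MDA) bias. Passing tests therefore show
that the statistics and decision rules are computed correctly and
recover planted signal under clean mapping; they do not certify
robustness to alignment artifacts or library-preparation biases in real
viromes.

Randomness: one global seed; every genome, mutation call and virome
draws from its own named stream (seed + CRC32 of the stream name via a
numpy `SeedSequence`), so regenerating a subset of the study never
perturbs the rest, and the whole pipeline is byte-reproducible.

## Problem sizes in the test suite

The validation suite runs on deliberately small instances chosen to make
the statistical checks sharp: genomes of 10–20 kb, viromes of 2 000–50
000 reads. The abundance-recovery check plants a 100× weight gradient
over ten genomes and uses 50 000 reads so that the rarest genome still
receives ~200 reads, keeping pairwise abundance-ratio noise well inside
the 15% acceptance band; ANIr recovery uses 2 000 reads (standard error
~0.03 points against a 0.3-point band). The end-to-end specificity check
plants human-only, shared and animal-only phages at 20 000 reads per
pool, which saturates horizontal coverage for present phages and leaves
absent phages at zero.

## Known limitations

* The built-in aligner is ungapped; indel-diverged pairs under-score
  (external fragments are the remedy).
* Overlap trimming rescales identical counts proportionally rather than
  recounting per-position identity on the trimmed interval.
* Exact Mann–Whitney is restricted to the enumeration regime.
* Pooling assumes read ids are unique within each virome; best-hit
  resolution is applied within viromes, never across them.
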