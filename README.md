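# oligotyper

Entropy-based oligotyping of aligned 16S rRNA amplicon reads, with
reference-based clade assignment and environmental correlate analysis —
built for microbial ecologists studying fine-scale (sub-OTU) diversity in
time-series survey data, such as *Synechococcus* populations in estuarine
waters.

Closely related community members often differ at only a handful of
nucleotide positions within an amplicon, below the resolution of OTU
clustering or database classification. Oligotyping recovers this
microdiversity: it finds the alignment columns that carry real variation,
partitions reads by their bases at those columns, and filters out the
partitions that sequencing error alone would create. The resulting
oligotype abundance trajectories can then be related to the environment.

## Method

Given an alignment of `n` equal-length reads, the Shannon entropy of
column `j` is

```
H(j) = − Σ_c p_c(j) · log2 p_c(j),       c ∈ {A, C, G, T, –}
```

with `N` excluded from the counts. Component positions are chosen greedily:
start from the globally maximal-entropy column, then repeatedly partition
the reads on the current positions and add the column with the highest
remaining *within-oligotype* entropy, skipping columns that do not refine
the partition (redundant information), until no column reaches the
convergence threshold ε (default 0.2 bits) or the position cap (default 19)
is hit. Reads are grouped by their exact base string at the selected
positions, and an oligotype is retained only if its most abundant unique
full-length member sequence occurs at least `M` times (minimum substantive
abundance, default `M = 20`); dissolved reads are tallied as "other".

Downstream, representatives (the most abundant unique member sequence per
oligotype) are matched against a clade-labelled reference alignment by
base-pair distance (ties reported jointly); abundances are normalised to
per-sample totals (genus or whole-community); and the samples × oligotypes
relative-abundance matrix is analysed by centered PCA. Each principal
component's scores are regressed on all 2⁴ subsets of {temperature,
salinity, dissolved oxygen, weekly precipitation}, ranked by

```
BIC = n·ln(RSS/n) + k·ln(n)
```

and the argmin subset is reported alongside the full 16-row table.

A ground-truthed simulator generates study-scale synthetic data — 12
variants of length 482 differing at 19 positions, 7 stations × 27 dates,
softmax abundances driven by seasonal covariates, multinomial read draws
with per-base substitution error — so every stage can be validated against
known truth.

## Worked example

Simulate the default two-summer estuarine scenario and run the pipeline:

```
$ oligotyper simulate --seed 1 --out demo
simulated 37800 reads from 12 variants -> demo

$ cat > demo/run.yaml <<EOF
reads: demo/reads.fna
out_dir: demo/out
env_table: demo/env.csv
daily_precip: demo/precip_daily.csv
totals: demo/totals.tsv
EOF

$ oligotyper run --config demo/run.yaml
12 oligotypes; 97.9% of reads assigned
```

The run recovered all 12 simulated variants as oligotypes from 11
automatically selected component positions, with 97.9% of reads assigned
(the remainder are reads carrying a sequencing error at a component
position, dissolved by the M filter). `demo/out/manifest.json` records the
stage summaries; among them:

```
"selected_subsets": {"PC1": ["temp_c", "dissolved_oxygen"],
                     "PC2": ["salinity_psu"]}
```

i.e. the first principal component of the oligotype relative-abundance
matrix (91.7% of variance here) separates the cool-water/high-oxygen
early-summer community from the warm-water late-summer community, and the
second axis tracks salinity — exactly the structure the simulator encodes.
Per-stage outputs (count and relative-abundance matrices, representative
FASTA, entropy profile, pairwise identity matrix, co-occurrence R², PCA
scores/loadings and the 16-row BIC tables) land under `demo/out/`.

The same stages are available as library functions
(`oligotyper.select_positions`, `decompose`,
`apply_min_substantive_abundance`, `assign_clade`, `pca`,
`best_subset_bic`, ...) and as per-stage subcommands (`prep`, `oligotype`,
`clades`, `envstats`, `simulate`).

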