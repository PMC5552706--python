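# Methods

## Entropy decomposition

Column entropy is Shannon entropy in bits over the five-character alphabet
{A, C, G, T, –}. Gaps are kept in the alphabet because uninformative gap
columns (gap frequency above `max_gap_fraction`, default 0.99) are removed
beforehand, so any residual gap is as diagnostic as a substitution. `N`
(any non-ACGT/gap intake character) is excluded from both the numerator and
denominator of the frequency estimate; a column of pure `N` has entropy 0
by convention, with a warning. Entropy is therefore bounded by log₂ 5 ≈
2.32 bits.

Position selection formalises the supervised, iterative curation used in
practice as a deterministic greedy loop. At each step the reads are
partitioned on the current position set and the per-column entropy profile
is computed *within* each oligotype; the column with the highest
within-oligotype entropy is added provided (a) it reaches the convergence
threshold ε and (b) it actually refines the partition — a column whose
addition leaves the partition unchanged carries only redundant information
and is excluded permanently (this is sound: a column constant within every
current group stays constant within every refinement of those groups).
Selection stops when no column qualifies ("converged entropy") or at
`max_positions`. Ties are broken toward the lowest column index; all
orderings elsewhere (oligotype rank, member tallies) are by descending
count with lexicographic tie-break, making every output bit-reproducible.

One robustness rule extends the textbook loop: oligotypes with fewer than
`min_group_size` reads (default 20, matching the default M) contribute no
candidate entropy. Under realistic per-base error rates, reads carrying an
error at an already-selected column split into tiny groups of one to three
reads; within such a group a single disagreement at an arbitrary error
column exhibits a full bit of entropy and would dominate the greedy argmax,
spending the position budget on noise. Substantive-size groups are exactly
the ones a curator inspects, and exactly the ones the M filter would keep.

**Defaults and their rationale.** ε = 0.2 bits: within an oligotype of
substantive size, per-base error at rate ≤ 0.5% produces at most ≈ 0.06
bits per column, while a genuine 3%-minor-allele mixture produces ≈ 0.2
bits, so 0.2 separates error from signal with margin. `max_positions` = 19
and `M` = 20 are the standard operating settings for this analysis scale.
"Substantive abundance" is deliberately the count of the oligotype's most
abundant *unique full-length sequence*, not its total read count: a
noise-generated oligotype accumulates many distinct error-bearing reads but
no frequently repeated exact sequence. No relative-abundance, per-sample,
or multi-sample occurrence threshold is applied.

## Clade assignment

Representatives are compared to the reference alignment by base-pair
difference: columns gapped in both sequences are excluded, a gap opposite a
base counts as one difference (the strictest consistent reading of
"base pairs different"). The clade call takes *all* reference entries at
the minimal distance, reporting tied clades jointly (e.g. "CB4, CB5").
References must share the reads' alignment coordinate system; providing a
re-aligner is out of scope, so this is a documented preprocessing contract
checked only via sequence length.

## Abundance tables, identity, co-occurrence

Count matrices carry the "other" bucket separately so that genus-normalised
fractions plus the other fraction sum to one per sample. A sample with a
zero denominator is *missing*, not zero (an absence of data, not an
observation of absence), and is excluded from PCA and correlations rather
than imputed. Percent identity is 100 × matches / comparable columns with
the same gap rules as the distance, so identity ≡ 100 − 100·d/comparable
by construction. Co-occurrence is squared Pearson correlation of two
relative-abundance series with pairwise deletion; pairs with fewer than 3
shared samples or a zero-variance series are reported missing.

## PCA and environmental model selection

The samples × oligotypes relative-abundance matrix (genus-normalised,
"other" excluded — the ordination is of oligotypes) is column-centered but
not variance-scaled, since all entries share units; the decomposition is a
plain SVD. Sign indeterminacy is fixed by making the largest-magnitude
loading of each component positive. Oligotype projections use the biplot
convention (loadings × singular values), so a zero-variance oligotype lands
at the origin. Group centroid distances are Euclidean in the PC1/PC2
plane; group labels are supplied by the user, not inferred.

Weekly precipitation is the trailing 7-day sum including the sampling day;
a window with any missing day yields a missing value.

Best-subset regression fits all 16 subsets of {temperature, salinity,
dissolved oxygen, weekly precipitation} by OLS with an intercept, after
listwise deletion (minimum 6 complete samples). The BIC convention is
Gaussian with the error variance profiled out, `n·ln(RSS/n) + k·ln(n)`
with k counting the intercept; alternative conventions differ by additive
constants that cannot change the argmin. RSS is floored at `n·1e-12` so a
perfect fit keeps a finite criterion; rank-deficient designs are flagged
and excluded from the argmin but kept in the table.

## Synthetic scenario

The generator emulates a two-summer estuarine survey: 12 variants of
length 482 differing only at 19 informative positions (pairwise identity
> 94%), 7 stations × 27 dates (weekly in summer, monthly otherwise; 189
samples), 200 reads per sample, per-base substitution error 0.002.
Variants get a hierarchical structure — one private substitution each,
plus shared "marker" substitutions in half of them — giving the selector
both discriminating and genuinely redundant columns. Temperature is a
seasonal sinusoid (≈ 4–30 °C) plus a +5 °C offset at the shallow isolated
station; salinity is ≈ 28–31 psu except a fresh end-member station with a
strong seasonal swing; dissolved oxygen declines with temperature;
daily precipitation is intermittent exponential rain. Variant abundances
are softmax-transformed log-linear responses to the standardised
covariates: a cool-water/high-oxygen early-summer trio, a warm-water
late-summer trio, four rare salinity-associated variants, one variant
private to the warm isolated station, and one with no seasonal driver.
Reads are drawn multinomially and mutated base-by-base (substitutions
only — indel noise belongs to the out-of-scope aligner, and its absence
keeps simulated reads aligned by construction). All randomness flows from
one seed through a single generator stream.

What the simulator does *not* emulate: platform-specific homopolymer
errors, chimeras, PCR amplification bias, phylogenetically structured
sequence evolution, or read-depth variation between samples. Passing the
recovery tests therefore demonstrates correctness of the decomposition and
statistics under the stated error model, not robustness to every artifact
of real amplicon data.

**Known limitation.** With per-base error ε and s selected component
positions, a fraction 1 − (1 − ε)^s of reads carries an error at a
component position and leaves its oligotype's code for the "other" bucket
(≈ 2.2% at ε = 0.002, s = 11). At 200 reads per sample this loss makes
per-sample relative-abundance estimates fluctuate by an L1 distance of
≈ 0.02 (mean) to ≈ 0.05 (worst sample) against truth, while the pooled
dataset-level abundance error stays below 0.005. Per-sample abundance
precision at low coverage is limited by this mechanism, not by the
decomposition itself.

## Numerical and degenerate-input choices

- Empty FASTA → empty read set; empty read set → entropy profile and
  position selection are errors, dereplication returns an empty tally.
- Alignment intake maps every non-{A,C,G,T,-} character to N and logs the
  count; unequal read lengths abort with the offending record named.
- Column indices are 0-based in the API, 1-based (original, pre-trim
  coordinates) in written reports.
- `decompose` with an empty position set returns a single oligotype; with
  all columns it coincides with dereplication.
- Problem sizes in the test suite: study scale (37,800 reads × 482
  columns) for the recovery checks, which complete in a few seconds; the
  model-selection recovery check uses 100 replicates at n = 50.
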