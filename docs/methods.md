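# Methods

## The analysis model

`cytomag` treats a sorted-metagenomics experiment as four coupled
book-keeping problems.

**Gate partitioning.** Events measured on a DAPI × forward-scatter plane
fall inside a master cell gate; sorting gates are axis-aligned rectangles
inside it with half-open bounds `[low, high)` on both axes (an event on the
lower boundary is inside, on the upper boundary outside; gates must not
overlap, so assignment is unambiguous). The dominant/low-abundant split uses
the arithmetic mean of per-gate counts computed **over gated cells only** —
outer cells do not enter the mean. Dominance is strict (`count > mean`); a
gate exactly at the mean is low-abundant, because dominance is defined as
being *above* the average. Cell totals are conserved by construction:
`DG + LA + OG = master`. Tube planning is ceiling division,
`tubes = ⌈target / per_tube⌉`, with a 1 × 10⁻⁹ rounding guard so that exact
multiples (4.95 × 10⁷ / 2.25 × 10⁶ = 22) are not inflated by float noise.

**MAG quality.** `score = completeness − 5 × contamination`, both percent.
Contamination is uncapped in the score (it can go negative); the tier rules
carry the caps. Boundary decisions, tested explicitly: completeness exactly
80 is medium (closed medium band, open high band); score exactly 50 fails
(strictly greater than 50 in both tiers).

**gOTU dereplication.** ANI is estimated from fixed-size bottom sketches of
canonical k-mers (k = 16, sketch 2,000), with Jaccard estimated from the
bottom of the merged sketch and converted through the Mash relationship
`ANI ≈ 100·(1 + ln(2j/(1+j))/k)`. The estimator is deterministic (splitmix64
hashing, no process-dependent state) and accurate to about ±1 ANI point near
the 95% species boundary, which the test suite asserts on simulated pairs
with known substitution rates. Estimates whose shared sketch fraction is
below 0.05 are *unreliable* and contribute no edge — unrelated genomes share
essentially no sketch, and treating that as "low ANI" rather than "no
information" would be meaningless. Clustering is single-linkage over
reliable edges with ANI ≥ 95 (the conventional reading of "clustered at 95%
ANI"; greedy-centroid would be a one-line swap). Components are labelled
`gOTU_01…` by smallest member id, making output order-invariant; each
representative is the member with the highest quality score, ties to the
smallest id. Known-bad genomes are handled by an explicit exclude list, not
a rule.

**Abundance profiling.** Coverage is `L·N/G` (read length × mapped reads /
genome size). The detection rule is inclusive at 10× ("a minimum of 10×"):
coverage exactly 10 is detected and carries an abundance. Relative abundance
normalizes each detected genome's coverage by the library's **detected
total only** — BDL genomes contribute nothing to the denominator — which is
the only rule that keeps a library's abundances summing to 100% while BDL
entries are reported as bounds. The per-library detection limit, expressed
as an abundance, is `100 × 10 / Σ(detected coverage)`; the cross-library
summary is the mean with the **sample (n − 1)** standard deviation. Coverage
is carried at full precision throughout; a `rounded` mode rounds half-up to
whole folds *before* masking and normalizing, reproducing reports printed at
integer coverage. Display rounding is half-up (2 dp for percentages, 1 dp
for the gate mean).

**Pseudo-mapping.** Reads are assigned to the indexed genome sharing the
most canonical 21-mers, requiring at least 5 shared k-mers; ties are
discarded and tallied. This is a deliberately simple assigner: at the
whole-genome coverage resolution this profiling needs (integer folds against
a 10× threshold), k-mer voting recovers mixture fractions within multinomial
error, which the tests assert against generator truth. It does not model
alignment scores, pair constraints or multi-mapping probabilities.

**Rarefaction.** Per-read assignments are subsampled without replacement at
each requested depth (a fixed number of replicates, seeded), coverage is
recomputed, and genomes at ≥ 10× are counted. Subsampling operates on reads,
not coverage units.

**16S rOTUs.** Sequences shorter than 900 bp are removed (strict: 899 goes,
900 stays). The chimera flag is a two-segment best-parent test: a sequence
is chimeric when the best-matching reference differs between its left and
right halves and each half beats the best full-length identity by ≥ 2
percentage points. This is a deliberate simplification of reference-based
chimera detection; it is validated only on synthetically labelled chimeras
(≥ 90% sensitivity, ≤ 2% false positives when parents are ≥ 5% divergent)
and makes no claim to match any external tool's behaviour on real data.
Clustering is greedy-centroid at 97% identity: sequences in decreasing count
order (ties: longer first, then smallest id) join the first centroid they
match, else found a cluster — so every member is within threshold of its
centroid, a certificate the tests re-verify by independent alignment.
Primary clustering runs per library; secondary clustering runs on the pooled
primary centroids only (never on raw sequences), carrying each primary
cluster's summed count. Abundance aggregation is three steps: per-sequence
count fractions per library; sums within primary clusters; sums within each
secondary cluster — so each rOTU ends with a library-resolved vector and
every library totals 100%. Abundances are computed *after* filtering and
renormalized to the retained set, keeping the 100% invariant (the
alternative — reporting against the unfiltered total — would make the
totals depend on how much was discarded).

**Identity definition.** All identity thresholds refer to one fixed global
aligner: match 1, mismatch −1, gap open −2, gap extend −1, terminal gaps
free; identity = matches / alignment columns, counting internal gap columns,
excluding terminal overhangs. The tests cross-check this against an
independent edit-distance aligner on substitution-only pairs.

**Concordance.** Taxon matching between gOTUs and rOTUs is exact string
equality after canonicalization (trim, collapse whitespace, strip `*`/`_`
italics markup at token edges); no fuzzy matching. Sharing counts are over
taxa with any genome recovery: unsorted-only, sorted-only, shared
(unsorted + ≥ 1 sorted), and present-in-all. The resolution ratio is
reported on MAG counts and on distinct-taxon counts, labelled separately,
because the two answer different questions (assembly yield vs. taxon
discovery).

## Synthetic data: what it emulates, and what it does not

The generator exists so every stage can be tested against exact truth.

- **Genomes** are i.i.d. uniform nucleotide sequences, one per species, with
  per-species sub-seeds derived by SHA-256 hashing of
  (master seed, stage, species id) — every output is a pure function of the
  spec. Uniform genomes are adequate because no downstream stage assumes
  genomic realism; they also make unrelated genomes maximally distinct,
  which is the conservative case for dereplication specificity.
- **16S genes** are mutated copies of one random ancestor per community;
  each species mutates exactly `round(d% × length)` distinct positions, so
  a pair at divergences d₁ and d₂ from the ancestor sits near d₁ + d₂ apart.
  Defaults: 1,500 bp genes (1,200 in some tests, still near-full-length).
- **Events** are independent axis-aligned bivariate normals per species with
  multinomial species counts — the simplest model with the gate separability
  that cluster-based gating assumes. No covariance, no spillover, no debris.
- **Reads** are single-end at fixed length L = 150 (coverage uses *average*
  read length; a fixed length makes L exact), drawn uniformly along the
  genome, reverse-complemented with probability 0.5, with i.i.d.
  substitution errors. No PCR duplicates, GC bias, quality decay, indels or
  paired ends.
- **Chimeras** are left-half/right-half joins of two distinct parent genes,
  injected at a configured rate with labels kept in the ground truth.
- **Default study conditions** used in tests: 200,000 events per measurement,
  21 gates in the worked example, 11 species / 24 MAG dereplication
  scenarios, 20–50 kb test genomes and 20,000–50,000-read libraries. Genome
  and library sizes are scaled to what the estimators need (sketch ANI is
  stable from ~20 kb; mixture recovery is multinomial-limited, not
  genome-size-limited), so the tests exercise the same arithmetic a
  full-size run would at a fraction of the compute.

Because of these simplifications, passing tests demonstrate the
*book-keeping and estimators* are right — they do not demonstrate robustness
to real cytometric spillover, assembly chimerism beyond the two-parent
model, strain microdiversity, or alignment-level mapping artifacts.

## Numerical and degenerate-input choices

- Ceiling, rounding and tie rules as above; all display rounding half-up.
- A library with no detected genome has an empty abundance vector and an
  *absent* (None) detection limit; summaries skip absent limits.
- Zero read depth yields empty read sets, not errors; an all-N read is
  unassigned; an empty genome index is an error.
- `estimate_ani` on genomes shorter than k is an error; reliability floors
  are applied before thresholds.
- Duplicate MAG ids, overlapping gates, and two gOTUs mapping to one taxon
  label are rejected loudly rather than silently merged.

## Known limitations

- The ANI estimator saturates near 100% (sketch resolution ~1/k per shared
  k-mer) and is unreliable below ~85% ANI; both regimes are outside the 95%
  decision boundary it serves.
- Greedy 97% clustering is order-dependent by design (count order is the
  declared order); a different tie order can change centroid choice, though
  never the membership certificate.
- The chimera flag needs parents ≥ ~5% divergent to clear its 2-point
  margin; closer parents are not detectable by this test.
- The concordance step trusts taxon labels; mislabeled inputs propagate.
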