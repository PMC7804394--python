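# Methods

This note records the conventions, models, and numerical choices behind the
package, including decisions made where common practice leaves room.

## Coordinate conventions

All intervals are 0-based, half-open `[start, end)` (BED convention); GTF
input (1-based, closed) is converted on read and back on write. Two intervals
**overlap** only when they share at least one base pair. The edge-to-edge
**distance** between touching intervals (`a.end == b.start`) is 0, but they do
not overlap; this distinction matters for the first distance bin, where
"overlap" and "within (0, 100] bp" are separate rows. A query on a chromosome
with no subject intervals has no defined distance and is reported as `None`
(terminal bin in binned summaries).

## Consensus THS construction

Per genotype, the THS set is the **base-pair intersection** of the two
replicate peak sets, merged. The cross-genotype consensus is the merged union
of all genotype sets, with per-region provenance (which genotypes contributed).
Retention as "high-confidence" requires both of:

1. accessibility above 3 CPM in at least one genotype, where the per-genotype
   value is the **mean over that genotype's replicate columns**, and
2. a q-pass in at least one genotype, where a genotype passes a region only
   when **both** of its replicates have an overlapping peak called at
   q < 0.05 (strict inequality; peaks without a q-value never pass).

The pooled-signal noise floor is the lower 5th percentile of all matrix
entries (numpy linear interpolation). With the default generator it lands
near the background/signal boundary; a fixed 3 CPM floor is available via
`percentile=None`.

## Distance association and co-localization

Each region is assigned once, to the bin of its nearest mark domain:
`overlap`, `(0,100]`, `(100,500]`, `(500,1000]`, `(1000,2000]`, or beyond/none.
Because headline statements are cumulative ("within d bp", with overlap
counted at every d), a cumulative table is emitted alongside. Co-localization
classifies each region by the presence of an A and/or B domain within d bp
(inclusive, default 2,000) and reports the share of A-associated regions that
are also B-associated.

## Monte Carlo enrichment

The observed statistic is the **median per-region feature overlap count**.
Null region sets are matched in count and in the exact multiset of region
lengths; for each region the chromosome is drawn with probability
proportional to its number of feasible start positions
(`chrom_length − region_length + 1`) and the start uniformly among them.
Null regions may overlap each other; an optional exclusion list triggers
rejection resampling with a bounded retry count. The empirical p is the
add-one form `(1 + #{null ≥ observed}) / (n_sets + 1)`, whose smallest value
at 10⁴ sets is 10⁻⁴ — never zero. The enrichment ratio is
observed / mean(null medians).

The median statistic **dilutes under wide features**: a feature whose center
lies outside a region can still overlap it, so the measured ratio for a
planted density factor f over a region mass fraction `frac` approaches
`f / (f·frac + (1 − frac))` as features widen. `density_enrichment` — the
ratio of feature-center density inside vs outside the regions — is therefore
the estimator used to recover a planted factor, while the median-based test
provides the significance call.

## Moderated differential statistics

Signals are transformed as `log2(x + 0.5)`; the pseudocount bounds fold
changes on zero entries and is configurable. Per row, the pooled variance
`s_g²` is shrunk toward the grand mean `s0² = mean(s_g²)` with a **fixed**
prior df `d0 = 4`:

```
s̃² = (d0·s0² + d_g·s_g²) / (d0 + d_g),   df = d0 + d_g
```

At `d0 = 0` this is exactly the ordinary pooled-variance two-sample t (a
tested identity). The fixed prior is a deliberate deviation from
empirical-Bayes fitting of `d0`: with 2–3 replicates the fit is unstable, and
a fixed prior keeps the statistic deterministic. The cost is approximate
calibration — null p-values are exactly uniform only at `d0 = 0`; at the
default prior the type-I error at p < 0.05 stays near nominal (tested).

Level classification uses the **linear** mutant/WT ratio of mean CPM, binned
left-closed: `[0,.2) [.2,.4) [.4,.6) [.6,.8) [.8,1.2) [1.2,∞)`. "Below 60% of
WT" is equivalent to log2FC ≤ log2(0.6) = −0.7369…, printed as −0.74.
Expression calls are activated iff log2FC ≥ +1 (inclusive) and p < 0.05
(strict); repressed symmetric; everything else unaltered.

One-sided group comparisons use the Mann–Whitney–Wilcoxon test: exact
enumeration when the smaller group has ≤ 8 observations and no ties, the
tie-corrected normal approximation otherwise.

## Gene-centric rules

A gene's regulatory window is its body plus a **750 bp strand-aware promoter**
upstream of the TSS, truncated at chromosome edges. Peak→gene assignment,
mark-category calling (any wild-type dataset suffices per mark), and gene↔THS
pairing all reuse this window for consistency; the pairing rule and the
per-gene summary over multiple THSs (mean; max optional) are conventions
chosen here, not dictated by the underlying experimental designs. Per-gene
mark signal averages over the base-pair **union** of associated peaks, each
base counted once.

## The synthetic generator

`SimSpec` defaults plant the study conditions; they are not tuned to tests:

* **Genome/THSs** — 5 × 8 Mb chromosomes, 2,000 THSs with log-normal lengths
  (mode ≈ 400 bp, clipped to [100, 2000]). THSs are placed on a slot grid
  with 7 kb margins so that a neighbouring THS's mark domain (gap ≤ 2 kb plus
  domain length ≤ 6 kb) can never contaminate another THS's distance bin.
* **Replicates** — edge jitter (sd 20 bp), 5% dropout, plus replicate-specific
  uniform noise peaks that the replicate intersection removes.
* **Accessibility** — piecewise-constant CPM tracks: genotype multiplier ×
  base 10 CPM at THSs over a 0.5 CPM background, Gaussian track noise.
* **Marks** — per-THS distance bins drawn from planted fractions
  (H2AK121ub: 30% overlap, 20/15/7.5/7.5% in the following bins → 50%
  within 100 bp, 80% within 2 kb; H3K27me3 totals 40%), with 96% of
  K27-associated THSs drawn from the H2A-associated subset.
* **TFBS** — mixture placement giving an exact center-density factor
  (default 7.5) inside THS mass.
* **Coupling** — genes whose primary mark falls below 60% of WT in a focal
  mutant have their anchoring THS boosted ×2 in accessibility there, and 40%
  of them are planted as activated, 60% as unaltered — the generator's
  ground-truth version of the headline observation.

All stage RNGs derive from `numpy.random.SeedSequence(seed, spawn_key)` so
stages are independent and the whole study is a pure function of the seed.

## Scope

The generator emulates the *structure* of the data layers (peak geometry,
planted fractions, multiplicative noise), not read-level realism: no read
counts, no mappability or GC structure, no peak-caller artifacts. Dataset
harmonization across developmental stages, GO enrichment, and genome-browser
visualization are out of scope.
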