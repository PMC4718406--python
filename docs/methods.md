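# Methods

## Coordinate and counting conventions

SAM input is 1-based; everything internal is 0-based, converted exactly
once at ingest. A read pair is represented by its TLEN > 0 mate only,
which counts each fragment once without name-pairing; unmapped,
mate-unmapped, secondary and supplementary records are dropped (the data
this pipeline targets are aligned with best-hit reporting, so one primary
alignment per read is assumed). The fragment midpoint is
`(POS − 1) + ⌊TLEN/2⌋`. The floor is arbitrary at 10-bp bin resolution but
fixed so results are exactly reproducible.

Size classes are inclusive on both ends: `nominal ± round(0.2·nominal)`,
so the mono-nucleosome class 150 bp spans [120, 180]. "±20 %" is read as
including the endpoints, which also matches the printed half-width of
30 bp.

Tracks are dense per-chromosome arrays of 10-bp bins labelled by their
zero-referenced start coordinate (bin *i* covers `[10i, 10i+10)`); the
`.sgr` serialisation writes that start coordinate. Whether historical
tools labelled bins by start or center is not recoverable; start was
chosen and is used consistently for all downstream offsets.

## Smoothing

Two smoothers with distinct downstream roles:

* **3-bin moving average** (peak calling, clustering): interior bins
  average three terms; chromosome-end bins average the two available terms
  (truncated window, no padding). Linear, non-negativity preserving.
* **Epanechnikov kernel, h = 30 bp** (displays, site-aligned profiles):
  a weighted kernel sum on the bin grid,
  `s[j] = Σᵢ v[i]·K((xⱼ−xᵢ)/h)/h`, rather than a probability density over
  base pairs. With h = 30 and 10-bp bins the support is the five bins
  within ±2 of the source. The result is rescaled so `Σs = Σv`
  (mass-preserving, default on): smoothed tracks stay on the frequency
  scale and remain comparable across data sets. Whether the historical
  scripts probability-normalised before their window normalisation is
  unknown; mass preservation is the divergence risk for *absolute*
  smoothed values, and is irrelevant after per-window normalisation.

Both smoothers are validated against direct double-loop evaluations
(property tests over tracks up to 500 bins).

## Peak marking

Bin *i* of the moving-average track is a summit iff `v[i] > θ` (strict),
`v[i] > v[i−1]` (strict) and `v[i] ≥ v[i+1]` (non-strict). The asymmetric
tie rule marks the leftmost bin of a plateau exactly once; missing
neighbours at chromosome ends are treated as −∞. No minimum inter-peak
distance is imposed beyond what the local-maximum rule already implies
(adjacent bins can never both be summits). The default threshold θ = 25
is calibrated to genome-scale sequencing depth. Peak calling refuses
tracks whose provenance is not the 3-bin moving average unless forced.

Because the exact historical tie/edge rules are not recoverable, a
genome-wide positioned-nucleosome count obtained with this implementation
may differ from previously published counts by a small margin attributable
to tie handling; the count should always be reported together with the
rule version above.

## Site-aligned profiles

Windows are extracted strand-aware: offsets run 5′→3′, so for − strand
features the genomic window is reversed. Off-chromosome bins contribute
zero and set a per-feature truncation flag. The cumulative profile sums
raw window vectors across features (summing, rather than averaging
per-feature first, was chosen; the two differ only at chromosome edges)
and divides by the arithmetic mean over all window bins, zeros included —
so the normalised profile averages to exactly 1 and is invariant to
duplicating the feature set. An all-zero window is a reported error, not
a NaN. The clustering matrix uses a fixed TSS→TSS+1,500 bp window
(150 bins), covering the first ~9 nucleosomes of the gene-body array;
genes shorter than the window keep their full window (the track is
genomic), matching equal-width heatmap rows. Window length is a
configuration knob.

## Clustering and statistics

* **k-means** (default k = 9, squared Euclidean, Lloyd, k-means++ init,
  n_init = 1, ≤300 iterations) via scikit-learn with a fixed seed;
  determinism given the seed is the contract — the historical
  initialisation is not reproducible. Row order is ascending cluster
  label, then ascending distance to the assigned centroid, and can be
  re-applied to a second condition's matrix for side-by-side display.
* **Subsampled t-test**: features are partitioned into `n_subsets`
  disjoint random subsets of `subset_size` (one shared partition for both
  conditions, keeping the comparison per-feature-matched), and the two
  vectors of subset means are compared with a two-tailed unpaired
  Student's t-test (defaults 29 × 100). Subsampling bounds the effective
  n so p-values remain meaningful with thousands of features. If
  `n_subsets × subset_size` exceeds the feature count, overlapping subsets
  are drawn instead and flagged. Welch (`equal_var=False`) and paired
  variants are available as options; unpaired Student is the default.
* **Overlap test**: `P(X ≥ k)` for X hypergeometric(background, n_a, n_b),
  validated against exhaustive enumeration at small sizes.

## The synthetic chromatin generator

The generator emulates the regularities the analysis is designed to
detect, with defaults chosen as a realistic fission-yeast-like baseline:

| parameter | default | meaning |
|---|---|---|
| `ndr_width` | 150 bp | nucleosome-depleted region upstream of the TSS |
| `plus_one_offset` | 60 bp | TSS → +1 nucleosome center |
| `repeat_length` | 154 bp | center-to-center array spacing (configurable; never asserted as a constant) |
| `n_nucleosomes_per_array` | 10 | array length into the gene body, plus one −1 nucleosome mirrored across the NDR |
| `occupancy` | 0.9 | probability a nucleosome is present per cell |
| `fuzziness_sd` | 10 bp | SD of cell-to-cell positional jitter |
| `background_rate` | 2 /kb | uniform non-nucleosomal fragments |
| fragment length | N(165, 12) low / N(150, 12) high digestion, clamped [50, 400] | heavier digestion trims fragments shorter |
| depleted condition | occupancy ×0.7, fuzziness ×2.0 | chromatin-assembly-mutant phenotype: lower peaks, filled troughs |

Per nucleosome, a Poisson(depth × occupancy) number of fragments is drawn,
centered on the nucleosome with Gaussian jitter; fragments are emitted as
proper SAM pairs (flags 99/147, symmetric ±TLEN, 50 bp reads, `*`
sequence — only fields the ingest consults are load-bearing), sorted
deterministically, so identical seeds give byte-identical SAM. The
depleted condition's scales are illustrative, not calibrated to any
measured per-locus occupancy change: real mutant data constrain protein
levels, not per-nucleosome occupancy.

What the generator does **not** emulate: sequence-dependent MNase bias,
PCR duplicates, mappability, chromatin heterogeneity beyond a single
array geometry per gene, or MNase-sensitive labile particles. Passing
recovery tests on this model therefore demonstrates the pipeline's
correctness and sensitivity under idealised phasing, not performance on
real libraries.

### Depth-scaled peak threshold for simulations

The expected moving-average summit height over a planted nucleosome is
`depth · occupancy · retention · P(|N(0, σ)| < 15 bp) / 3`, where
retention is the size-class fraction of the fragment-length distribution.
For simulations, `suggested_peak_threshold` sets θ to half that expected
height — the same "well above background, well below a typical summit"
role the genome-scale default of 25 plays at real sequencing depth. This
rule is analytic, fixed by the simulation's own parameters. At the
default simulation depth (50 fragments/nucleosome, low digestion) it
gives θ ≈ 5.9.

## Problem sizes and numerical choices

The validation suite runs on synthetic genomes of 20 genes (recovery:
220 planted nucleosomes, ~10⁴ fragments) and 120 genes (condition
contrast and t-tests: 29 subsets of 4 features, since 29 × 100 features
would need genome-scale gene counts), with 10⁵ fragments for the
digestion-shift check and 1,000 bootstrap replicates for the null
calibration of the subsampled t-test (two same-condition resamples per
replicate; the Kolmogorov–Smirnov distance of the resulting p-values from
U(0,1) is ~0.03). Recovery tolerance is ±10 bp (one bin). All stochastic
stages take explicit integer seeds; the pipeline manifest records
parameters and output checksums so a rerun is verifiably identical.

## Known limitations

* The plateau/edge tie rules in peak marking are this package's
  re-specification; counts on real data may shift slightly relative to
  other implementations of the same heuristic.
* Kernel smoothing at chromosome ends loses tail mass off the end before
  global rescaling; only the outermost bins are affected.
* The per-gene clustering window is fixed-length, not gene-length-scaled.
* BigWig/BedGraph export is not provided; `.sgr` is the interchange
  format.
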