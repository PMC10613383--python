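# Methods

## The scan statistic

The scan asks, for every position in the genome, whether differential
expression is locally enriched beyond what the genome-wide rate predicts.
Each chromosome arm is tiled with sliding windows of width *w* (default
500 kb) advanced in steps of *s* (default 20 kb); windows never cross
centromeres, and the last windows on an arm are truncated at the arm end.
A gene belongs to the window containing its TSS (half-open intervals,
0-based).

Genes are first called up- or down-regulated from the upstream
differential-expression table: a gene is upregulated when its adjusted
p-value (FDR) is ≤ 0.05 and its fold change is ≥ 2 (log2FC ≥ 1),
downregulated symmetrically (FC ≤ 0.5), both thresholds inclusive and
user-adjustable. Each gene then receives a nonnegative **raw score**
under one of three schemes, crossed with a scan direction (upregulated /
downregulated / mixed):

* **count** — 1 if the gene's call matches the direction, else 0;
* **significance** — −log10(FDR) if matching, else 0 (FDR floored at
  1e−300 so upstream underflow cannot produce infinite scores);
* **foldchange** — |log2FC| if matching, else 0.

The window **enrichment score** is `ES(W) = Σ_{g∈W} RS(g)`, and `n` is
the number of *all* genes in the window, zero-scored ones included.

## Null models

**Count scoring.** Each gene is modelled as an independent Bernoulli
trial whose success probability `p̂` is the genome-wide fraction of
matching calls, so the window sum is Binomial(n, p̂). The window p-value
is the upper tail of the *plain* normal approximation
N(np̂, np̂(1−p̂)) — deliberately without a continuity correction, as the
method defines it. Windows with `n = 0` or degenerate variance get
p = 1, so gene deserts can never form clusters.

A consequence worth stating plainly: without the continuity correction,
the Gaussian survival evaluated at integer ES differs from the exact
binomial survival by roughly `pmf(mode)/2 ≈ 0.2/σ` near the centre of
the distribution, i.e. ~0.07 at n = 50, p̂ = 0.1, dropping below 0.01
only once `np̂(1−p̂) ≳ 400`. In the upper tail the approximation is
anti-conservative (binomial tails are heavier than normal for skewed
cases). At sparse gene densities (~5 genes per 500-kb window) this makes
count-mode scans call more windows significant than the nominal rate:
on signal-free synthetic genomes we measure a raw p < 0.05 exceedance of
~0.08 and several spurious clusters per genome. With ≥ 30 genes per
window the exceedance is within ~2 points of nominal. Users scanning
sparse annotations should prefer the empirical null below; the count
null is retained in its published form.

**Significance / fold-change scoring.** The null is built from the
genome-wide pool of raw scores of *all* scanned genes (zeros included —
the exchangeable unit is any gene, since `n` counts all genes). For
windows with `n < t` (default t = 30) the null is a bootstrap: draw
x = 6400 sums of `n` scores sampled with replacement from the pool, and
report `p = (1 + #{sums ≥ ES}) / (1 + x)` — the add-one estimator keeps
p positive and valid under resampling noise. For `n ≥ t` the central
limit theorem replaces the bootstrap: p is the upper tail of
N(n·μ, σ·√n), with μ and σ the *population* (1/N) mean and standard
deviation of the pool. The source description prints this Gaussian as
N(μ, σ) with no dependence on n, which cannot be the distribution of a
sum of n scores; we implement the CLT form N(n·μ, σ·√n) that the
surrounding text derives. Gaussian tail values are floored at 1e−300;
a degenerate σ = 0 pool yields p = 1 below the mean and the floor above
it.

Inside a full scan, one bootstrap null sample is drawn per *distinct*
window gene count `n` (ascending order, one shared RNG seeded from the
scan seed) and shared by all windows with that `n`. This is
bit-reproducible, ~n-distinct-values cheaper than a fresh null per
window, and statistically equivalent marginally; the public
single-window function draws its own null. Note the bootstrap p cannot
go below `1/(x+1)` ≈ 1.56e−4 at the default x, which bounds how deep
into a genome-wide Benjamini–Hochberg ranking a bootstrap window can
reach: score-method scans only call clusters where enough windows sit
at the floor. Raising `x` relaxes the floor at linear cost.

## Correction and cluster calling

Window p-values are Benjamini–Hochberg adjusted once genome-wide per
(direction, method) run (step-up, monotonised, capped at 1; delegated to
`statsmodels`). Maximal runs of windows with adjusted p < the FDR
threshold (default 0.05) that are *adjacent in grid index on the same
arm* become clusters — with the default s ≪ w adjacent windows overlap
physically, so index adjacency is the only consistent notion of
contiguity. A cluster spans the union of its windows (hence is at least
one window wide), records the lowest adjusted p among them, and lists
every gene whose TSS falls inside, flagging the direction-matching
regulated ones.

## TAD rearrangements

Two TAD call sets at the same contact-matrix resolution are compared by
their boundaries (TAD starts and ends). A boundary is concordant if the
complementary set has a boundary within one bin width (inclusive; a
proximity test, not a one-to-one matching). Candidate rearrangement
regions are the intervals between consecutive concordant *pre*
boundaries (chromosome ends act as implicit anchors so terminal changes
remain classifiable) that contain at least one discordant boundary from
either set; candidates overlapping a centromere are discarded because
TAD calls there are unreliable. With `m` pre-TADs and `k` post-TADs
intersecting the region (≥ 1 bp):

| condition      | category       |
|----------------|----------------|
| m > 1, k = 1   | simple merge   |
| m = 1, k > 1   | simple split   |
| m > k ≥ 2      | complex merge  |
| 2 ≤ m < k      | complex split  |
| m = k ≥ 2      | balanced shift |

Candidate construction between concordant anchors makes the m = 1 (or
k = 1) rows coincide with "a single TAD completely spans the region".
The degenerate m = k = 1 case — possible only with gapped TAD inputs
when a gap edge moves — is reported as a balanced shift, since the TAD
count is unchanged while a boundary moved. Exchanging the two call sets
maps merges to splits and vice versa; anchoring candidates at pre
boundaries means swapped candidate intervals coincide exactly whenever
concordant boundaries match at zero distance, and may shift by up to one
bin otherwise.

## Co-localization

Overlap fractions: for each stratum (whole genome, up-clusters,
down-clusters — cluster intervals unioned first, since overlapping
windows can yield overlapping clusters) we report the fraction of bases
in each rearrangement category plus "not rearranged"; rearrangement
regions are disjoint by construction, so the fractions partition each
stratum. Loop odds ratios: a loop contacts a cluster when either anchor
overlaps the cluster interval by ≥ 1 bp; the per-cluster OR compares
post- versus pre-perturbation significance odds over the contacting
loops with the Haldane–Anscombe +0.5 applied to all four cells always
(not only on zeros), which keeps the pre/post swap an exact inversion
OR → 1/OR. Group comparisons (up- vs down-cluster ORs; inside- vs
outside-cluster fold changes and significances) use two-sided
Mann–Whitney U tests; track similarity across conditions uses Spearman
rank correlation of per-window p-values on an identical grid. When ORs
are aggregated by rearrangement type, each cluster is assigned the
category of the rearrangement it overlaps most.

## Synthetic data

The generator emulates the statistical structure the scan assumes, not
the sequencing process. Defaults: three 50-Mb chromosomes with a 1-Mb
centromere at the midpoint; 10 genes/Mb with uniform TSS positions per
arm (~1500 genes, ~7350 default windows); background regulation
probability 0.10 per direction, the scale of a strong stimulation
contrast; regulated genes draw FDR ~ U(0, 0.05) and |log2FC| ~
N(2.0, 0.5) floored at 1.0 so that threshold classification reproduces
the planted labels exactly; unregulated genes draw FDR ~ U(0.05, 1) and
log2FC ~ N(0, 0.2). Planted clusters elevate the regulation probability
of their direction inside an interval (the opposite direction keeps its
background rate). Adjusted p-values are drawn directly rather than
derived from simulated counts: the scan consumes the upstream model's
output interface, and emulating its distributional shape exercises every
code path. TAD pairs start from a gapless 1-Mb tiling of each arm
(100-kb bins) and apply archetypal edits inside planted intervals —
remove a boundary (merge), insert one (split), 3→2 or 2→3 re-tilings
(complex), or a 2-bin boundary displacement (balanced shift) — leaving
everything else identical. Loops get uniform anchors; anchors touching a
planted up-cluster have elevated post-perturbation significance
probability (0.8 vs 0.3), and symmetrically pre for down-clusters.

What the generator does **not** emulate: non-uniform gene density (real
DEG clusters sit in gene-rich regions, which materially boosts window
occupancy and hence power), correlated regulation between neighbouring
genes beyond the planted blocks, realistic FDR/fold-change joint
distributions, gapped or nested TAD calls, and distance-dependent loop
frequencies. Passing recovery tests therefore demonstrate correctness of
the machinery under the stated model, not expected sensitivity on real
genomes.

At these desk-scale conditions, recovery of 1.5-Mb clusters planted at
5× background (regulation probability 0.5) with the count statistic runs
at roughly 70–85% of planted intervals reaching 50% coverage across
seeds: a Poisson-realised cluster can land 7–13 genes with too few
regulated ones in any single 500-kb window to clear genome-wide BH. This
ceiling is a property of the statistic at 10 genes/Mb, not of the
implementation; the reproduction script reports the measured value.

## Numerical and design choices

* Coordinates are 0-based half-open throughout; BED I/O is native.
* Chromosomes without a centromere annotation are treated as one arm.
* Gene position is the TSS: `start` for + strand, `end` for − strand,
  `start` when the strand is unknown. Genes on chromosomes absent from
  the layout (or with centromeric TSS) are dropped with a logged count.
* Window generation starts a window at every step position inside the
  arm, so several trailing windows may be truncated at the arm end.
* σ of the score pool uses the population convention (1/N); at
  genome-wide pool sizes the difference from 1/(N−1) is negligible.
* "Exceeding the FDR threshold" is implemented as adjusted p strictly
  below the threshold.
* Problem sizes in the test-suite and reproduction script (20 null
  genomes, 10 recovery seeds, 100k-draw bootstrap checks) are chosen so
  the whole validation runs in well under a minute while keeping
  Monte-Carlo error far below the asserted margins.
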