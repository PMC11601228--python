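# Methods

## Screen generative model

The simulator mirrors the physical stages of a fluorescence-sorted pooled
CRISPRi screen and is the basis for every calibration claim the test suite
makes.

**Infection.** Each of *N* cells receives *k* ~ Poisson(MOI) guides drawn
uniformly with replacement from the library; cells with *k* = 0 are discarded
(antibiotic selection). The default MOI of 0.15 matches the low-multiplicity
design used in practice, at which ~7.3% of surviving cells carry more than
one guide (the conditional-Poisson value 1 − MOI·e^(−MOI)/(1 − e^(−MOI))).
The number of infected cells is chosen so the surviving population hits the
requested coverage (default 500 cells per guide).

**Phenotype.** A cell's log2 fluorescence is
μ0 + mean over its guides of γ(gene) + ε, ε ~ N(0, σ²), with μ0 = 10 and
σ = 1 log2 units by default. Multi-guide cells take the *mean* of their
guides' effects: at MOI 0.15 these are rare, and averaging bounds the bias a
multi-guide cell can contribute without modelling epistasis.

**Sorting.** Cells are ranked by fluorescence (stable sort; ties keep input
order) and exactly ⌊q·n⌋ cells enter each of the low and high gates
(q = 0.25 by default, the two-quartile design); the middle 50% is discarded
and never sequenced. A cell contributes one tally unit per carried guide,
since each integrated cassette is amplified from genomic DNA.

**Sequencing.** Bin tallies become read counts by a Dirichlet–multinomial:
proportions ~ Dirichlet(α_g = tally_g/φ), counts ~ Multinomial(depth, p).
This gives negative-binomial-like overdispersed marginals (inflation factor
(depth + A)/(1 + A) with A = Σα) while conserving depth exactly; φ = 0
degenerates to a plain multinomial, and guides absent from a bin keep
exactly zero probability mass. Defaults: depth 10^6 reads per bin, φ = 0.01,
3 replicates. Neither depth nor coverage is reported for the original
experiments; the defaults are desk-scale values a screen of this size would
consider adequately powered (≥ 4,000 reads and 500 cells per guide) and are
exposed in `ScreenConfig`.

**Seeding.** Every stage draws from `numpy.random.default_rng([seed,
replicate, stage])`, so any replicate or stage can be reproduced in
isolation and results are independent of platform iteration order.

What the generator deliberately omits: PCR jackpotting, index hopping, sort
impurity, guide-efficacy heterogeneity, and fitness effects of knockdowns on
cell abundance. Passing calibration/power tests therefore demonstrates the
statistics behave correctly under idealised noise of realistic magnitude,
not that any particular wet-lab artefact is handled.

## Scoring pipeline

Counts are normalised to reads per million after adding a pseudocount of
0.5 (keeps zero-count guides finite in log space with minimal LFC bias).
Per-replicate LFCs are averaged rather than counts pooled — robust to
unequal depths — with a pooled-count mode behind a flag. Guide z-scores use
the NTC median and 1.4826·MAD so a handful of outlier controls cannot
inflate the null spread.

Gene aggregation is a weighted geometric mean of guide fold changes with
weights ∝ max(|z|, 0.25); the floor keeps a null-looking guide from being
silenced entirely, and an equal-weight mode reduces to the plain geometric
mean. The gene test is a two-sided Mann–Whitney U of guide LFCs against NTC
guide LFCs, computed exactly (scipy's exact method, verified against full
enumeration in the tests) whenever the gene has ≤ 3 guides and there are no
ties — always the case in a 2-guide design — and by normal approximation
with continuity and tie correction otherwise. The volcano score is
`phenotype_lfc · (−log10 p)`.

**Empirical FDR.** NTC guides are regrouped into pseudo-genes of the modal
real-gene size (all C(n, k) combinations when ≤ 10,000, e.g. all 378 pairs
of 28 NTCs; seeded sampling beyond that) and scored identically to genes; a
pseudo-gene's Mann–Whitney background excludes its own member guides so the
two samples stay disjoint. For the positive tail, the raw FDR at threshold
s is [(#pseudo ≥ s)/N_pseudo]/[(#gene ≥ s)/N_gene] clipped to [0, 1], and a
gene's q is the minimum raw FDR over thresholds at or below its own score,
which makes q monotone non-increasing in score; the negative tail is the
mirror image. Tails partition genes by the sign of the phenotype, so no
gene can be called in both directions. Hits require the tail-matched q
below α = 0.01. Benjamini–Hochberg q-values on the Mann–Whitney p-values
are reported alongside but do not gate hits; a guide-level negative-binomial
test is not implemented — the rank test is the primary gene-level statistic,
and the negative-binomial character of the data lives in the simulator.

Under 20 all-null screens at the study design (102×2 + 28, 3 replicates,
coverage 500, depth 10^6), the measured mean fraction of genes called hits
is ≈ 0.009 — the estimator runs essentially at its nominal 0.01 because the
raw tail ratio can reach exactly zero whenever a gene outranks all 378
pseudo-genes; a +1 guard in the pseudo count would make it conservative but
would also put the smallest attainable q above 0.01 for small hit sets,
defeating the 0.01 gate, so the unguarded ratio is used.

## Read counting

Reads are assigned by extracting the protospacer slot (fixed offset after a
configurable 5′ constant, or a 5′-most-wins sliding scan) and hash lookup
against the library; at one allowed mismatch, a unique guide at Hamming
distance 1 wins and any tie is unassigned. Quality scores are ignored and
reads are not reverse-complemented by default (stranded amplicon), with an
opt-in RC flag. Assigned + unassigned always equals reads processed. The
FASTQ emitter writes 5′constant + protospacer + 3′constant with constant
'I' quality, so emit → count is an exact identity used as a pipeline oracle.

## Cluster occupancy

Occupancy is the fraction of a perturbation's cells per transcriptomic
state; change is the additive difference from the NTC row (so rows of the
delta table sum to zero), matching how occupancy-change bar plots are read;
a log-ratio would be undefined for empty states. Perturbations under 10
cells are excluded with a warning, not an error. No significance test is
attached to occupancy shifts by default — a percentile-bootstrap CI helper
is provided for callers who want one. The multinomial generator applies
additive probability shifts and renormalises, erring on negative shifted
probabilities.

## Imaging metrics

**Surveillance area** is the pixel count of the logical-OR (max projection)
over a single cell's binary mask stack divided by its frame-0 area; it is
≥ 1 whenever frame 0 is non-empty and equals 1 iff the cell never leaves
its initial footprint. A disk of radius r translating a total distance d
sweeps a stadium of area πr² + 2rd, so the ratio approaches 1 + 2d/(πr);
the rasterised measurement agrees within 2% at r = 20 px, d = 40 px.

**Stabilization** registers each frame to frame 0 by the integer translation
maximising binary overlap, searched exhaustively within ±max_shift
(default 10 px); a best shift on the search boundary is an error rather
than a silent truncation. Registration targets the field of view — fixtures
inject field jitter separately from cell motion, because registering to the
moving cell itself would cancel the very motion being measured.

**Segmentation** is global thresholding (Otsu or fixed) plus connected
components, with a minimum-size filter and an optional largest-component
single-cell mode. **Colocalization** reports Pearson r over in-mask pixels
(NaN for a constant channel) and Manders M1/M2 against per-channel
thresholds (Otsu within the mask by default, overridable for determinism).
Viability is a per-nucleus intensity threshold; dot arrays are
replicate-averaged and background-subtracted with no clipping.

## Flow readouts

Gating operates on log10(intensity + 1); the automatic gate sits at the
density minimum of a two-component Gaussian mixture between its component
means, mirroring how a bimodal marker histogram is gated by eye. Uptake is
the sample median of the green channel over gated events, insensitive to
sub-gate events by construction. The in-well paired design is tested with a
paired t on per-well (KD − control) differences; p-values are reported
unadjusted (multiple paired t-tests, as the assay reports them), with an
optional BH flag. ΔΔCt fold change is 2^(−ΔΔCt) against a housekeeping
gene and reference condition.

## Problem sizes used in the tests

Pipeline calibration and recovery run at the full screen design (102 or 20
genes × 2 guides + 28 NTCs, 3 replicates, coverage 500, depth 10^6 reads)
over 20 seeds; Monte-Carlo distributional checks use 100–200 seeds of
smaller draws; imaging fixtures are ~120×160 px stacks. The whole suite
completes in well under a minute.

## Known limitations

* Guide weights, the score form, and the empirical-FDR/BH combination
  follow the conventions of published screen-scoring pipelines in this
  family; where the original aggregation internals are unpublished, the
  |z|-weighted geometric mean with the threshold-minimised tail ratio is
  this package's declared choice, with the equal-weight mode as the
  sensitivity check.
* The simulator's fluorescence model is a single Gaussian per cell; real
  uptake distributions are heavier-tailed, so absolute power estimates are
  optimistic.
* Occupancy analysis consumes precomputed cluster labels; clustering and
  demultiplexing quality are upstream concerns.
* FCS binary parsing is out of scope; flow events are consumed as CSV
  exports.
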