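# Methods

This note documents the models and procedures each module implements,
the parameters that matter, what the synthetic-data generators emulate
(and what they deliberately do not), and the numerical choices made
where the design was genuinely open.

## Two-bottle choice (`drinking`)

Minute readings above 0.1 ml are sensor/leak artifacts. The comparison
is strict (`> 0.1 ml` removed, the boundary retained) and removed
minutes are **excluded**, never interpolated or zeroed: they are
erroneous measurements, and interpolation would invent volume. Sessions
are the half-open overnight window [20:00, 14:00 next day); the
half-open convention prevents double counting, and a minute stamped
exactly 20:00 belongs to that evening's session. Bottle contents and
sides change only in the 14:00–20:00 off window, so contents are
constant within a session and the session is labeled by its start date.

Preference is the test solution's share of total session volume (%); a
zero-intake session is flagged undefined rather than scored. Dose is
`concentration(µg/ml) · volume(ml) / weight(g)` mg/kg per session-day,
with weights linearly interpolated between the every-other-day
measurements (smooth-growth assumption; outside the measured range the
nearest value is used and flagged). Side bias over the water-vs-water
habituation period excludes an animal only when the left-side share is
strictly below 20% or strictly above 80%.

## Maze behavior (`behavior`)

EOM open-arm time is scored in three 3-minute blocks timed from maze
placement; frames map to blocks by half-open intervals on the frame
timestamp, so block percentages are invariant to the frame rate. A short
trace flags the partial block instead of silently rescaling it.

The CPP score is test − pretest seconds in the drug-paired chamber.
Group assignment for conditioning is unbiased: for two groups of up to
22 animals the balanced partition minimizing the between-group mean
pretest bias is found **exactly** by meet-in-the-middle enumeration;
larger problems (or more than two groups) use deterministic greedy
assignment of animals sorted by |bias| plus pairwise-swap refinement.
Exact search was chosen over plain greedy pairing because greedy does
not reliably dominate the best of many random splits at these problem
sizes, while exact search does by construction. The drug-paired chamber
alternates within each group in bias order; odd group sizes make perfect
counterbalancing infeasible and are flagged. Assignment produces labels
only — no animal's data is touched.

## Spike-train responses (`spikes`)

Rates are counted on 60-s windows stepped by 15 s; only windows fully
inside the recording are emitted (partial edge windows are dropped, not
renormalized), and windows are indexed by their center time. The
baseline is the mean rate over windows fully inside the 180 s before the
injection; a zero or missing baseline raises a typed error so the unit
is excluded with a reason. The response period is the 180 s after the
injection, taken as windows with centers in (injection, injection+180],
i.e. excluding the injection instant itself. A unit is *flat* when both
the upward and downward excursions of the normalized curve stay within
20 points of 100% (configurable); otherwise the larger excursion decides
activated vs inhibited. The nicotine-vs-saline statistic is the
difference of the signed dominant variations.

Bursts follow the classic criterion for dopamine cells: onset at an
inter-spike interval below 80 ms, offset when an interval exceeds
160 ms; %SWB is the percentage of spikes inside bursts. Both thresholds
are parameters.

## cFos networks (`fosnet`)

Volcano statistics per region: Welch's unequal-variance t test,
Benjamini–Hochberg q-values across regions, and
`log2 fold change = log2((mean_b + 1)/(mean_a + 1))` (pseudo-count 1
guards zero-count regions). The pass flag is exactly
`(fold change > 0) and (−log10 p > −log10(0.05) = 1.30)`.

Correlation matrices are Pearson by default (Spearman by config) across
animals within one group; constant regions are dropped and reported.
Hierarchical modules use average linkage on the distance 1 − r with the
tree cut at k = 4 by default; the reordered matrix is a pure permutation
by dendrogram leaf order. Louvain communities are computed on the graph
whose edges are the positive correlations (negative weights are clipped
because standard weighted modularity assumes non-negative weights; an
absolute-value rule is available). The backend is igraph's multilevel
algorithm followed by a single-node-move refinement pass, so every
returned partition is a local optimum of weighted modularity; restarts
permute the vertex order under a fixed seed and keep the best Q, making
results deterministic for a given seed and node order.

**Reorganization test.** The degree of community reorganization between
two groups is measured on *consensus co-membership* matrices: for each
group, Louvain partitions are computed over 32 seeded subsamples of 70%
of the animals, and entry (i, j) is the fraction of subsamples in which
regions i and j share a community. The score is the mean absolute
difference between the two groups' matrices over region pairs; the null
is built by permuting animal group labels and recomputing both matrices
(paired subsample indices on both sides), with
`p = (1 + #{null ≥ obs}) / (n_permutations + 1)`. A consensus statistic
is used instead of a distance between the two hard partitions because
hard-partition distances saturate: when the pooled data supports two
near-tied community merges, label-permuted halves occasionally adopt
opposite merges and produce maximal null scores no matter how many
animals are available, destroying power. Co-membership frequencies
degrade continuously and do not have this atom. The hard-partition
1 − NMI value is still reported (`nmi_score`), and per-region change
flags come from the two hard partitions aligned by maximal overlap.
This significance procedure is this package's own formalization of
"community reorganization"; no published recipe is being reproduced.

## Bouton segmentation (`boutons`)

Seeds are 26-neighborhood local maxima at or above a threshold
(histogram mode + 5 robust SDs by default, or explicit); plateau maxima
resolve to the lowest linear index, and maxima on the one-voxel stack
border are discarded (border-clipped objects are not counted, and the
maximum filter's edge padding creates spurious maxima there). On noisy
stacks a Gaussian pre-smoothing of 1 voxel SD is recommended and used in
the recovery suites; all thresholds and fits then apply to the smoothed
intensities, which leaves the segmentation equivariant to intensity
rescaling.

Around each seed a 1-D Gaussian (amplitude, center, σ, offset) is fitted
to the intensity profile along each axis (anisotropic per-axis fits;
±10 voxels). The border intensity is where the central 95% of the
Gaussian's area lies: `background + exp(−1.96²/2) · amplitude ≈
background + 0.146 · amplitude` — so equally sized boutons of different
brightness segment to equal volumes. Growth is driven by a single global
priority queue ordered by candidate intensity (so a contested voxel goes
to the seed that reaches it along the brighter path) under three
criteria: intensity at or above the seed's border threshold; intensity
not above the included voxel it extends (monotone descent); and an
already-included 26-neighbor strictly closer (in µm, respecting
anisotropy) to the seed. Degenerate fits (σ ≤ 0 or no converging axis)
drop the seed. Objects outside 0.01–1.0 µm³ (configurable) are
discarded. Density is count per 10 × 10 × 10 µm standard volume =
`count · 1000 / stack volume(µm³)`.

## Currents (`currents`)

Inward currents are negative in storage; peaks and charges are reported
as magnitudes. Decays are fitted from the transient peak with 1- and
2-exponential models by bounded nonlinear least squares; the model is
chosen by small-sample-corrected AIC, with a guard that treats a
collapsed second component (amplitude share < 1% or time-constant ratio
< 1.2) as an over-parameterized mono fit. τ_w is the amplitude-weighted
mean of the time constants (τ_w = τ for mono fits). Charge is the
trapezoidal AUC of the baseline-subtracted current; the default window
runs from the 10%-of-peak crossing to the return within 2 noise SDs of
baseline (both configurable), and an explicit baseline can be supplied
so adjacent sub-windows add exactly. PPR is peak2/peak1 of two evoked
responses 50 ms apart; the AMPA/NMDA ratio decomposes a composite sweep
against its AMPA-blocked counterpart and takes the ratio of component
peaks (the component-peak convention is an interpretation — fixed-latency
measurement is not used). Drug effects are
`100 · (AUC_drug − AUC_baseline)/AUC_baseline` on averaged traces.

sEPSC detection is threshold-based (no published algorithm is being
reproduced): excursions beyond 3 robust noise SDs below the epoch
baseline that persist ≥ 0.5 ms, with a 10-ms minimum interval between
event peaks — no shorter than a typical event, so a noise-split decay
tail is not double-counted. Amplitude is read as the median of a
7-sample window at the peak because the raw minimum sample carries an
extreme-value noise bias of about +2 SD.

## Statistical battery (`stats`)

Every comparison is gated by Shapiro–Wilk on the pooled within-group-
centered residuals at α = 0.05 (residuals, not raw data — the gate
should test distributional shape, not group separation; config-exposed).
Parametric branch: Welch t (two-sample) or one-sample t vs zero.
Nonparametric branch: Wilcoxon rank-sum / signed-rank. The rank-sum p is
exact — full enumeration of label assignments with midranks under ties —
up to 14 combined observations, and a normal approximation with
continuity correction beyond; the reported W follows the
rank-sum-minus-minimum convention (the Mann–Whitney U of the first
sample). k-group designs run Kruskal–Wallis followed by pairwise
rank-sum tests with Holm correction. The two-way mixed ANOVA implements
the split-plot decomposition directly (between effect against
subjects-within-groups; within and interaction against the
subject-by-level residual; uncorrected p), reporting F = 0, p = 1 for
zero-variance effects and F = ∞, p = 0 for a nonzero effect over a zero
error term — degenerate inputs that off-the-shelf routines reject.
Corrections go through statsmodels' `multipletests` (Holm step-down,
Benjamini–Hochberg step-up), order-preserving against the input.

## Synthetic data (`synth`)

What the generators emulate, and what they do not:

- **Drinking** — per-minute gamma bout volumes (shape 4, mean 0.03 ml,
  capped at the 0.1-ml artifact threshold) gated by a von Mises
  circadian weight peaking one hour after dark onset (concentration 2),
  ~130 bouts/day ≈ 4 ml/day; bottle choice is i.i.d. Bernoulli with the
  programmed preference. Artifacts are uniform 0.11–0.5 ml minutes.
  Real lickometer data has bout autocorrelation and meal structure the
  generator omits — passing recovery tests shows bookkeeping and
  estimator correctness, not robustness to behavioral structure.
- **Spike trains** — piecewise-constant-rate renewal process with a 2-ms
  refractory period, exact mean rate per segment; the response is a
  rate step ×(1 ± magnitude) for 180 s after the injection. With
  burst_fraction = 0 the ISI chain forbids consecutive sub-80-ms
  intervals (rate-compensated, solving the stationary mean-ISI equation
  numerically), so no multi-spike burst exists by construction. Real
  dopamine responses ramp and adapt; the step is a deliberate
  simplification that makes the plateau magnitude well-defined. The
  default unit is 4.5 Hz baseline, 600-s recording, injection at 300 s.
- **Region counts** — latent equicorrelated Gaussians per planted
  module (`z = √ρ·module factor + √(1−ρ)·noise`) mapped through
  `round(mean·(1 + 0.2·z))`, so the planted correlation transfers to
  counts nearly unchanged at CV 0.2 around a base mean of 500 cells;
  group-2 means scale by the planted shift. Count overdispersion
  families (negative binomial) are not modeled.
- **Behavior** — frame-wise i.i.d. Bernoulli zone labels per block;
  CPP chamber times with Gaussian noise (SD 7 s) renormalized to 900 s.
- **Bouton stacks** — background + isotropic-in-µm Gaussian spots +
  white noise; no PSF, no autofluorescence gradients.
- **Currents** — analytic templates (bi-exponential decay; 1-ms rise /
  5-ms decay EPSC template) plus white noise; no access-resistance or
  filtering artifacts.

All generators are deterministic given (seed, parameters) and attach a
`GroundTruth` record.

## Problem sizes and tolerances in the test suites

The recovery suites run at sizes chosen to keep the whole test run on a
single CPU in minutes while leaving comfortable statistical margins: 8
drinking sessions per preference level (±3%), 200 spike units (±10
points, ≥95% classification), 100 animals/group for module recovery
(NMI ≥ 0.9), 200 null simulations at 12 animals/group and 99
permutations for the reorganization calibration ([0.025, 0.075] at
α = 0.05), 20 stacks × 20 spots at SNR 10 for segmentation
(precision/recall ≥ 0.95), and 2000 replicates per null for the gated
engine ([0.038, 0.062]). The acceptance script uses the same sizes
except 100 reorganization nulls and 10 bouton stacks. Exactness claims
(rank-sum enumeration, Holm/BH, %SWB, modularity vs exhaustive search on
≤8 nodes) are asserted at 1e-9 or tighter; Louvain must either match the
exhaustive optimum or be verifiably single-move locally optimal (the
refinement pass guarantees the latter, and ≥90% of random small graphs
hit the global optimum with 10 restarts).

## Known limitations

- The reorganization statistic is a formalization chosen here; other
  reasonable choices (edge-weight distances, ARI-based scores) would
  give different absolute scores, though the permutation framework is
  unchanged.
- The mixed ANOVA uses unweighted group means for unbalanced groups and
  reports uncorrected p (no sphericity correction).
- Bouton growth assumes roughly Gaussian, non-merging objects; heavily
  overlapping boutons are split by the brighter-path rule, not by a
  shape model.
- The AMPA/NMDA decomposition measures component peaks, not
  fixed-latency amplitudes.
- `mannwhitneyu`'s asymptotic branch (used above 14 observations)
  applies the usual tie-corrected variance; exact-with-ties beyond that
  size is not attempted.
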