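# Methods

## Data model

The unit of data is a cells x proteins reporter signal-to-noise (s/n)
matrix with missing values, wrapped with per-cell metadata (LC-MS file,
TMT channel, plate well, sorted population, index-FACS fluorescence)
and per-protein annotations in an AnnData-backed container
(`ScmsDataset`). Named layers track the processing state: `raw_sn`
(as exported), `normalized` (after median equalization and, later, the
per-cell median shift; fold changes are always computed here),
`log2`, `imputed` and `scaled`. Every operation appends to an
append-only provenance log.

A 16-row x 24-column sort plate is partitioned into 24 contiguous
16-well blocks, one per multiplexed sample (column-major, so each
column is one block). Each block maps its 16 wells onto the 16 TMTpro
channels in a seeded random order; the booster channel (126) and the
channel adjacent to it left empty for isotopic-impurity reasons (127C)
are unsorted, the other 14 receive one cell each: 24 samples and 336
cells per plate. In balanced mode the 14 single-cell channels of each
block are split across populations as evenly as possible (three
populations: 5/5/4) and shuffled — the premise of the normalization
below.

## Normalization and quality control

**Iterative median equalization.** With a balanced, channel-randomized
layout the true median of every protein is the same in every file and
every channel, so per-file and per-channel multiplicative biases are
identified without a bridge channel. Each iteration sweeps files then
channels; a sweep multiplies each level so its per-protein median
(missing values ignored) matches that protein's grand median, defined
as the median of the per-level medians. Sweeps update the current
matrix (Gauss-Seidel style). Iteration stops when the largest absolute
elementwise change of the matrix relative to the previous iteration
falls below 1.1 s/n — an absolute criterion, chosen because 1.1 s/n
sits just above the reporter noise floor; a relative criterion would be
scale-free and lose that anchoring. Factors accumulate per protein per
level and are returned for inspection. Non-convergence at `max_iter`
warns and flags the result rather than failing silently. Proteins
absent from a level are left untouched in that sweep.

**Noise floor.** After normalization, values strictly below 1.1 s/n
are set to missing (the boundary value is kept).

**Cell QC.** The log2 of each cell's total summed s/n separates intact
single cells from empty wells, doublets and preparation losses. Cells
outside `median ± 3 × 1.4826 × MAD` (the 1.4826 makes the MAD
sigma-consistent for normal data), or with fewer than a configurable
number of observed proteins, are removed with a per-cell reason.
Residual technical structure is audited per factor (file, channel,
plate row) by Kruskal-Wallis heterogeneity and per-level Mann-Whitney
tests on summed intensity and protein count, plus Cramér's V between
each technical factor and the population label — a factor confounded
with biology cannot be normalized away and the affected rows may need
exclusion instead (`exclude_rows`).

**Protein filter, shift, transform.** Proteins quantified in fewer
than 3 cells are dropped ("fewer than" is exclusive). Per-cell totals
are then equalized to the median total (cell size/sampling depth), and
the matrix log2 transformed. The shifted pre-log matrix replaces the
`normalized` layer so that downstream fold changes never touch imputed
or log values.

## Imputation and embedding

Low-coverage proteins tend to be low-abundance and imputing them mostly
injects noise, so the coverage cutoff is selected per dataset: each
candidate threshold is evaluated by imputing, scaling, embedding to
2-D UMAP with a fixed seed, and scoring the mean silhouette of known
labels; the argmax wins, ties going to the lowest threshold (keeps the
most proteins). Imputation is k-nearest-neighbour (k = 5): cell-cell
distance is the root mean squared difference over mutually observed
proteins (rescaling by the shared-feature count keeps distances
comparable under missingness); a missing entry becomes the mean of the
protein's observed values among the k nearest cells, falling back to
the protein's global mean when none of them observes it. Observed
entries are never altered. Scaling is per protein to zero mean and
unit sample variance (ddof 1); constant proteins scale to zeros with a
warning.

Embeddings run through scanpy: PCA, a k-nearest-neighbour graph
(default 15 neighbours), then UMAP (min_dist 0.5), diffusion maps
and/or a force-directed layout, all seeded. Diffusion pseudotime is
computed from a root cell (pseudotime 0) and scale-normalized to
[0, 1]; unreachable cells get missing values rather than a sentinel.
The default root is the extremal cell of a named population along the
first non-trivial diffusion component. For one-dimensional
differentiation continua we use 2 diffusion components for pseudotime —
the minimal choice for a single linear trajectory, and the most stable
in recovery experiments — and leiden resolution 0.5 for the
trajectory-selection clustering on datasets of a few hundred cells
(resolution 1.0, the config default, yields ~60-cell clusters whose
one-vs-rest tests amplify censoring-bias fold changes; see
Limitations).

## Statistics

Group comparisons use a two-sided Welch t-test per protein on the log2
layer, missing values excluded and never imputed; proteins with fewer
than 3 observed values in either group are reported untested.
Identical degenerate groups (zero variance, zero difference) are
defined as t = 0, p = 1. P-values are Benjamini-Hochberg adjusted;
significance combines q < 0.05 with an optional |log2FC| floor. Fold
changes are log2 ratios of group means on the pre-log normalized
layer. Term enrichment is the upper-tail hypergeometric probability
P(X >= k) per term, BH-adjusted across terms; terms without foreground
hits report p = 1. Trajectory-variable proteins are the union over
leiden clusters of proteins passing, in a one-vs-rest comparison:
detected in >= 200 cells, |log2FC| >= 0.15, BH q < 0.05 (a config
switch allows raw p). For display, selected proteins are ordered by
pseudotime, smoothed by a centered 50-cell moving average (windows
truncated at the edges, no padding), min-max normalized to [0, 1] per
protein (constants map to 0), hierarchically clustered (correlation
distance, average linkage — pattern-based, configurable) into five
clusters, and aggregated into per-cluster mean signatures, again
min-max normalized.

## Replicate benchmarking

Technical replicates of one pooled sample measured at different
injection-time (IT) settings are compared by first equalizing, per
protein, each replicate's median over the single-cell channels to the
median of those medians (one factor per protein per replicate). The
per-channel CV is the sample SD (ddof 1, since n is typically 3) of
the *normalized* values across replicates divided by the mean of the
*raw* values; channels seen in fewer than two replicates are skipped
and only proteins present in every replicate are scored. The per-
protein mean CV (over up to 14 channels) summarizes precision, and the
fraction of proteins with mean CV < 20% summarizes a setting. Accuracy
is the Pearson correlation of population log2 fold changes against a
reference, with complete-case, shared-protein and top-N-coverage
subset variants, and a binned view of |ΔFC| across equal-count mean
log2 s/n bins (quantile binning, configurable).

## Integration of unbalanced designs

Median equalization assumes balanced composition, which fails when a
pre-enriched experiment meets an unbiased bulk-sorted one. Such
datasets are first coverage-filtered (>= 40% valid values per protein,
inclusive), reduced to the shared protein space, imputed, scaled and
jointly PCA-transformed; then every non-reference dataset is aligned
to the reference by mutual-nearest-neighbour (MNN) translation: mutual
pairs are detected in PC space, pairs farther than 5x the reference's
own nearest-neighbour scale are discarded (if none survive, the
datasets share no detectable populations and an error is raised), one
anchor — the closest mutual partner — is kept per target cell so that
identical datasets anchor each cell to its own copy with a zero
vector, and each cell receives a Gaussian-kernel weighted average of
the anchor vectors. A `panorama` backend delegates to the external
scanorama package when installed; the built-in backend exists so the
integration contract is testable without it.

## The synthetic-data generator

The generator emulates the statistical structure of booster-channel
scMS so every stage has ground truth:

* three populations (defaults: stem at tau 0.10, progenitor 0.50,
  blast 0.85, weights 5/14, 5/14, 4/14, per-cell jitter sd 0.08) on a
  latent differentiation axis tau in [0, 1]; a continuum mode draws
  tau uniformly and labels cells by the nearest centre;
* per-protein log2 baselines ~ Normal(2.5, 1.5) — median s/n of a few
  units, matching published single-cell channel medians — with 20% of
  proteins varying linearly in tau (|slope| uniform in 0.8–2 log2
  units across the axis);
* two designated FACS-marker proteins (one falling, one rising in
  tau) with baselines at mean + 1.5 sd: surface markers like
  CD34/CD38 are abundant and precisely measured; index-FACS
  fluorescence is a monotone transform of tau with log-scale noise;
* per-cell size factors (log2 sd 0.25), per-file batch factors
  ~ LogNormal(0, 0.30) and per-channel factors ~ LogNormal(0, 0.15);
* additive booster bleed: a fraction lambda = 0.002 of the 200-cell
  booster signal leaks into the mass-adjacent channels (127N, 127C,
  128C) — about 0.4 cell-equivalents, the magnitude that motivates
  leaving 127C empty; an ambient background of 0.5% of baseline keeps
  empty wells above exactly zero;
* counting-statistics measurement noise: the log-normal sigma for an
  entry of true signal s at injection time IT is
  `sigma_noise * sqrt(it_ref/IT) * sqrt(sn_ref/s)` (sn_ref = 8 s/n,
  capped at 2), so precision improves with both abundance and ion
  sampling — the behaviour seen in published CV-vs-s/n densities; the
  plate-level default sigma_noise is 0.1 at the 500 ms reference;
* abundance-dependent detection: P(observed) =
  logistic(-1 + 0.8 log2 s) on the true signal, giving ~45-55%
  missingness at the default abundance program;
* empty wells (background only) and doublets (pre-noise sums of two
  cells' true abundances) at configurable rates, both zero by default.

Technical replicates share one pooled sample: each of the 14 channels
is a pool of 12 cells of a fixed population (5/5/4 across channels),
and replicate injections at each IT level differ only in measurement
noise and detection depth (the measured scale grows proportionally to
IT). The replicate benchmark configuration uses sigma_noise = 0.4 with
the 150/300/1000 ms levels, calibrated once so the simulated
%CV < 20% spans the published precision range (roughly 10% to 99%
across that sweep).

What the generator does **not** emulate: peptide-to-protein rollup and
shared-peptide effects, co-isolation interference, the scan-speed /
proteome-depth trade-off of long injection times (only s/n scaling and
noise are modelled), FAIMS gas-phase fractionation, plate-position
(row/edge) effects unless injected explicitly, and non-linear
population structure (branching trajectories). Passing recovery tests
therefore demonstrate correctness of the algorithms under the stated
generative assumptions, not instrument-level realism.

**Factor-recovery oracle.** The batch factor a file or channel carries
in the generated data is the injected factor composed with that
level's sampling-composition offset (its 14–20 cells happen to be
larger or smaller, or drawn from slightly different tau positions).
Median equalization removes the composite — as it should — so recovery
is scored against `injected_level_effects(...)`: per protein, the
level's median true signal relative to the grand median, aggregated by
the median over proteins, times the injected factor. Against the bare
factor alone the apparent error would be dominated by the ~3-5%
sampling term at realistic cells-per-level counts.

## Test problem sizes

The validation suite simulates one to three 384-well plates with
300–1000 proteins: 500 proteins x 280 cells (20 files x 14 channels)
for factor recovery, ~1000 wells for QC sensitivity, a ~500-cell
continuum (two 18-column plates) for trajectory recovery, 500 proteins
for the IT sweep, and a split plate with an injected per-protein shift
for the integration contract. These sizes keep every recovery
statistic well-determined while the full suite runs in well under a
minute per scenario.

## Known limitations

* Missingness in scMS is not at random: values are censored below the
  detection/noise floor. Group means over observed values are
  therefore biased, and one-vs-rest fold changes between cell clusters
  that differ in sampling depth can exceed the 0.15 selection floor
  for truly flat proteins. The coverage filters mitigate but do not
  remove this; cluster granularity should stay coarse on small
  datasets (see resolution note above).
* The median-equalization identifiability argument needs a balanced,
  randomized layout; for unbalanced designs only the MNN/panorama
  route is valid, and it requires overlapping populations across
  datasets.
* The convergence criterion is absolute (s/n units), so normalization
  is scale-equivariant only when the threshold is rescaled alongside a
  global rescaling of the data.
* Pseudotime assumes a single connected trajectory; cells unreachable
  from the root are reported missing, and branching topologies are out
  of scope.
* The imputation kNN metric treats proteins as exchangeable after
  rescaling by shared-feature count; heteroscedastic alternatives were
  not pursued.
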