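# Methods

`paleoveg` classifies vegetation ("open" grasslands, savannas, steppes,
desert vegetation and tundra versus "closed" forest) at arbitrary points
in space and geologic time, from two information channels: the spatial
and temporal proximity of fossil and current occurrences of selected
taxa, and abiotic predictors (paleoclimate, elevation, global climate
curves, coordinates and age). The classifier is a Bayesian neural
network whose weights are sampled by Markov chain Monte Carlo, so every
prediction is a posterior distribution over class labels rather than a
point estimate.

## Temporal discretization

Ages are binned into the geological stages of the International
Chronostratigraphic Chart (v2020/03), embedded as package constants;
17 stages intersect the default 0–30 Ma study window. Every dated
record is moved to the midpoint of its containing stage. Stage
intervals are treated as half-open `[top, base)`: an age exactly on a
shared boundary belongs to the older stage. The chart is silent on this
choice; any fixed convention works, and this one is deterministic and
documented. A user-supplied CSV (`name, top_ma, base_ma`) can override
the embedded table.

## Occurrence curation

Occurrence tables are expected to arrive pre-curated (species-level
identification, name reconciliation, removal of aquatic groups handled
upstream); the package validates the schema, crops records to the study
window, removes spatiotemporal duplicates — identical
(taxon, lon, lat, stage), first record kept — and filters taxa by a
range-through criterion: a taxon is informative if the inclusive stage
span between its first and last occurrence covers at least 9 of the 17
stages. Presence is range-through (assumed in all interior stages), not
an observed-stage count, so a taxon seen only in stages 3 and 14 spans
12 stages and is kept. Duplicates are defined on stage-discretized ages,
matching the midpoint rounding applied to all dated records.

## Feature generation

For each instance (a point with longitude, latitude, age) and each
taxon, the biotic block stores one (Δs, Δt) pair per stage: Δs is the
Euclidean distance, in an Albers equal-area conic projection (standard
parallels 29.5°N/45.5°N, central meridian −96°, origin 23°N — the
conventional North America setup, configurable), to the taxon's nearest
occurrence in that stage, computed from present-day coordinates under
the assumption that relative within-region distances are negligibly
affected by plate motion over 30 Myr; Δt is the absolute difference
between the instance age and the stage midpoint (absolute value keeps
distances nonnegative). The projection is implemented directly from the
spherical Albers formulas (authalic radius 6371.0088 km) and verified
by symmetry, triangle-inequality and known-length tests.

Stages in which a taxon has no occurrence receive a sentinel Δs equal
to the projected diagonal of the crop window — an upper bound on any
real within-window distance, which scales to ≈1 ("maximally far"). The
sentinel is configurable; it keeps the tensor dense without a missing-
data mechanism.

The abiotic block holds 8 predictors: temperature, precipitation and
elevation sampled from gridded surfaces at the instance's
paleocoordinates (nearest-valid-cell fallback inside no-data regions),
global mean temperature and CO2 interpolated from scalar curves at the
instance age, and the paleocoordinates and age themselves. Gridded
surfaces provided at coarse ages are linearly interpolated cellwise to
the query age; queries outside the covered range clamp to the nearest
slice with a warning. Rasters are read and written as plain-text
(ESRI ASCII) grids, one file per variable per time slice with the age
in the filename. Paleocoordinates are accepted as precomputed input
columns (`paleolon`, `paleolat`); when absent, present-day coordinates
are used with a warning — plate rotation is intentionally outside this
package's scope.

All features, distances included, are min–max scaled to [0, 1]
*jointly* across every instance a model will see (training and
prediction), so train and prediction features share one mapping; the
bounds are persisted with a trained model for later batches. Constant
columns map to 0. A perturbation utility implements the raster
sensitivity test: each selected value v is resampled from
Uniform(v·(1−level), v·(1+level)).

The reported feature count is one per taxon plus the 8 abiotic columns
(e.g. 100 taxa → 108 features); the per-stage distance pairs are not
separate features because the network's first two layers reduce them to
one proximity value per taxon.

## Network architecture

With Δs_ij, Δt_ij the scaled distances of taxon i at stage j, the
forward pass is

1. h¹_ij = g(w_s·Δs_ij + w_t·Δt_ij) — two scalar weights shared across
   all taxa and stages;
2. h²_i = g(Σ_j h¹_ij · W²_ij) — a per-taxon contraction over stages
   with taxon-by-stage weights, one "proximity" node per taxon;
3. optional pooling of the taxon nodes into exactly one faunal and one
   floral feature (max- or sum-pooling over the mammal and plant taxa
   respectively), or the identity;
4. fully connected hidden layers h = g(Wx) and a softmax output over
   the two classes, g being the swish activation x·sigmoid(x)
   throughout.

No layer carries bias terms; the layer equations contain none. The
softmax is stabilized by max-subtraction, which is exact by shift
invariance. Class order is fixed as [closed, open] everywhere and the
reported posterior probability (PP) is that of "open". Either input
block can be switched off (`use_biotic` / `use_abiotic`) to fit
biotic-only or abiotic-only models.

## Priors, likelihood and sampling

Every weight has an independent standard-normal prior; the likelihood
is categorical, floored at 1e−12 per instance to survive degenerate
softmax outputs. Weights start at Normal(0, init_sd), init_sd 0.1.
All weights are sampled jointly by Metropolis–Hastings: each iteration
perturbs a random 5% subset of the flattened weight vector with
Gaussian steps (sd 0.1) and accepts with probability
min(1, exp(Δ log posterior)). Subset updates keep acceptance workable
in the ~300-dimensional weight space; symmetric proposals reduce the
acceptance ratio to the posterior ratio. The proposal scale and subset
fraction were chosen so that a prior-only chain (constant likelihood)
reproduces the standard normal — the sampler's built-in correctness
check, enforced in the test suite via the Kolmogorov–Smirnov distance
of pooled thinned samples (bound 0.05 at 50,000 iterations) — while
data-driven chains still accept 50–80% of proposals.

Chains default to 200,000 iterations thinned every 200; the desk-scale
analyses in the tests and the acceptance script use 50,000 iterations,
which suffices for the default synthetic world. The first 10% of
iterations is flagged as burn-in but retained in the trace. Chains are
resumable from their final state (appended samples flagged, never
burn-in) and refuse a mismatched architecture via a config hash. One
seeded RNG drives each chain, so traces are bit-reproducible.

## Prediction and uncertainty

The PP of each class for a new instance is the mean class probability
across post-burn-in weight samples; per-sample argmax classes are kept
so that downstream fractions have full posterior distributions. A PP
threshold converts probabilities to labels: an instance whose
winning-class PP (max of pp_open and 1−pp_open) falls below the
threshold is "unknown". The threshold applies to the winning class —
symmetric in the two labels — rather than one-sidedly to pp_open. It is
calibrated on labeled data as the smallest value on a 0.01 grid over
[0.5, 1.0] whose retained predictions reach a target accuracy (default
90%); when no threshold attains the target it is set to 1.0 and
everything is reported unknown.

Open-habitat fractions through time are computed per posterior sample
(open cells / land cells at each age), then summarized by the mean and
the 95% highest-posterior-density interval — the shortest contiguous
window of sorted samples holding ⌈0.95·n⌉ of them, chosen because it is
exactly testable against brute force. The expansion rate at age t is
the mean-fraction change over the preceding 1-Myr bin, positive while
open habitat expands toward the present. Cells classified unknown are
excluded from both numerator and denominator of habitat-association
fractions (configurable); per-sample fraction series use argmax classes
and therefore have no unknowns.

## Evaluation

Models are scored by 5-fold cross-validation stratified by instance
source, so each fold preserves the paleo:current ratio to within one
instance. The headline accuracy is the 10:1 weighted mean of the pooled
paleo and current test accuracies (the paleo set spans many stages, the
current set one); pooled — not fold-averaged — accuracies are the
headline numbers, with per-fold values logged. Threshold calibration
uses the pooled paleovegetation test predictions when any exist.

Permutation feature importance shuffles one feature across instances
and reports Δacc = baseline accuracy − shuffled accuracy, per posterior
weight sample (default 100 randomly selected post-burn-in samples),
with the baseline recomputed per sample rather than on the
posterior-mean prediction. A taxon's biotic feature is shuffled as a
unit — its whole per-stage distance block, spatial and temporal
together — because importance is reported at the taxon level;
permutations are drawn once per feature and reused across samples so
per-sample Δacc values are comparable.

## Synthetic data

The generator emulates the structure of the real inputs without
mimicking real biogeography. The latent field is a latitudinal
open/closed frontier drifting with age (open iff latitude >
lat0 + shift·age; defaults lat0 40°, shift 0.5°/Myr on a 30–50° grid),
chosen so true open fractions and expansion rates have closed forms for
oracle tests. Defaults are sized for fast runs: a 20×20 one-degree
grid, 10 slices over 27 Myr, 12 taxa (two open specialists, two forest
specialists, two generalists per group; specialist affinity 0.9) with
Poisson(8) occurrences per taxon and slice (~1,000 records). Abiotic
surfaces are linear baseline gradients plus an additive open-state
effect (temperature +8 °C, precipitation −400 mm/yr, elevation 0 by
default) plus Gaussian noise (temperature sd 0.5, scaled per variable);
global curves are linear in age. Training points sit at cell centers so
labels read directly off the truth field, with an optional label-noise
rate.

What the generator does not emulate: realistic coastlines or land
masks, taphonomic and spatial sampling biases, correlated noise fields,
taxon range dynamics, or dating uncertainty. Passing the recovery tests
therefore demonstrates that the pipeline recovers a signal it is built
to represent, not that real-data accuracies are attainable at desk
scale.

Because the generator's spatiotemporal features (latitude, age) fully
determine the latent frontier, a "no-signal" control cannot be obtained
merely by removing the habitat bias and abiotic effects — the labels
would remain a deterministic function of the coordinates. The
chance-level control therefore additionally randomizes labels
(label-noise 0.5), making them independent coin flips; cross-validated
accuracy must then fall within binomial noise of 0.5.

## Numerical and design notes

- Problem sizes in tests and the acceptance script: 200 training
  points (100 paleo + 100 current), 50,000-iteration chains, 5 folds;
  one end-to-end evaluation takes ~2 minutes on one CPU.
- At a PP of exactly 0.5 the argmax convention assigns "closed"
  (class index 0); ties are vanishingly rare with continuous weights.
- The bias-free architecture forces the decision boundary through the
  all-features-at-minimum corner of the scaled feature space; real
  instances never occupy that corner, and the joint 0–1 scaling keeps
  informative features away from it.
- `hpd_interval` returns the first shortest window under ties
  (lowest start), and degenerates to a point interval for n < 2.
- Max- and sum-pooling are the two implemented reductions of the taxon
  nodes; they collapse the classifier input from (n_taxa + 8) to
  (2 + 8) exactly.
- An empty dataset (or `data=None`) makes the likelihood constant, so
  the chain samples the prior — used as a correctness oracle rather
  than an error.
- Trace files are a compressed array container (`.npz`) with a JSON
  sidecar carrying settings, config hash, acceptance rate and seed;
  prediction commands refuse traces whose config hash does not match.

## Known limitations

- Random-walk MH scales poorly beyond a few thousand weights; the
  default architectures stay small (hundreds of weights). No adaptive
  proposals, parallel tempering or gradient-based samplers.
- Only the single built-in equal-area projection; no raster
  reprojection, no great-circle distance option.
- GeoTIFF is not supported; rasters must be plain-text grids.
- Plate rotation is not computed; paleocoordinates must be supplied, or
  present-day coordinates are used as-is.
- The threshold grid is fixed at 0.01 resolution over [0.5, 1.0].
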