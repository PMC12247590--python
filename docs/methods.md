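# Methods

## Model and assumptions

comICA assumes that an evoked response which is *real* (stimulus-locked
neural activity rather than noise) appears in every recording of the same
subject performing the same task, with the same time course and the same
field topography up to an intensity factor. Three assumptions make the
algorithm work:

1. **Linearity** — sensor data are a linear superposition of source
   contributions, so a lead-field column times a source time course is a
   rank-1 term in the data matrix.
2. **Temporal independence** — distinct sources have (approximately)
   independent time courses, so temporal ICA can factor the data into
   components.
3. **Spatial consistency** — a reproducible component has the same field
   pattern in every recording, up to a positive scale; cosine similarity is
   therefore the right comparison, since it deliberately ignores intensity
   differences between sessions (head position and SNR change between
   visits, topography does not).

Concatenating the recordings along the channel axis before ICA forces one
shared set of source time courses; all between-recording differences are
pushed into the mixing matrix, where they can be measured per component.

The method applies to recordings of one subject. Across subjects the
"same" response has genuinely different topographies (anatomy differs), so
cross-subject blocks would rarely pass a similarity threshold; group
analyses should apply comICA per subject first.

## Similarity metric and centering

The weighted mode computes the cosine under the metric `C⁺`, the
pseudoinverse of the covariance of the centered patterns
(`C = (1/(M·N)) Σ ā ā'`, the two-recording normalization `1/(2N)`
generalized to `M`). Centering the patterns is part of this
Mahalanobis-style construction: the covariance is defined about the mean
pattern, and distances are measured in the whitened pattern space. `C` is
estimated from only `M·N` samples in an `n_sens`-dimensional space, so it
is rank-deficient whenever `M·N < n_sens` — the expected regime — hence
the pseudoinverse, truncating eigenvalues below `rank_tol` (default
`1e-10`) times the largest.

The identity (unweighted) mode is the plain cosine between the raw mixing
columns' per-recording segments. It deliberately does *not* center: with
few components (the simulation protocol extracts three, giving six
patterns) the grand mean pattern contains a large share of whatever
pattern is common to the recordings, and subtracting it would remove
precisely the reproducible structure whose presence is being tested.
Measured on the simulation conditions, centering in unweighted mode
roughly halves the fraction of iterations in which the shared component
survives selection. The weighted mode needs enough components for a
meaningful covariance (the quantile selection additionally requires at
least 20 between-component similarities); with three components the
unweighted mode is the appropriate choice, and is what the simulation
study uses.

## Component selection

A component is retained when every entry of its `M × M` similarity block
exceeds the threshold. Two threshold policies:

* `fixed_threshold` (default 0.9): the simulation protocol's choice.
* `distribution_quantile`: the similarities between patterns of
  *different* components form an empirical null of "unrelated topography"
  similarity; the threshold is its `1 − α` quantile (α default 0.05).
  This mode errors out below 20 null samples and directs the caller to
  the fixed threshold.

Antiparallel patterns (`d ≈ −1`) are rejected like any sub-threshold
block; a sign-flipped match is not treated as reproducible.

Empty retained sets are legal (the reconstruction is the zero signal plus
restored means) and are flagged in logs and diagnostics rather than raised
as errors: "nothing reproduced" is a valid scientific outcome.

## ICA backend and conventions

`decompose` uses scikit-learn's FastICA (fixed-point negentropy
maximization, log-cosh contrast, PCA whitening to `n_components`
dimensions), seeded by the caller. `n_components="full"` uses the
numerical rank of the centered concatenated data. Components are reported
in descending order of explained data variance (`‖A_i‖²·‖s_i‖²` over the
total), and source signs are normalized so each time course's
largest-magnitude sample is positive; selection and reconstruction are
invariant to both conventions. Mean restoration after reconstruction is on
by default so that cleaned and raw recordings are directly comparable;
real-data workflows typically follow with `baseline_correct`.

ICA on a trial-averaged evoked estimates higher-order statistics from only
`T ≈ 280` samples, and the Morlet sources are deterministic curves whose
temporal overlap makes them statistically dependent even when their
correlation is near zero. Separation therefore fails in a minority of
simulated iterations even without noise — the "fat tail" of the GoF
distribution. This is a property of the problem, not of a particular
solver: alternative contrast functions (`cube`, `exp`), tighter tolerances
and multi-restart strategies were measured and change the failure rate by
at most a few percent. Running ICA on trial-concatenated (unaveraged)
epochs was also measured and performs worse at the default noise level:
the per-trial SNR is √60 lower, which corrupts the estimated patterns more
than the 60-fold sample count helps.

## Synthetic head model

The simulator replaces anatomy-based forward modeling with a parametric
stand-in: dipoles on a hemisphere (radius 0.07, arbitrary head units),
sensors on a concentric cap (radius 0.10), and each lead-field column a
difference-of-Gaussians profile in the angular distance between sensor and
source directions (positive core 0.25 rad, negative surround 0.55 rad,
surround weight 0.55) — mimicking the signed structure of dipolar field
patterns and the decay of topography overlap with source separation
(maximally distant sources have |cosine| ≈ 0.1). Positions get a 1% seeded
jitter, so heads are reproducible from their seed. Columns are calibrated
so a 55 nAm dipole yields unit peak sensor amplitude; every evaluation
metric (GoF, ratios, correlations) is scale-free, so this gain convention
affects nothing measurable. Default 204 sensors mirror a planar
gradiometer array; tests use 32–64 sensors for speed.

What the generator does **not** emulate: realistic depth-dependent gain
variation (columns are near-equal norm by construction), magnetometers,
spatially structured physiological noise (an optional correlated-noise
mode exists but is not the default), inter-trial latency jitter, and
anatomical variation between sessions. Passing the simulation study
therefore demonstrates the algorithm's behaviour under its own model
assumptions, not performance on real recordings.

## Simulation conditions

Per iteration: three distinct dipoles (one shared, one unique per run);
Morlet parameters drawn uniformly (`α ∈ [40, 70]` nAm, `T ∈ [95, 500]` ms,
`t0 ∈ [T/2+50 ms, 1150 ms−T/2]`, phase fixed at π/3, `σ = 0.375·T`,
`ω = (3/4)·2π/T`); 60 trials per run with i.i.d. Gaussian sensor noise of
standard deviation `noise_scale` (default 1.5) times the shared source's
peak sensor amplitude, averaged into evokeds — giving an averaged-evoked
peak-channel amplitude SNR of √60/1.5 ≈ 5, a moderate value chosen since
the real noise level such data would have is scenario-dependent. Windows
are [−0.2, 1.2) s at 200 Hz, i.e. 280 samples with sample `k` at
`tmin + k/sfreq`.

The study protocol runs comICA with 3 components, unweighted cosine and
fixed threshold 0.9, and scores each run's mean-restored reconstruction
against the noiseless shared-only field at the shared source's peak
sample: `GoF = 100·(1 − Σ(true−est)²/Σ true²)`. No re-centering is applied
to the reconstruction before scoring: with means restored, a noiseless
single-source reconstruction scores exactly 100, which anchors the scale.

The distributed study size is 500 iterations (1,000 per-run GoF values), a
scale at which the full study completes in a couple of minutes on one CPU;
the per-run success probability under these conditions is close to 0.5,
so the median GoF sits near the success plateau (~93–95%) but fluctuates
by one to two points across study seeds.

Summary statistics: median GoF; fraction of values above a configurable
cutoff (default 80%); per-covariate binned medians in 8 equal-occupancy
bins with nonparametric bootstrap (1,000 resamples) 95% confidence limits.
The four covariates are the sensor-level RMS amplitude ratio
(unique/shared), the great-circle distance between the dipoles, the
Pearson correlation of the two source time courses, and the shared
source's fraction of the noiseless sensor variance.

## Numerical and design choices

* **Epoch equalization** keeps the first `min(counts)` epochs of each set
  (drop-from-end): deterministic and order-preserving.
* **Peak-to-peak rejection** is per channel: an epoch is dropped when any
  channel's max−min exceeds the threshold, the common artifact-rejection
  convention.
* **Channel order** is enforced, not assumed: `align_channels` reorders by
  channel name and errors on set mismatches.
* **Similarity edge cases**: zero-norm patterns get similarity 0 against
  everything (flagged); `D` is symmetrized and clipped to [−1, 1] to
  suppress rounding excursions; diagonal pinned at 1.
* **Quantile selection null**: all off-block entries of `D` (symmetric
  duplicates included; they do not shift the empirical quantile).
* **Determinism**: every stochastic step (head jitter, parameter draws,
  trial noise, ICA initialization) flows from caller-supplied seeds;
  identical (config, seed) pairs give byte-identical study outputs.

## Known limitations

* Reproducibility scoring needs `M·n_sens ≫ N` patterns for the weighted
  metric to be estimable; with few components use the unweighted mode.
* Components whose time courses overlap strongly (temporal correlation
  near ±1, or same support with similar frequency content) may not be
  separable by ICA at all; comICA then either misses the shared component
  or retains a mixture. The binned covariate summaries quantify this.
* The selection rule is all-or-nothing per component; partially
  reproducible components (reproducing in a subset of recordings when
  `M > 2`) are rejected.
* The synthetic head is a stand-in; absolute GoF levels depend on its
  geometry and the assumed noise, so simulation results transfer to real
  data only qualitatively.
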