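# comica

**comICA** extracts the evoked-response signal components that reproduce
across repeated MEG recordings of the same subject — e.g. two sessions of
the same task on different days — and reconstructs each recording from
those components only. It is aimed at individual-level (rather than
group-level) analyses of evoked responses, where the question is whether a
subject's stimulus-locked activations are consistent from one measurement
to the next, and at denoising: everything that does not reproduce across
recordings is projected out.

## Method

Given `M ≥ 2` evoked recordings with identical channel sets (each a
`n_sens × T` matrix of trial-averaged sensor data), comICA:

1. **Concatenates** the recordings along the channel axis into
   `x ∈ R^{(M·n_sens) × T}` and removes each row's mean.
2. **Decomposes** `x = A·s` by temporal ICA (FastICA, log-cosh contrast,
   PCA whitening). Because the recordings share the time axis, every
   independent time course `s_i` is common to all recordings by
   construction; all recording-specific structure lives in the mixing
   matrix `A`.
3. **Splits** each mixing column `i` into `M` spatial field patterns
   `a_{i,k}` (one per recording `k`) — interpretable as the magnetic field
   topography of component `i` in recording `k`.
4. **Scores reproducibility** with the metric cosine similarity

   `d_{h,j} = (a_h' C⁺ a_j) / sqrt((a_h' C⁺ a_h)(a_j' C⁺ a_j))` ∈ [−1, 1],

   where `C⁺` is the pseudoinverse of the covariance of the centered
   patterns (weighted mode), or the identity (plain cosine, recommended
   when `M·N` is small). The pairwise similarities form a matrix `D` whose
   `M × M` diagonal blocks `B_i` compare component `i`'s patterns across
   recordings.
5. **Selects** the components whose block entries all exceed a threshold —
   a fixed value (0.9 in the simulation protocol) or the `1 − α` quantile
   of the between-component similarities.
6. **Reconstructs** `x̃ = A_r·s_r` from the retained components and splits
   it back into `M` cleaned recordings.

The package also ships the full simulation study used to validate the
algorithm: two runs per iteration, each containing one Morlet-wavelet
source shared between the runs and one run-unique source
(`s(t) = α·cos(ω(t−t0)+φ)·exp(−(t−t0)²/2σ²)`, with `σ = 0.375·T`,
`ω = (3/4)·2π/T`, `φ = π/3`, and `α ∈ [40, 70]` nAm, `T ∈ [95, 500]` ms,
`t0 ∈ [T/2+50 ms, 1150 ms−T/2]` drawn uniformly), projected through a
synthetic hemispherical head model, with 60 noisy trials per run averaged
into evokeds at 200 Hz over −0.2…1.2 s. Reconstructions are scored by the
goodness of fit at the shared source's peak time,
`GoF = 100·(1 − Σ(true−est)²/Σ true²)` in percent.

## Worked example

Simulate two 64-channel runs that share one source (plus one unique source
each, 60 noisy trials averaged), then recover the shared component:

```python
import numpy as np
from comica import (SimConfig, SourceSpec, build_synthetic_head,
                    simulate_run, morlet_source, ComICA)
from comica.evaluation import gof

cfg = SimConfig(n_sens=64, n_src=32, noise_scale=1.5, seed=2)
head = build_synthetic_head(cfg.n_sens, cfg.n_src, cfg.seed)
shared = SourceSpec(alpha=55.0, T=0.20, t0=0.35, dipole_index=4)
uniques = [SourceSpec(alpha=50.0, T=0.25, t0=0.70, dipole_index=11),
           SourceSpec(alpha=60.0, T=0.15, t0=0.85, dipole_index=23)]
rng = np.random.default_rng(0)
runs = [simulate_run(shared, u, head, cfg, rng)[0] for u in uniques]

est = ComICA(n_components=3, metric="identity", threshold=0.9,
             random_state=0)
cleaned = est.fit_transform(runs)
print("retained components :", est.retained_)
print("block minima        :", np.round(est.selection_.per_block_min, 3))

tc = morlet_source(shared, cfg.sfreq, cfg.window)
peak = int(np.abs(tc).argmax())
true_field = head.leadfield[:, 4] * tc[peak]
for k, rec in enumerate(cleaned):
    print(f"run {k+1} GoF at peak  : {gof(rec.data[:, peak], true_field):.2f} %")
```

Output:

```
retained components : (2,)
block minima        : [ 0.068 -0.181  0.966]
run 1 GoF at peak  : 95.95 %
run 2 GoF at peak  : 96.45 %
```

Only component 2 has cross-run pattern similarity above 0.9 (0.966) — that
is the shared source; the two run-unique components have dissimilar
patterns (0.068, −0.181) and are projected out. The cleaned recordings
match the noiseless shared-source field at its activation peak to ~96%.

The same pipeline is available from the shell:

```bash
comica fixtures --out fx/                     # tiny deterministic datasets
comica run -i fx/fixture_run1.h5 -i fx/fixture_run2.h5 \
       --metric identity --threshold 0.9 --n-components 3 --out out/
comica simulate --iterations 10 --seed 0 --out sim/
comica evaluate --iterations 100 --seed 0 --out study/
```

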