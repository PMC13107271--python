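# dielcorrect

False-positive-aware Bayesian estimation of diel (24-hour) activity patterns
from AI-labeled wildlife detections.

Automated classifiers — acoustic song detectors, camera-trap image models —
produce time-stamped species detections faster than humans can verify them.
Some of those detections are wrong, and when the errors cluster at particular
times of day (a nocturnal look-alike species, wind noise at dawn) the pooled
activity histogram acquires spurious peaks. `dielcorrect` is for ecologists
who have a large AI-labeled detection table and a human-verified subset of
it, and want the species' diel activity pattern with the false positives
modeled out rather than ignored.

## Model

The day is split into J equal time-of-day bins (default hourly, J = 24).
Each detection i falls in bin b_i and is a true positive with probability θ,
the dataset-average true-positive rate. Verified records have known labels;
unverified records follow a two-component mixture:

    uniform errors:  p(b_i | θ, f)            = θ f[b_i] + (1 − θ)/J
    skewed errors:   p(b_i | θ, f_true, f_fp) = θ f_true[b_i] + (1 − θ) f_fp[b_i]

where f (f_true) is the species' activity histogram over the day and f_fp is
a learned false-positive histogram for temporally clustered errors. Priors
are Beta(1,1) on θ and flat Dirichlet on each histogram; posteriors are
sampled by conjugate data augmentation (4 chains × 1000 iterations, 500
warmup) with rank-normalized split R-hat ≤ 1.01 and bulk ESS > 400 required
for every parameter. Agreement between two patterns is the overlap
coefficient Δ = Σ_j min(f1_j, f2_j) ∈ [0, 1].

Everything is also available through a simulation study API that generates
detection datasets with known truth (von Mises activity peaks, injected
uniform or night-skewed false positives, a random verified subset) and
measures how much verification effort the correction needs.

## Worked example

```python
import numpy as np
from dielcorrect import (
    ScenarioConfig, preset_shape, simulate_dataset,
    DetectionDataset, MixtureModelSpec, SamplerSettings,
    fit, posterior_activity, overlap_delta, histogram_from_times,
)

# a species with a midday activity peak, 30% night-skewed false positives,
# 20% of records human-verified
config = ScenarioConfig(
    n_detections=4000, fp_rate=0.30, verification_fraction=0.20,
    true_shape=preset_shape("skewed_true"), fp_structure="skewed", seed=42,
)
sim = simulate_dataset(config)

fitted = fit(
    DetectionDataset.from_simulated(sim),
    MixtureModelSpec(error_structure="skewed"),
    SamplerSettings(seed=1),
)
corrected, lower, upper = posterior_activity(fitted)

truth = histogram_from_times(sim.times[sim.is_true], config.grid)
raw = histogram_from_times(sim.times, config.grid)
print(f"theta posterior mean: {fitted.theta_mean:.3f}")
print(f"overlap with truth, uncorrected: {overlap_delta(raw, truth):.3f}")
print(f"overlap with truth, corrected:   {overlap_delta(corrected, truth):.3f}")
```

Output:

```
theta posterior mean: 0.700
overlap with truth, uncorrected: 0.708
overlap with truth, corrected:   0.981
```

The raw histogram shares only 71% of its mass with the true pattern — the
night-clustered false positives manufacture a nocturnal peak — while the
corrected estimate recovers 98% overlap and θ matches the generating
true-positive rate of 0.70.

The same workflow runs from the shell on real detection tables
(CSV with `timestamp,verified,label` columns):

```bash
dielcorrect simulate --n 4000 --fp-rate 0.3 --verification 0.2 \
    --shape skewed_true --fp-structure skewed --seed 42 --out det.csv
dielcorrect fit det.csv --model skewed --seed 1 --out fit.json
dielcorrect sweep --replicates 100 --seed 7 --out sweep.csv --min-out minima.csv
```

`fit` writes a JSON summary (θ posterior mean and 95% interval, convergence
diagnostics) plus a per-bin histogram CSV with 95% credible intervals.

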