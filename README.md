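# resphs

Harmony-search hyperparameter optimization for a 1D CNN that classifies
human respiration patterns, bundled with a synthetic respiration-signal
simulator so the whole system can be built, exercised and validated without
access to radar recordings.

## The problem

Non-contact radar sensing produces one-dimensional chest-motion traces whose
shape distinguishes five clinically meaningful breathing patterns: **eupnea**
(normal, 15–20 breaths/min), **bradypnea** (slow, ≤ 12/min, shallower and
longer cycles), **tachypnea** (rapid shallow, ≥ 20/min), **apnea** (airflow
reduced by more than 90 %), and **movement** (large irregular baseline
drift).  A 1D convolutional network classifies fixed-length 10 s signal
"pieces" into these classes, but its accuracy depends strongly on
architecture hyperparameters: per-layer kernel size (KS) and kernel count
(KC), and the neuron counts of the two dense layers (DLNC).  With kernel
sizes 3–81 (odd), kernel counts 16–1024, dense widths 256–4096 and three
convolutional layers, the search space holds

```
|KS|^cld · |KC|^cld · |DLNC|^2 = 40³ · 1009³ · 3841² ≈ 9.69934 × 10²⁰
```

candidate architectures — far beyond any grid search.

## The method

Harmony Search (HS) is a music-inspired stochastic metaheuristic.  A
**harmony memory** (HM) of HMS candidate architectures, each scored by its
validation recognition rate R (percent correct), is refined one proposal per
iteration:

* with probability **HMCR** recall a random memory member; then with
  probability **PAR** pitch-adjust *every* coordinate by a random signed
  step of magnitude ≤ **MPAP** (parity-preserving on the odd kernel-size
  axis, clipped to bounds);
* otherwise draw a fresh uniform candidate.

A proposal strictly better than the worst memory entry replaces it, keeping
the memory sorted by R descending.  The run stops at the iteration budget or
once the best entry has gone *k* consecutive iterations without improving.
Recommended HS parameter grids: HMCR ∈ {0.50…0.70}, PAR ∈ {0.60…0.80} in
0.05 steps, MPAP ∈ [10, 18], HMS = 1000, budget = 10 000, k = 200.

The CNN objective builds, trains (minibatch SGD, softmax cross-entropy) and
validates the architecture encoded by each candidate; the engine itself is
objective-agnostic and ships with a cheap planted-optimum surrogate for
verification.

## Worked example

```python
import numpy as np
from resphs import (HyperparameterSpace, HSParams, TrainingConfig, derive_rngs,
                    generate_dataset, split_dataset, make_objective, run_hs)

rng_sim, rng_split, rng_search, rng_train = derive_rngs(1)
ds = generate_dataset(3, 12, fs=10.0, duration=10.0, rng=rng_sim, noise=0.15)
split_dataset(ds, 150, 0.2, rng_split)          # 120 train / 30 val / 30 test

space = HyperparameterSpace(cld=2, ks_min=3, ks_max=15, kc_min=1, kc_max=12,
                            dlnc_min=2, dlnc_max=32)
objective = make_objective(ds, TrainingConfig(epochs=10, batch_size=30,
                                              learning_rate=0.1), rng_train)
params = HSParams(hmcr=0.6, par=0.7, mpap=10, hms=10, max_iterations=20, k=200)
best, trace = run_hs(objective, space, params, rng_search)
print(f"best {best.r:.1f}% after {len(trace.records)} iterations, "
      f"{trace.n_evaluations} trainings: {best.hp.as_tuple()}")
```

Output (seed 1):

```
best 80.0% after 20 iterations, 25 trainings: (13, 9, 8, 8, 20, 12)
```

The best candidate reaches 80.0 % validation recognition after 25 CNN
trainings (10 memory initializations plus 20 proposals, minus cached
re-proposals); the tuple is `(ks¹, ks², kc¹, kc², dlnc¹, dlnc²)`.  The same
flow is available from a shell via `resphs simulate / optimize / grid /
evaluate` (see `resphs --help`), which also writes the best-update
trajectory, per-iteration trace and archived config beside the results.

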