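# aad — auditory attention decoding from EEG microstate & recurrence dynamics

In a cocktail-party setting a listener attends one of two competing
speakers. `aad` decodes *which one* from multichannel EEG alone — no access
to the speech signals — by exploiting the fact that attention modulates the
brain's fast topographic dynamics:

1. **Microstate analysis.** The EEG is reduced to its global field power
   GFP(t) = √(Σᵢ(xᵢ(t) − x̄(t))²/N); topographies at GFP peaks are clustered
   (polarity-invariant modified k-means, AAHC, PCA or ICA) into K prototype
   maps, every sample is backfitted to its best map, and each state is
   summarized by mean GFP, occurrence (1/s), duration (ms) and coverage.
   Fit quality is the global explained variance
   GEV = Σₜ GFP(t)²·corr²(x(t), map) / Σₜ GFP(t)².
2. **Recurrence quantification.** Each scalar dynamics series (the GFP
   sequence, or per-state parameter series over sub-windows) is thresholded
   into a recurrence plot R_ij = Θ(ε − ‖xᵢ − xⱼ‖_∞) and quantified by eight
   statistics: RR, DET, L_MEAN, L_MAX, ENTR, TT, V_MAX, RPDE.
3. **Classification.** Per-window feature tables (microstate-only,
   recurrence-only, or the 104-column multivariate combination) are screened
   (Kolmogorov–Smirnov, then Mann–Whitney U) and fed to five classifiers:
   KNN, SVM, LSTM, Bi-LSTM, and **GCQL** — a Q-learning agent whose
   action-value function is a GRU + 1-D-convolution network, trained with
   experience replay on one-step window episodes (reward ±1), evaluated by
   ACC / TPR / TNR over trial-level 70/30 splits and across window lengths
   from 0.02 s upward.

A seeded synthetic-EEG generator plants exactly this structure (orthonormal
topographies switching every ~60–120 ms, class-dependent switching rates,
snr 10), so the whole pipeline is testable without any data download.
See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
from aad.synthetic import SyntheticSpec, simulate_eeg
from aad.microstate import prototypes_from_recording
from aad.io_preprocess import segment_windows
from aad.features import build_features, screen_features
from aad.classify import ClassifierSpec, GCQLConfig, split_trials, train, evaluate

spec = SyntheticSpec(n_trials_per_class=10, trial_length_s=10.0, seed=1)
rec, truth = simulate_eeg(spec)                     # 64-ch, 256 Hz, 20 trials

protos = prototypes_from_recording(rec, K=4, seed=0)
print(f"GEV(K=4) = {protos.gev_total:.3f}")

windows = segment_windows(rec, length_s=1.0)        # 200 one-second windows
fm = build_features(windows, protos, mode="MULTIVARIATE")
print(fm.df.shape)

sig = screen_features(fm, alpha=0.05)
print(f"{len(sig.significant_features)} of {fm.df.shape[1]} features significant")

tr, te = split_trials(fm, 0.7, seed=0)
model = train(ClassifierSpec("GCQL", seed=0), tr,
              gcql_config=GCQLConfig(epochs=8, seed=0))
rep = evaluate(model, te)
print(f"ACC {rep.acc:.3f}  TPR {rep.tpr:.3f}  TNR {rep.tnr:.3f}")
```

Output:

```
GEV(K=4) = 0.995
(200, 104)
46 of 104 features significant
ACC 1.000  TPR 1.000  TNR 1.000
```

GEV ≈ 0.995 means the four fitted prototype maps explain essentially all
GFP-weighted topographic variance (the generator planted four). 46 of the
104 multivariate recurrence-of-microstate features separate the two
attention classes at α = 0.05 — the class difference is a switching-rate
difference (100 ms vs 60 ms mean state duration), invisible to static
topography but prominent in the dynamics features. The GCQL agent then
decodes attention perfectly on the held-out trials from single 1-s windows
(98–100 % across seeds; `scripts/acceptance.py` reports 98.3 % at seed 1);
accuracy *decreases* for longer windows (see `aad sweep`), because fewer,
longer windows mean fewer decisions and no extra dynamic contrast.

The same flow is scriptable:

```bash
aad simulate --seed 1 --out run/
aad microstate --in run/recording.npz --k 4 --out run/ms/
aad features --in run/recording.npz --prototypes run/ms/prototypes.npz \
    --mode multivariate --out run/features.csv
aad screen --in run/features.csv
aad train --features run/features.csv --model gcql --seed 0 --out run/model/
aad run --seed 1 --out run/full   # the whole pipeline + manifest in one go
```

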