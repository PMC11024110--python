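# Methods

This package decodes auditory attention — which of two competing speakers a
listener attends — from multichannel EEG alone, without access to the speech
stimuli. The pipeline has four scientific stages: preprocessing, microstate
analysis, recurrence quantification, and classification. This note records
the models, the defaults and why, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Preprocessing

Recordings are resampled to 256 Hz (polyphase, anti-aliased), band-pass
filtered 0.5–70 Hz, and re-referenced to the average of two reference
electrodes (TP7/TP8 by convention for the BioSemi 64-channel montage).

The band-pass is a zero-phase windowed-sinc FIR filter. The order is set
automatically from the transition bandwidth (25 % of each band edge, floored
at 2 Hz and capped at the edge frequency), and additionally capped at a third
of the signal length so the filter never outgrows the data. Channel means
are removed before filtering, so DC is rejected exactly. Artifact handling
is limited to an optional amplitude-threshold window rejection (off by
default): automated artifact correction such as ICA is out of scope, and a
deterministic default keeps runs bit-reproducible.

Windows tile each trial independently (half-open sample intervals, 0-based);
trailing partial windows are dropped and a window never spans a trial
boundary, so the attended-speaker label of a window is always well defined.

## Microstate analysis

The global field power is the spatial standard deviation across the `N`
electrodes at each sample,

    GFP(t) = sqrt( Σᵢ (xᵢ(t) − x̄(t))² / N ).

Topographies at local GFP maxima (minimum peak distance 10 ms by default)
are clustered into K prototype maps. Peak maps are mean-centered across
channels and unit-normalized before clustering. Four fitting methods are
provided:

* **modified k-means** (the default): polarity-invariant — samples are
  assigned by squared spatial correlation and each prototype is updated to
  the dominant eigenvector of its members; best of `n_init` (default 10)
  restarts by GEV;
* **AAHC**: atomize-and-agglomerate — the cluster contributing least
  GFP²-weighted squared correlation is dissolved and its members reassigned;
* **PCA / ICA**: component loadings (principal axes, or FastICA mixing
  columns) over the peak-map ensemble, unit-normalized. These are not
  clusterings in the strict sense; they are included as alternative map
  decompositions.

Backfitting labels every sample with the prototype of highest absolute
spatial (Pearson) correlation; the winning sign is kept as a separate
polarity sequence, since spontaneous-EEG microstates are conventionally
polarity-invariant. Ties break to the lowest state index; zero-variance
samples inherit the previous label. Fit quality is the global explained
variance

    GEV = Σₜ GFP(t)² · corr²(x(t), map_label(t)) / Σₜ GFP(t)²,

which is 1 when every sample is a scaled copy of its assigned map and 0 for
orthogonal assignments. A temporal minimum-duration smoothing of the label
sequence is available but off by default.

Per analysis window and state, four parameters are computed: mean GFP (µV),
occurrence (maximal runs per second), duration (mean run length, ms) and
coverage (fraction of samples). Coverages sum to 1 by construction, and
coverage = occurrence × duration / 1000 exactly when no run touches a window
edge.

The number of states defaults to 4 (the canonical resting-state inventory).
A model-order scan fits K = 2…10, keeping the best GEV of 10 seeded reruns
per cell, and `gev_elbow` selects K as the point of greatest drop in
marginal GEV gain: with K* planted orthogonal topographies each additional
prototype up to K* explains a comparable share of variance, and the gain
collapses beyond K*, so the drop peaks exactly at K*. Clustering is
per-recording by default; nothing precludes pooling peak maps across
recordings before fitting.

## Recurrence quantification

A scalar series (the GFP sequence of a window, or the sub-window series of
a microstate parameter) is delay-embedded with dimension `m` and delay `τ`
(both default 1 — the parameter series are short and already state-like),
and thresholded with the Chebyshev norm:

    R_ij = Θ(ε − ‖x_i − x_j‖_∞),  Θ(0) = 1.

Eight statistics are computed: RR, DET, L_MEAN, L_MAX, ENTR, TT, V_MAX and
RPDE (definitions in `aad.rqa`). Conventions, each configurable:

* RR is normalized by N² over the **full** matrix, so the line of identity
  (LOI) is included.
* Diagonal-line statistics (DET, L_MEAN, L_MAX, ENTR) **exclude** the LOI;
  the `theiler` parameter widens the excluded band (default 0 = LOI only).
  Without this exclusion DET would be trivially inflated by the LOI.
* Vertical-line statistics (TT, V_MAX) use the full matrix, the standard
  laminarity convention.
* `l_min = v_min = 2`; line-length entropies are over lines ≥ `l_min`.
* RPDE is the normalized type-II recurrence-time entropy H/ln(T_max) ∈ [0,1]
  (consecutive recurrences collapsed to run starts before differencing);
  degenerate cases (no qualifying lines, single return time, T_max ≤ 1)
  return 0.

The default threshold rule is TARGET_RR 0.1: the smallest ε achieving
RR ≥ 0.1, computed exactly from the sorted pairwise-distance spectrum. This
makes recurrence structure comparable across windows of different amplitude.
One consequence worth stating plainly: under TARGET_RR the RR column itself
is pinned near the target (up to one matrix cell) and is therefore nearly
constant across windows — the discriminative signal flows through the
line-structure statistics (DET, TT, RPDE, …) instead. A fixed-ε or
STD_FRACTION strategy restores a varying RR and is available as a switch.

## Feature tables and screening

Three modes per window: `MS_ONLY` (4 parameters × K states), `RQA_ONLY`
(8 statistics of the window's GFP series), and `MULTIVARIATE` — the 8
statistics applied to the raw GFP(t) series plus the per-state
occurrence/duration/coverage series recomputed over consecutive 0.25 s
sub-windows (with K = 4: 8 × (1 + 3×4) = 104 columns). Sub-window
recomputation is the natural way to turn window-level summaries into short
series; the sub-window length is the main resolution/length trade-off and
shrinks automatically (to a quarter window) for short windows.

Screening is per feature: a Kolmogorov–Smirnov normality check (EEG features
are generally non-normal, which motivates the rank test) followed by a
two-sided Mann–Whitney U between the two attention classes; significance at
α = 0.05 on raw p-values, with optional Benjamini–Hochberg correction.
Constant features are flagged degenerate with p = 1.

## Classifiers

* **KNN**: 1 nearest neighbor, Euclidean metric, standardized features.
* **SVM**: RBF kernel, box constraint 1, kernel-scale multiplier 1.1 on the
  variance-scaled gamma.
* **LSTM / Bi-LSTM**: 5 / 3 stacked (bidirectional) LSTM layers of 32 units,
  max-pool over time, dropout 0.2, a single dense softmax head; Adam,
  batch 512, 100 epochs by default. Consecutive windows within a trial can
  be grouped into sequences (`seq_len`, default 1).
* **GCQL**: a Q-learning agent whose action-value function is a GRU (64
  units) over the feature sequence, a 1-D convolution (32 filters, kernel 3)
  applied along the GRU hidden-state axis — well defined at sequence
  length 1 — a 32-unit dense layer, and 2 action values. Each window is a
  one-step episode: actions are the two speaker predictions, reward +1/−1
  for correct/incorrect, ε-greedy exploration decaying linearly 1.0 → 0.05,
  experience replay of 10 000 transitions, squared-TD-error minibatches of
  512 under Adam. Because episodes are single-step the TD target reduces to
  the immediate reward for any discount (the terminal bootstrap is zero);
  the discount defaults to 0 to make that explicit. This degenerate-MDP
  reading is one admissible formalization of per-window decisions, not a
  claim that nothing else is possible.

The recurrent networks and the Q-network run on a small in-package
reverse-mode automatic-differentiation engine over numpy arrays (`aad.nn`);
its gradients are verified against central finite differences in the test
suite. Everything is seeded: retraining with the same seed reproduces
parameters bit-for-bit.

Evaluation uses trial-level stratified splits (default 70/30, e.g. 34 of 48
trials in training), so windows of one trial never straddle the split, and
reports ACC, TPR and TNR with "attend speaker 1" as the positive class.
A window-length sweep repeats the whole pipeline per length; below 8 samples
per window the multivariate mode falls back to the GFP-series statistics
alone, since per-state sub-series cannot be resolved.

## Synthetic benchmark

The generator plants the structure the pipeline assumes: K = 4 orthonormal
zero-mean topographies (QR of a seeded Gaussian), a semi-Markov state
sequence (uniform next state ≠ current; truncated-normal run durations,
sd = 25 % of the mean, minimum 2 samples), a half-sine amplitude envelope
per run so GFP peaks fall mid-state, and white sensor noise with
clean-RMS/noise-sd = 10. The class signal lives purely in the dynamics:
attending speaker 1 means 100 ms mean state duration, speaker 2 means
60 ms — shared topographies, different switching rates — mirroring the
premise that attention modulates microstate dynamics rather than maps, and
making short windows the informative regime. Defaults: 256 Hz, 64 channels,
20 trials per class. Trial length defaults to 10 s, a desk-scale choice
that preserves the windows-per-trial structure of ~50 s recordings while
keeping full-pipeline runs short; tests and the acceptance script use
3–10 trials per class for the same reason.

What passing tests show: the implementation recovers planted labels,
durations and coverages, selects the planted K, and decodes the planted
dynamics difference far above chance. What they do not show: performance on
real EEG, which adds 1/f background, artifacts, volume conduction,
non-orthogonal and drifting topographies, and much weaker class effects.
The generator is a correctness instrument, not a realism claim.

## Numerical choices and degenerate inputs

* Θ(0) = 1 throughout; ε from TARGET_RR is floored at the smallest positive
  float so constant series remain analyzable (RR = 1, RPDE = 0).
* GFP peaks use strict local maxima; endpoints are never peaks.
* Modified k-means reseeds empty clusters from a random peak map; the best
  restart is chosen by GEV, weighted by the raw (pre-normalization) peak
  GFPs.
* All-zero windows make GEV undefined and raise, rather than returning 0.
* Confusion-matrix rates with an absent class are reported as NaN with a
  warning, never silently zeroed.
* Every random draw flows from an explicit seed; pipeline stages derive
  per-stage seeds from the root seed by hashing, so stages are independently
  reproducible.

## Known limitations

* PCA/ICA "prototypes" are linear-component surrogates for cluster centers;
  their GEV is typically below k-means on planted data.
* The GCQL agent with discount 0 is equivalent in its fixed points to
  reward regression; its reinforcement-learning machinery (replay,
  exploration) affects optimization dynamics, not the optimum.
* TARGET_RR pins the RR feature (see above).
* EDF/BDF/FIF reading is delegated to mne; BDF writing is not provided
  (no writer dependency), so round-trip tests use FIF and the internal NPZ
  bundle.
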