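# Methods

`somnoseq` implements an automatic five-stage sleep classifier for
30-second polysomnography (PSG) epochs, together with the training
protocol, evaluation statistics and rater-agreement analyses needed to
exercise it end to end.  Because overnight pediatric PSG with manual
AASM scoring is not freely shareable, the package also ships a
synthetic cohort generator that stands in for such data in every test
and example.  This note records the models, the defaults and why they
were chosen, the numerical choices, and the limits of what the
synthetic experiments demonstrate.

## 1. Staging model

The classifier maps a sequence of `T` consecutive 30-s epochs of
3-channel signal (frontal EEG F4-M1, EOG E1-M2, chin EMG Chin1-Chin2;
100 Hz working rate, so 3000 samples per epoch per channel) to `T`
stage posteriors over {W, N1, N2, N3, R} in one pass, so the recurrent
part can exploit inter-epoch context (sleep-stage sequences are highly
autocorrelated; a single epoch is often ambiguous).

Per epoch, a time-distributed convolutional encoder summarizes the raw
signal:

    [Conv1d - BatchNorm - ReLU] x 2 -> MaxPool
    [Conv1d - BatchNorm - ReLU] x 2 -> MaxPool
    [Conv1d - BatchNorm - ReLU] x 2 -> GlobalAveragePool

The resulting per-epoch feature vectors pass through Gaussian dropout
(train-time only), a bidirectional LSTM that emits one output per
epoch, and a time-distributed dense softmax layer.  The LSTM cell uses
tanh for the cell activation and the hard sigmoid
(`clip(0.2 z + 0.5, 0, 1)`) for the three gates.  The predicted stage
of an epoch is the argmax of its posterior; exact ties (measure-zero
in practice, but tests need determinism) break toward the lowest
ordinal stage in the order W < N1 < N2 < N3 < R.

**Default widths.** The architecture's topology is the contract; the
exact layer widths are tunable.  Defaults: filters (16, 16, 32, 32,
64, 64), kernels (7, 7, 5, 5, 3, 3), all strides 1, pools (4, 4) with
stride 4, 64 LSTM units per direction, dropout rate 0.3, sequence
length 100 epochs — 95,605 trainable parameters.  A `TINY_PRESET`
(filters 8–32, 16 LSTM units, sequence length 20, stride 2 on the
first convolution) runs the whole protocol in minutes on one CPU and
is used by the tests, the demo subcommand, and the examples.  The
Gaussian-dropout rate is a single layer at 0.3 (configurable); one
dropout site before the LSTM is the simplest reading of the
architecture.

**Implementation.** The network, its backward passes and the Adam
optimizer are implemented directly in NumPy (`somnoseq.nn`): 'same'
padded strided 1-D convolution via im2col, batch normalization with
running statistics, non-overlapping max pooling, BPTT through the
bidirectional LSTM.  Every backward pass is validated against central
finite differences through the full stack in `tests/test_nn.py`
(float64, relative error < 1e-4).  Initialization is Glorot-uniform
from a seeded generator; the LSTM forget-gate bias starts at 1.
Training runs in float32; the batch statistics of BatchNorm are used in
training mode and the running averages at inference, which makes
inference posteriors independent of batch partitioning (asserted to
1e-5).

## 2. Training protocol

* **Sequences.** Recordings are windowed into sequences of 100 epochs
  (20 for the tiny preset).  Training windows overlap 75%, which
  multiplies the number of training sequences by four; validation and
  test windows do not overlap.  A recording shorter than one window is
  padded by repeating its final epoch, with a mask excluding padded
  positions from loss and metrics.  The same pad-and-discard rule
  covers the tail window at inference, so every epoch is scored
  exactly once.
* **Cross-validation.** Recordings are shuffled (seeded) and split
  into k = 10 near-equal test folds (sizes differ by at most one); the
  non-test recordings of each fold are split 90/10 into train and
  validation.  All splits are at the recording level — epochs of one
  subject never appear on both sides of a split; a leakage guard
  asserts pairwise disjointness at run time.  Test predictions are
  pooled over folds into a single confusion matrix.
* **Optimization.** Categorical cross-entropy over non-padded
  positions, Adam, and cosine annealing with warm restarts between
  lr_max = 1e-3 and lr_min = 1e-5.  A cycle of nominal length `T_i`
  spans `T_i + 1` training epochs with `T_cur` in `[0, T_i]`
  inclusive, so both endpoints of the rate range are attained exactly
  (`lr_max` at the cycle start, `lr_min` at the cycle end); after each
  cycle `T_i` is multiplied by `T_mult`.  Defaults `T_0 = 10`,
  `T_mult = 2` — the standard choice for this schedule, which the
  protocol leaves open.  The learning rate is constant within one
  training epoch.
* **Early stopping.** Patience 20 on validation loss (any improvement
  resets the counter — the simplest faithful patience rule), capped at
  200 training epochs; the weights of the best validation epoch are
  restored.  Divergence (NaN loss) raises with the history attached.
* **Learning-rate finder.** An advisory exponential sweep
  (`find_lr_range`) records a smoothed loss curve and suggests the
  steepest-descent point as lr_max with 1/100 of it as lr_min.  It
  never overrides the protocol defaults.  Its test uses a quadratic
  toy problem whose stable step-size region (lr < 2/a) is known in
  closed form.
* **Batch size** defaults to 8 sequences (unconstrained by the
  protocol; fits comfortably in memory at desk scale).  No class
  weighting or resampling is applied, so the scarce-N1 difficulty of
  real scoring is reproduced rather than patched over.

## 3. Evaluation statistics

Confusion matrices are reference-by-predicted (rows = reference).
From them: accuracy (trace/total); Cohen's kappa
`(p_o − p_e)/(1 − p_e)` with `p_e` from the marginals; per-stage
one-vs-rest sensitivity, specificity, PPV, NPV; and sleep-vs-wake
binary metrics obtained by collapsing {N1, N2, N3, R} against W — by
construction sleep sensitivity equals W-stage specificity and vice
versa, and the tests assert this identity exactly.  Kappa values carry
Landis–Koch remarks with upper-inclusive bands ((0.60, 0.80] =
"Substantial", (0.80, 1] = "Almost Perfect").

Any metric with a zero denominator is reported as an explicit
undefined marker (`nan` in memory, `null` in JSON), never silently 0 —
with N1 at ~3% of epochs, zero-denominator cells are a real occurrence
and coercion would distort small-sample summaries.

Stage-collapsed scoring merges N1+N2 (4-stage) or all NREM (3-stage);
merging can only convert errors into matches, so accuracy is
non-decreasing along 5 → 4 → 3 (property-tested).

Rater agreement: pairwise percent agreement and kappa over any set of
scorings; per-stage agreement uses the symmetric-average convention
between human scorings (neither is privileged) and manual-as-reference
against the automatic scoring.  The consensus analysis reports the
fraction of epochs where two scorers agree, the automatic accuracy and
kappa restricted to that subset, and the fraction of epochs where the
automatic scoring matches at least one scorer.  Hypnogram summaries
define TST as 0.5 min per non-W epoch and sleep efficiency against the
full scored span (trimmed recordings carry no lights-off annotation,
so scored span stands in for time in bed).

Groupwise evaluation pools per-recording confusion matrices by
recruitment flag (SDB-symptomatic vs control) and by PSG-quantified
OSA status with the pediatric threshold AHI ≥ 1 (a recording exactly
at 1.0 events/h belongs to the ≥ group).

## 4. Synthetic cohort generator

The generator emulates the study conditions the classifier targets; it
is deliberately simple enough to reason about and hard enough that the
classifier must read the signal, not an artifact.

**Hypnogram dynamics.** A 5-state Markov chain over stages.  Self-
transitions follow the mean bout lengths (geometric bouts),
`p_ii = 1 − 1/m_i`; exits are distributed so that every stage's inflow
balances its outflow under the target composition, found by a one-sided
Sinkhorn-style iteration.  Flow balance with the fixed diagonal makes
the target distribution exactly stationary (verified analytically to
1e-6 against a power-iteration oracle).  The default target is the
whole-dataset stage composition of the reference pediatric cohort
(W 7.1%, N1 3.1%, N2 24.3%, N3 46.1%, R 19.3% — an N3-heavy mix
typical of preadolescent sleep); default mean bouts are (W 4, N1 2,
N2 10, N3 20, R 15) epochs, chosen for plausible-looking hypnograms
since the composition tables constrain no dynamics.  At 100,000
simulated epochs the empirical composition carries a standard error of
~0.7 percentage points on N3 because of bout-level autocorrelation;
recovery tests use the package's deterministic seed-derivation scheme.

**Signals.** Per-band EEG carriers are band-limited noise (4th-order
Butterworth-filtered white noise over delta/theta/alpha/beta),
generated once per recording and mixed per epoch with stage-dependent
gains, so in-band signal is continuous and epoch boundaries switch
only the mixing weights.  Band-limited noise rather than sinusoids
prevents the classifier keying on phase artifacts.  Stage signatures
follow the textbook pattern at clearly separable margins:
alpha-dominant low-voltage W, theta-dominant N1, delta-leaning N2 with
1-s Hann-windowed 13 Hz spindle bursts at 3/min, high-amplitude
delta-dominant N3 (80 µV RMS, delta weight 0.75 — the maximum
stage-band weight, enforced as an invariant), theta-dominant R.  EMG
is broadband noise at a stage-dependent tone with REM atonia enforced
(R strictly minimal, 1.5 µV vs 5–15 µV elsewhere).  EOG carries
attenuated EEG crosstalk, slow drift, and stage-typed deflection
events (slow movements in W/N1, rapid deflections in R).  A 2 µV
broadband floor sits on every channel.  K-complexes, arousals,
artifacts and age-dependent EEG maturation are deliberately absent.

**Scorers.**  Imperfect manual scorings are simulated by relabelling
each epoch independently through a row-stochastic, strictly diagonally
dominant confusion kernel; the default keeps 85% of epochs and
concentrates errors on AASM-adjacent confusions (N1↔N2, N1↔W, N2↔N3).
Expected agreement is the truth-weighted diagonal mass (tested at 3
binomial standard errors).

**Cohorts and seeds.**  Per-recording seeds derive from a master seed
by a splitmix64-style mix (`derive_seed`), so cohorts are reproducible
and extensible — recording k is identical whether the cohort has 8 or
80 members.  Group flags alternate SDB/control and AHI values cycle
through (0.3, 0.8, 1.0, 2.4) events/h to straddle the OSA threshold.
Every generator is a pure function of its inputs and a seed.

**What passing tests do and do not show.**  The synthetic cohort makes
stages separable chiefly through amplitude and spectral composition at
generous margins, so the desk-scale experiments demonstrate that the
architecture, the training loop, the windowing arithmetic, the splits
and the metrics are correct and leak-free — not that the model reaches
human-level accuracy on real PSG.  Real pediatric EEG has artifacts,
inter-subject variability, stage-transition ambiguity and far subtler
N1 signatures; results on the synthetic cohort overstate attainable
real-data performance by construction.

## 5. Preprocessing and I/O

EDF reading goes through `mne` with case-insensitive, alias-tolerant
channel matching ("EOG E1-M2" resolves to E1-M2); signals are handled
in microvolts as read, with no rescaling and no filtering beyond the
anti-alias step — the classifier consumes raw amplitudes.  EDF writing
(needed by the generator) is a minimal self-contained writer: 16-bit
samples, 1-s records, symmetric physical range per channel; the
round-trip error is bounded by the quantization step and tested with
`mne` as the independent reader.  Downsampling 200 → 100 Hz applies a
zero-phase FIR low-pass (129 taps, cutoff at 0.8× the target Nyquist,
forward-backward) before integer decimation, preserving the phase of
stage-defining waveforms; passband tones survive with < 2% power
error.  Unscored recording margins (contiguous prefix/suffix only) are
trimmed so that hypnogram length × 30 s × rate equals signal length
exactly; the 30-s epoch grid is anchored at the scored-signal start
with half-open intervals, and a trailing partial epoch is dropped,
never padded.  Hypnograms travel as one uppercase token per line
(UTF-8, blank-line tolerant, `?`/`UNSCORED` sentinel accepted only by
the margin-aware reader) or as an `epoch_index,stage` CSV.

## 6. Problem sizes in tests and the acceptance script

The test suite trains the tiny preset on 8 synthetic recordings × 240
epochs with 2-fold cross-validation and 12 training epochs per fold —
large enough to cross the first warm-restart boundary and to beat the
~48% majority-class floor decisively (pooled kappa ≈ 0.74 in ~3 min on
one CPU), small enough for routine runs.  `scripts/acceptance.py`
recomputes the generator's composition-recovery quantity from a
100,000-epoch simulation.  These sizes are the package's own choices
for desk-scale verification; all presets scale up by configuration.

## 7. Known limitations

* The per-epoch CNN feature length after pooling must stay ≥ 1;
  configurations that collapse it are rejected with the offending
  layer named.
* `find_lr_range` is advisory and brittle on flat or immediately
  diverging loss curves (it raises with the partial curve attached).
* The NumPy training loop is single-threaded beyond BLAS; full-scale
  presets (sequence length 100, 64-unit LSTM, whole-night cohorts) are
  CPU-feasible but slow — the package's scope is correctness and
  desk-scale demonstration, not throughput.
* The EDF writer targets the generator's needs (uniform rate, whole
  seconds, µV); it is not a general-purpose EDF+ annotation writer.
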