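# somnoseq

Sequence-to-sequence sleep staging for 3-channel polysomnography
(frontal EEG F4-M1, EOG E1-M2, chin EMG Chin1-Chin2), aimed at
overnight recordings scored in 30-second epochs into the five AASM
stages W / N1 / N2 / N3 / R.  The package is for researchers and
engineers who want a fully inspectable, dependency-light reference
implementation of a CNN–biLSTM sleep stager — including its training
protocol and agreement statistics — that can be exercised end to end
without access to restricted clinical PSG data.

## What it implements

* **Model** — a combined convolutional + recurrent network: per 30-s
  epoch, six 1-D convolutions (each with batch normalization and
  ReLU), max pooling after each pair and global average pooling at the
  end, applied time-distributed over a sequence of 100 epochs; then
  Gaussian dropout, a bidirectional LSTM (tanh cell, hard-sigmoid
  gates) and a time-distributed softmax dense layer.  The network maps
  a sequence of epochs to an equally long sequence of stage posteriors
  `p(stage | epoch, context)`; the scored stage is the argmax.  Layers,
  backprop and Adam are implemented in NumPy and verified against
  finite differences.
* **Training protocol** — recording-level 10-fold cross-validation
  with an inner 90/10 train/validation split, sequences of one hundred
  30-s epochs (75% overlap in training only, quadrupling the training
  data), categorical cross-entropy, Adam with cosine warm restarts
  between 1e-3 and 1e-5, early stopping with patience 20, at most 200
  training epochs, and an advisory learning-rate finder.
* **Metrics** — epoch-by-epoch confusion matrices (rows = reference),
  accuracy, Cohen's kappa `κ = (p_o − p_e)/(1 − p_e)` with
  Landis–Koch remarks, stage-wise sensitivity/specificity/PPV/NPV,
  sleep-vs-wake detection, 4-stage (N1+N2 merged) and 3-stage (NREM
  merged) collapsed scoring, hypnogram summaries (TST, sleep
  efficiency), and groupwise evaluation (SDB vs control, AHI ≥ 1 vs
  < 1).
* **Rater agreement** — pairwise intra-/inter-rater tables (percent
  agreement, κ, per-stage agreement with symmetric-average or
  fixed-reference conventions) and consensus-epoch analysis.
* **Synthetic cohorts** — a Markov-chain hypnogram simulator whose
  stationary stage mix is calibrated to a reference pediatric
  composition (W 7.1%, N1 3.1%, N2 24.3%, N3 46.1%, R 19.3%),
  stage-signature signal synthesis (band-limited EEG noise mixtures,
  N2 spindle bursts, REM atonia, slow/rapid eye movements), imperfect
  simulated scorers, EDF + hypnogram text output.

## Worked example

Desk-scale cross-validation on a synthetic cohort
(`examples/03_train_crossvalidate.py`; a few minutes on one CPU):

```python
from somnoseq.nn.model import TINY_PRESET
from somnoseq.pipeline import prepare_cohort
from somnoseq.simulate import generate_cohort
from somnoseq.training import TrainingConfig, run_cross_validation

cohort = generate_cohort(n_recordings=6, epochs_per_recording=120, seed=0)
triples = prepare_cohort(cohort)          # 200 Hz -> 100 Hz -> 30-s epochs
tcfg = TrainingConfig(seq_len=TINY_PRESET.seq_len, max_epochs=6,
                      patience=20, batch_size=8, seed=0)
result = run_cross_validation(triples, TINY_PRESET, tcfg, k=2)
```

prints

```
majority-class rate : 0.601
pooled accuracy     : 0.786
pooled Cohen's kappa: 0.584 (Moderate)
```

Every recording is scored exactly once, by the fold in which it is a
test recording.  The pooled accuracy is epoch-by-epoch agreement with
the reference hypnograms across the whole cohort; at 0.786 it clearly
beats the 0.601 majority-class floor of this N3-heavy label mix, and
κ = 0.584 is the chance-corrected agreement ("Moderate" on the
Landis–Koch scale).  Longer training and larger cohorts push both
higher — the acceptance-scale run (8 recordings × 240 epochs, 12
training epochs per fold) reaches pooled accuracy ≈ 0.83, κ ≈ 0.74.

The other examples each demonstrate one capability: cohort generation
and EDF round-trip (`01`), stage signal signatures (`02`), rater
agreement and consensus analysis (`04`), and the warm-restart schedule
plus learning-rate finder (`05`).

A thin CLI wraps the same pipeline:

```sh
somnoseq simulate --n-recordings 8 --epochs 240 --seed 0 --out-dir data/
somnoseq train-cv --data-dir data/ --tiny --folds 2 --seed 0 --out-dir run/
somnoseq predict  --model run/ckpt --edf data/synt000.edf --out-hypnogram pred.txt
somnoseq evaluate --ref data/synt000.hypnogram.txt --pred pred.txt --out metrics.json
somnoseq demo     --seed 7 --out-dir demo/     # tiny end-to-end loop
```

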