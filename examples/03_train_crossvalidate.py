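"""Train and cross-validate the stager on a desk-scale synthetic cohort.

Runs the full protocol in miniature: generate a labelled cohort at the
native 200 Hz, downsample to the 100 Hz working rate, cut into 30-s
epochs, window into sequences (75% overlap for training only), and run
2-fold cross-validation of the tiny CNN-biLSTM preset with the cosine
warm-restart schedule and early stopping.  Prints pooled epoch-by-epoch
accuracy and Cohen's kappa against the reference hypnograms — compare
them with the ~48.6% majority-class floor of this N3-heavy label mix.

Takes a few minutes on one CPU.  Increase the cohort size, sequence
length, and model width toward the full-scale presets for real use.
"""

import numpy as np

from somnoseq.nn.model import TINY_PRESET
from somnoseq.pipeline import prepare_cohort
from somnoseq.simulate import generate_cohort
from somnoseq.training import TrainingConfig, run_cross_validation

cohort = generate_cohort(n_recordings=6, epochs_per_recording=120, seed=0)
triples = prepare_cohort(cohort)
tcfg = TrainingConfig(seq_len=TINY_PRESET.seq_len, max_epochs=6,
                      patience=20, batch_size=8, seed=0)
result = run_cross_validation(triples, TINY_PRESET, tcfg, k=2)

counts = sum(h.counts() for _, h, _ in triples)
print(f"majority-class rate : {counts.max()/counts.sum():.3f}")
print(f"pooled accuracy     : {result.pooled_report.accuracy:.3f}")
print(f"pooled Cohen's kappa: {result.pooled_report.kappa:.3f} "
      f"({result.pooled_report.kappa_remark})")
print("\nper-recording test performance:")
for rid, d in result.per_recording.items():
    print(f"  {rid}: acc {d['accuracy']:.3f}  kappa {d['kappa']:.3f}")
print("\nfold 0 learning rates (cosine warm restarts):")
print("  " + " ".join(f"{v:.5f}" for v in result.histories[0].learning_rate))
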