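"""The cosine warm-restart learning-rate schedule and the advisory
range finder.

Prints the per-training-epoch learning rate over the first two restart
cycles (1e-3 at each cycle start, annealed to 1e-5 at cycle end, cycle
length doubling after each restart), then runs the exponential-sweep
range finder on a toy quadratic problem where the stable step-size
region is known in closed form.
"""

from somnoseq.training import TrainingConfig, find_lr_range, lr_at

cfg = TrainingConfig(seq_len=100, restart_period_T0=10, restart_mult_Tmult=2)
print("epoch:  lr")
for t in range(0, 33):
    marker = "  <- restart" if t in (0, 11) else ""
    print(f"{t:5d}: {lr_at(t, cfg):.6f}{marker}")

curvature = 100.0


def probe(lr, inner=5):
    w = 1.0
    for _ in range(inner):
        w -= lr * curvature * w
    return 0.5 * curvature * w * w


lr_min, lr_max, curve = find_lr_range(probe, n_steps=200,
                                      lr_lo=1e-6, lr_hi=1.0)
print(f"\nrange finder on 0.5*{curvature:g}*w^2 "
      f"(stable for lr < {2/curvature:g}):")
print(f"  suggested lr_max {lr_max:.4g}, lr_min {lr_min:.4g}")
print("  (advisory only; the training protocol keeps 1e-3 / 1e-5)")
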