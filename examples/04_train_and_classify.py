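"""Train the 4-3-1 network and classify held-out sessions.

Reproduces the evaluation protocol in miniature: 3 training sessions,
5 test sessions (the full protocol uses 10/20 — see
scripts/acceptance.py).  Reports per-session recognition rates under the
strict policy (UNDECIDED counts as wrong) and the nearest policy
(UNDECIDED resolved to the closer of 0/1).
"""

from fdbdrill import PipelineConfig, run_end_to_end

report = run_end_to_end(PipelineConfig(seed=11, n_train=3, n_test=5))

t = report["train"]
print(f"training: {t['n_samples']} frames, {t['epochs']} epochs, "
      f"final MSE {t['final_mse']:.2e} ({t['stop_reason']})")
for s in report["sessions"]:
    print(f"session {s['session']}: strict {s['strict']:.3f}  "
          f"nearest {s['nearest']:.3f}  undecided {s['undecided_fraction']:.3f}")
summary = report["summary"]["nearest"]
print(f"nearest-policy recognition: mean {summary['mean']:.3f} "
      f"(min {summary['min']:.3f}, max {summary['max']:.3f})")

# Rates near 1.0 mean nearly every frame's hardened network output agrees
# with the ground-truth layer label on sessions never seen in training.
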