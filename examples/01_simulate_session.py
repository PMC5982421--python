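"""Synthesize a drilling session and look at its ground truth.

A session emulates a drill bit passing through a vertebral pedicle:
outer cortical bone, a transition region, cancellous bone, a second
transition region, and inner cortical bone.  The simulator returns the
audio-rate acoustic-emission signal plus frame-level labels
(0 = cortical/cancellous, 1 = transition).
"""

import numpy as np

from fdbdrill import SessionConfig, synthesize_session

config = SessionConfig(seed=42)
record, truth = synthesize_session(config)

print(f"signal: {record.samples.size} samples at {record.sample_rate:.0f} Hz "
      f"({record.duration:.2f} s)")
print(f"frames labeled: {truth.times.size}")
print(f"true layer boundaries (s): {np.round(truth.boundaries, 2).tolist()}")
frac = truth.labels.mean()
print(f"fraction of frames in the transition region: {frac:.3f}")

# The boundaries are where drilling must react: the 2nd entry into a
# transition region (here ~10.2 s) is the surgical stop signal before the
# inner cortical wall.
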