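"""Find layer boundaries from synchronized coefficient jumps.

At a true layer change the fitted coefficients step together.  The
detector smooths each coefficient series, scores the jump of the local
median at every frame in robust z-units, and declares a boundary where at
least 3 of the 4 coefficients jump simultaneously.
"""

import numpy as np

from fdbdrill import SessionConfig, detect_boundaries, synthesize_session
from fdbdrill.pipeline import FAST_FIT_OPTIONS, extract_coefficients

record, truth = synthesize_session(SessionConfig(seed=21))
times, coeffs, _ = extract_coefficients(record, stride=10, options=FAST_FIT_OPTIONS)

found = detect_boundaries(times, coeffs)
print(f"true boundaries (s):     {np.round(truth.boundaries, 3).tolist()}")
print(f"detected boundaries (s): {np.round(found, 3).tolist()}")
for b in truth.boundaries:
    err = np.min(np.abs(found - b)) if found.size else np.inf
    print(f"  boundary at {b:6.2f} s located within {err:.3f} s")

# Errors of a few tens of milliseconds: the detector localizes each layer
# change to a handful of analysis frames, with no false alarms inside the
# homogeneous segments.
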