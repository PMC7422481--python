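"""Fit ridge LSR and epsilon-dragging DLSR on the same Gaussian blobs.

DLSR drags each one-hot regression target outward (true class above +1,
false classes below 0) through a nonnegative slack matrix, enlarging the
margin between classes; the objective trace shows the alternating solver
decreasing monotonically.
"""

import numpy as np

from tdlsr import fit_dlsr, fit_lsr
from tdlsr.synthetic import make_domain_pair

pair = make_domain_pair(
    C=3, d=6, n_source_per_class=60, n_target_per_class=30,
    shift_kind="identical", test_fraction=0.3, seed=42,
)
X, y = pair.source.X, pair.source.labels
X_test, y_test = pair.target_test.X, pair.target_test.labels

lsr = fit_lsr(X, y, lam=0.01)
dlsr, trace = fit_dlsr(X, y, lam=0.01)

print(f"LSR  test accuracy: {np.mean(lsr.predict(X_test) == y_test):.3f}")
print(f"DLSR test accuracy: {np.mean(dlsr.predict(X_test) == y_test):.3f}")
print(f"DLSR objective, first 5 iterations: "
      f"{[round(v, 2) for v in trace.objective_values[:5]]}")
print(f"converged={trace.converged} after {trace.n_iterations} iterations")
# The objective values shrink monotonically: each alternating step
# (closed-form (Z, p) ridge solve, then the slack clamp) is an exact
# block minimizer.  Both classifiers separate three 3-class Gaussian
# clouds well; DLSR's dragged targets matter most near class boundaries.
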