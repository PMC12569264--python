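"""Per-region maximal-activation landscape of an identified system.

For a random stable signature, computes each state region's maximum
possible terminal activation at horizon T_M = 10 scans, starting from
rest under unit input energy, and lays the min-max-normalized values on
the 12 x 12 display grid (unused cells masked). The most reachable
region is the one an energy-limited stimulus can excite the most.
"""

import numpy as np

from causalfp import landscape_grid, reachability_values, to_state_evolution_form
from causalfp.dynamics import CausalSignature

rng = np.random.default_rng(3)
m, n = 16, 4
Q = rng.normal(0.0, 0.3 / np.sqrt(m), (m, m))
np.fill_diagonal(Q, 0.0)
A = rng.normal(0.0, 1.0 / np.sqrt(m), (m, m))
A *= 0.9 / np.max(np.abs(np.linalg.eigvals(np.linalg.solve(np.eye(m) - Q, A))))
sig = CausalSignature(
    Q=Q, A=A, B1=rng.normal(size=(m, n)), B2=rng.normal(size=(m, n)), dt=0.72
)

form = to_state_evolution_form(sig)
print(f"spectral radius of A_hat: {form.spectral_radius:.3f} (stable: {form.is_stable})")
values = reachability_values(form, T_M=10, norm_model="energy")
print(f"reachability range: {values.min():.3f} .. {values.max():.3f}")
print(f"most reachable region: {int(values.argmax())}")

land = landscape_grid(values, horizon=10)
filled = (~land.grid.mask).sum()
print(f"grid: {filled} filled cells, {land.grid.mask.sum()} masked")
print(np.round(land.grid[:2], 2))  # first two grid rows of normalized values
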