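"""Panoramic inversion: current spread and neural health from a matrix.

Draws a 16-electrode ground truth with a 3-electrode dead region (η floor
0.05 on electrodes 10-12), simulates a noisy half-matrix acquisition,
mirrors it to full, and inverts it under the bounds and smoothness
constraints.  Prints the recovered profiles next to the truth.
"""

import numpy as np
from scipy import stats

from speedcap import (
    DeadRegion,
    SolverConfig,
    half_mask,
    mirror_half,
    noisy_amplitude_matrix,
    solve_pecap,
)
from speedcap.synthetic import SyntheticStudySpec, make_profiles

spec = SyntheticStudySpec(
    n_electrodes=16, dead_regions=(DeadRegion(start=10, width=3, floor=0.05),), seed=5
)
truth = make_profiles(spec)
rng = np.random.default_rng(spec.child_seed(2))
half = noisy_amplitude_matrix(truth, half_mask(16), rel_noise=0.02, rng=rng)
full = mirror_half(half)

est = solve_pecap(full, SolverConfig(seed=0))
eta_true = truth.eta / truth.eta.max()

print("el   sigma_true sigma_hat   eta_true  eta_hat")
for e in range(16):
    marker = " <- dead region" if 10 <= e + 1 <= 12 else ""
    print(
        f"{e + 1:2d}   {truth.sigma[e]:9.2f} {est.sigma_hat[e]:9.2f}"
        f"   {eta_true[e]:8.2f} {est.eta_hat_normalized[e]:8.2f}{marker}"
    )

r_eta = stats.pearsonr(est.eta_hat_normalized, eta_true)[0]
r_sigma = stats.pearsonr(est.sigma_hat, truth.sigma)[0]
print(
    f"\nfit RMSE {est.objective_rmse:.4f} (normalized units), converged={est.converged}; "
    f"r(eta)={r_eta:.2f}, r(sigma)={r_sigma:.2f}"
)
print(f"recovered eta minimum at electrode {int(np.argmin(est.eta_hat)) + 1} (truth: 10-12)")
# The dip in the neural-health estimate localizes the simulated dead region;
# its depth is limited by the smoothness cap (|Δη| ≤ 0.5 per electrode), so
# the fitted floor approximates rather than reaches the true 0.05.
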