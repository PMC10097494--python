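"""Repeatability and method-comparison error metrics on a paired study.

Simulates one synthetic participant through both acquisition designs —
a standard full-matrix recording acquired as four 12-sweep blocks and two
independent 50-sweep fast half-matrix recordings — then computes the
normalized-RMSE error family:

* split-half repeatability of the standard method (1/√2-corrected),
* repeatability between the two fast-method repeats,
* the between-method comparison error, and
* the symmetry-assumption error of the raw full matrix.
"""

from speedcap import epsilon_between, epsilon_sym, epsilon_within, mirror_half
from speedcap.synthetic import SyntheticStudySpec, make_profiles, simulate_dataset

spec = SyntheticStudySpec(n_electrodes=22, seed=5)
model = make_profiles(spec)
ds = simulate_dataset(model, spec)

m0 = ds.slowcap["M"]  # full matrix, 48 sweeps
msp1, msp2 = ds.speedcap  # half matrices, 50 sweeps each

triangle = msp1.recorded_mask  # compare methods on the jointly recorded cells

eps_0 = epsilon_within(ds.slowcap["Ma"], ds.slowcap["Mb"],
                       half_sweep_correction=True, cells=triangle)
eps_sp = epsilon_within(msp1, msp2, metric_name="epsilon_Sp")
eps_0sp = epsilon_between(m0, msp1, cells=triangle)
eps_s = epsilon_sym(m0)

print("metric                                value")
print(f"standard split-half (corrected)  ε0  : {eps_0.percent:6.2f}%  ({eps_0.n_cells} cells)")
print(f"fast repeat-to-repeat           εSp  : {eps_sp.percent:6.2f}%  ({eps_sp.n_cells} cells)")
print(f"standard vs fast              ε0,Sp  : {eps_0sp.percent:6.2f}%  ({eps_0sp.n_cells} cells)")
print(f"symmetry assumption            εsym  : {eps_s.percent:6.2f}%  ({eps_s.n_cells} cells)")

full_from_half = mirror_half(msp1)
print(
    f"\nmirrored half matrix is exactly symmetric: "
    f"{bool(full_from_half.is_symmetric())}; ready for inversion"
)
# With a symmetric generative model and recording noise only, all four
# errors sit in the few-percent range and the between-method error is
# comparable to the repeatability errors — the half-matrix shortcut does
# not add error beyond measurement noise.
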