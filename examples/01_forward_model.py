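"""Forward penetration model: concentration and fluorescence depth profiles.

Evaluates the erfc concentration field and the saturating fluorescence
response for the FITC standard-sample parameters, and cross-checks the
closed form against an explicit finite-difference solution of the
diffusion equation.
"""

import numpy as np

from crpen import PenetrationParams, concentration, fd_oracle, fluorescence

params = PenetrationParams(D=0.138, K=2.233, sample="FITC standard sample")

print(f"Sample: {params.sample}  (D = {params.D} um^2/s, K = {params.K})")
print(f"Saturation threshold 1/K = {1 / params.K:.3f}: fluorescence reads 1")
print("wherever the normalized buffer concentration exceeds that value.\n")

t = 300.0  # s after buffer application
print(f"Depth profile at t = {t:g} s:")
print(f"{'z (um)':>8} {'C(t,z)':>8} {'I_f(t,z)':>9}")
for z in [0.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0]:
    c = concentration(params.D, t, z)
    f = fluorescence(params, t, z)
    tag = "  <- saturated" if f == 1.0 else ""
    print(f"{z:8.1f} {c:8.4f} {f:9.4f}{tag}")

# independent check: explicit finite differences on Fick's second law
dz = 0.05
dt = 0.5 * (0.5 * dz**2 / params.D)  # half the explicit stability bound
z_grid, c_fd = fd_oracle(params, dz, dt, t)
err = np.abs(c_fd - concentration(params.D, t, z_grid)).max()
print(f"\nFinite-difference vs closed-form max |error|: {err:.2e}")
print("(the two agree to well under 1e-3: the erfc profile solves the")
print("semi-infinite diffusion problem the simulation discretizes)")
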