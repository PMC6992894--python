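"""End-to-end pipeline on a synthetic noisy stack series.

Generates a 64x64x50-voxel time series (four observation times, 2% read
noise) from known parameters, extracts depth profiles and isointensity
contours, refits (D, K), and verifies the fitted model against every
profile.
"""

from crpen import PenetrationParams, SyntheticSpec, generate_series, run_pipeline

truth = PenetrationParams(D=0.138, K=2.233)
spec = SyntheticSpec(params=truth, nx=64, ny=64, gaussian_sigma=0.02, seed=12)
series, _ = generate_series(spec)
print(f"Simulated {len(series.stacks)} stacks "
      f"({spec.n_planes}x{spec.ny}x{spec.nx} voxels) at t = {spec.times} s")

result = run_pipeline(series)
p = result.report.params
print(f"\nTruth:     D = {truth.D:.4f} um^2/s, K = {truth.K:.4f}")
print(f"Recovered: D = {p.D:.4f} um^2/s, K = {p.K:.4f}")
print(f"Relative errors: {abs(p.D / truth.D - 1):.2%} (D), "
      f"{abs(p.K / truth.K - 1):.2%} (K)")

print("\nContour slope fits (depth = slope * sqrt(t), through the origin):")
for f in result.report.slope_fits:
    print(f"  level {f.level}: slope = {f.slope:.4f} um/sqrt(s), "
          f"R^2 = {f.r_squared:.4f} ({f.n_points} time points)")

print("\nModel-vs-profile determination coefficients:")
for t, r2 in result.report.profile_r_squared:
    print(f"  t = {t:4.0f} s: R^2 = {r2:.4f}")
print("\nHigh R^2 at every time point means the fitted erfc+saturation law")
print("explains essentially all depth structure in the noisy stacks.")
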