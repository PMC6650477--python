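"""Per-slice fiber orientation from the 2D FFT amplitude spectrum.

Plants one bundle at 60° and walks the FFT-ellipse estimator down the
stack: each slice yields an orientation angle θ (minor axis of the
ellipse fitted to the directional spectral amplitude) and a degree of
orientation (the ellipse's axial ratio; 1 = isotropic).
"""

from fiborient import (
    FiberFieldSpec,
    analyze_stack,
    generate_collagen_geometry,
    rasterize_stack,
)

spec = FiberFieldSpec(
    z_extent=32.0,
    bundle_depths=[(16.0, 8.0)],
    mode_centers=[60.0],
    mode_weights=[1.0],
    mode_dispersion=5.0,
    bundle_coherent=False,
    waviness_amplitude=0.0,
    seed=5,
)
geom = generate_collagen_geometry(spec)
stack = rasterize_stack(geom, spec, channel="collagen")
profile = analyze_stack(stack, boundary_z=0)

print("depth(µm)  theta(°)  degree  isotropic")
for i in range(len(profile)):
    theta = f"{profile.theta_deg[i]:7.1f}" if not profile.isotropic[i] else "     --"
    print(f"{profile.depth_um[i]:8.0f} {theta} {profile.degree[i]:8.2f}  {profile.isotropic[i]}")
# Inside the bundle slab (depth ≈ 12–20 µm) the degree rises well above
# the 1.10 resolvability threshold and θ sits within ~2° of the planted
# 60°; fiber-free slices are flagged isotropic or stay below 1.10.
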