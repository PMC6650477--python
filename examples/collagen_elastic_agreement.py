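"""Local directional agreement between collagen bundles and elastic fibers.

At each collagen bundle peak, the elastic-channel orientation at the same
depth is paired with the collagen orientation; axial differences are
binned at 15°. With small planted jitter nearly all pairs land in the
0–15° bin, mirroring the high collagen–elastic co-alignment seen in
dermis.
"""

from fiborient import (
    FiberFieldSpec,
    analyze_stack,
    collagen_elastic_agreement,
    find_orientation_peaks,
    generate_collagen_geometry,
    generate_elastic_geometry,
    rasterize_stack,
)

spec = FiberFieldSpec(
    pixels_xy=256,
    z_extent=140.0,
    bundle_depths=[(25.0, 12.0), (55.0, 12.0), (85.0, 12.0), (115.0, 12.0)],
    waviness_amplitude=0.0,
    elastic_jitter_sd=5.0,
    elastic_density=4.0,
    seed=21,
)
collagen = generate_collagen_geometry(spec)
elastic = generate_elastic_geometry(collagen, jitter_sd=5.0, density=4.0, seed=22)
shg = rasterize_stack(collagen, spec, channel="collagen", seed=23)
tpaf = rasterize_stack(elastic, spec, channel="elastic", seed=24)

peaks = find_orientation_peaks(analyze_stack(shg, boundary_z=0))
elastic_profile = analyze_stack(tpaf, boundary_z=0)
hist = collagen_elastic_agreement(peaks, elastic_profile)

print(f"collagen peaks: {len(peaks)}; isotropic elastic slices excluded: "
      f"{hist.n_excluded_isotropic}")
for lo, hi, c in zip(hist.bin_edges[:-1], hist.bin_edges[1:], hist.counts):
    print(f"  {lo:4.0f}–{hi:3.0f}°: {c}")
print(f"fraction of differences ≤ 15°: {hist.fraction_leq_15:.2f}")
# With 5° planted jitter virtually every peak pairs within 15° of its
# elastic counterpart — the signature of a co-organized fiber system.
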