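"""Generate a two-channel synthetic dermis tile and write it to disk.

Builds one 211 µm tile with laminar collagen bundles (bimodal orientation
mixture 66° apart) and a co-aligned sparse elastic network, rasterizes
both channels into calibrated 8-bit z-stacks, and writes multi-page TIFFs
plus ground-truth CSV tables under ./phantom_out/.
"""

from pathlib import Path

from fiborient import (
    FiberFieldSpec,
    generate_collagen_geometry,
    generate_elastic_geometry,
    rasterize_stack,
    io,
)

out = Path("phantom_out")
out.mkdir(exist_ok=True)

spec = FiberFieldSpec(
    pixels_xy=256,  # smaller raster for a quick demo; the study size is 512
    z_extent=120.0,
    bundle_depths=[(20.0, 12.0), (50.0, 12.0), (80.0, 12.0), (105.0, 12.0)],
    seed=1,
)
collagen = generate_collagen_geometry(spec)
elastic = generate_elastic_geometry(collagen, jitter_sd=spec.elastic_jitter_sd,
                                    density=spec.elastic_density, seed=2)

shg = rasterize_stack(collagen, spec, channel="collagen", seed=3)
tpaf = rasterize_stack(elastic, spec, channel="elastic", seed=4)
io.write_stack_tiff(shg, out / "shg.tif")
io.write_stack_tiff(tpaf, out / "tpaf.tif")
collagen.truth_table().to_csv(out / "truth_collagen.csv", index=False)
elastic.truth_table().to_csv(out / "truth_elastic.csv", index=False)

print(f"collagen fibers: {len(collagen)} in {len(spec.bundle_depths)} bundles")
print(f"elastic fibers:  {len(elastic)}")
print(f"stack shape:     {shg.data.shape} at {shg.pixel_pitch:.3f} µm/px, "
      f"z-interval {shg.z_interval} µm")
print(f"wrote {out}/shg.tif, {out}/tpaf.tif and truth tables")
# The truth tables hold each fiber's bundle, depth and planted axial
# orientation — the ground truth the analysis modules are tested against.
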