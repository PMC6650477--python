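"""End-to-end run: 9-tile mosaic → orientation → peaks → agreement → modes.

Synthesizes a 3×3 mosaic of phantom tiles (reduced raster size for a
quick demo), applies the study protocol (equibiaxial extension λ = 1.25
before imaging), and reports the pooled mode structure per reticular
layer.
"""

import json

from fiborient import FiberFieldSpec, RunConfig, run_full_pipeline

spec = FiberFieldSpec(
    pixels_xy=256,
    z_extent=120.0,
    bundle_depths=[(20.0, 12.0), (50.0, 12.0), (80.0, 12.0), (105.0, 12.0)],
    mode_dispersion=10.0,
)
config = RunConfig(n_tiles=9, seed=5, field_spec=spec)
bundle = run_full_pipeline(config)

print(json.dumps(bundle.summary_dict(), indent=2, sort_keys=True))
# peaks_per_tile counts detected bundles per tile; the superficial mode
# fit should select K=2 with centers near the planted 30°/96° mixture
# (within the sampling error of ~40 pooled bundles at 10° bundle-level
# dispersion). All planted bundles sit above the extension-scaled 200 µm
# boundary, so the deep layer is empty here.
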