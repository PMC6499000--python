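"""Validate core/halo segmentation against phantom ground truth.

Sweeps 50 phantoms over core radii 100-400 um and halo counts 0-300 and
tabulates the relative core-area error, halo detection and mask containment.
"""

import numpy as np
import pandas as pd

from common import RESULTS
from spheroquant.phantoms import SpheroidPhantomSpec, make_spheroid_images
from spheroquant.segment import segment_spheroid

rows = []
radii = np.linspace(100.0, 400.0, 10)
for i, (radius, halo) in enumerate((r, h) for h in (0, 75, 150, 225, 300) for r in radii):
    spec = SpheroidPhantomSpec(core_radius_um=radius, halo_cell_count=halo,
                               noise_sd=2.0, seed=1000 + i)
    image, truth = make_spheroid_images(spec)
    res = segment_spheroid(image["brightfield"], pixel_size_um=spec.pixel_size_um)
    rows.append(dict(
        core_radius_um=round(radius, 1), halo_cells=halo,
        core_area_error=abs(res.core_area_um2 - truth.core_area_um2) / truth.core_area_um2,
        halo_detected=res.total_area_um2 > res.core_area_um2,
        containment=bool(np.all(res.total_mask[res.core_mask])),
    ))

df = pd.DataFrame(rows)
df.to_csv(RESULTS / "segmentation_recovery.csv", index=False)
print(f"{len(df)} phantoms: max core-area error {df.core_area_error.max():.4f}, "
      f"halo detected in {df[df.halo_cells > 0].halo_detected.mean():.0%} of halo phantoms, "
      f"containment holds on {df.containment.mean():.0%}")
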