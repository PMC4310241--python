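"""Extract a centerline from a segmented tube and measure its calibre.

The mask is thinned to a medial-axis skeleton, traced into polylines, and at
sampled centerline points the mask is resampled on the plane orthogonal to
the local tangent; the cross-section area A gives the equivalent-circle
radius sqrt(A/pi) (twice that is the diameter).
"""

import numpy as np

from coroseg import (BinaryMask, extract_centerline, measure_diameters)

# digitized straight cylinder: radius 2.35 mm, 0.625 mm voxels, along z
sp = 0.625
xs, ys = np.meshgrid(np.arange(24) * sp, np.arange(24) * sp, indexing="ij")
disk = (xs - 12 * sp) ** 2 + (ys - 12 * sp) ** 2 <= 2.35**2
tube = np.broadcast_to(disk[:, :, None], (24, 24, 48)).copy()
mask = BinaryMask(tube, (sp, sp, sp))

cl = extract_centerline(mask)
print(f"{len(cl.polylines)} polyline(s), {cl.n_points} skeleton points, "
      f"{len(cl.branch_points)} branch point(s)")

pairs = measure_diameters(mask, cl, step=5)
for pos, radius in pairs[2:-2]:
    print(f"  arc position {pos:5.1f} mm -> equivalent-circle radius "
          f"{radius:.3f} mm (true 2.350 mm)")
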