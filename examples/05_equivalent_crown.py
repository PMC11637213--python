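"""Carve the "equivalent crown" from a CBCT tooth using the scan's OBB.

A CBCT segmentation yields the whole tooth while the intraoral scan sees
only the clinical crown. Aligning the scan crown's oriented bounding box
to the CBCT tooth's box (x/y centres from CBCT, z kept from the scan;
prongs parallel) and cutting at the aligned box's bottom face leaves the
CBCT region that actually corresponds to the scanned crown.
"""

import numpy as np

from phmsr.crown_equivalence import align_obb_centers, crop_crown_by_obb_base
from phmsr.geometry_core import RigidTransform, apply_transform, compute_obb
from phmsr.synthetic_data import (make_cbct_cloud, make_scan_cloud,
                                  make_tooth_phantom)

phantom = make_tooth_phantom(seed=4)
scan = make_scan_cloud(phantom, 40.0, seed=5)
cbct_tooth, _ = make_cbct_cloud(phantom, seed=6)
# the CBCT frame is displaced from the scanner frame in reality
cbct_tooth = apply_transform(cbct_tooth,
                             RigidTransform(np.eye(3), [12.0, -6.0, 0.0]))

scan_obb = compute_obb(scan)
cbct_obb = compute_obb(cbct_tooth)
T = align_obb_centers(scan_obb, cbct_obb)
aligned_obb = compute_obb(apply_transform(scan, T))
result = crop_crown_by_obb_base(cbct_tooth, aligned_obb)

print(f"scan OBB centre : {np.round(scan_obb.center, 2)}")
print(f"cbct OBB centre : {np.round(cbct_obb.center, 2)}")
print(f"aligning shift  : {np.round(T.translation, 2)} (z untouched)")
plane_pt, plane_n = result.cut_plane
print(f"cut plane point {np.round(plane_pt, 2)}, normal {np.round(plane_n, 2)}")
print(f"retained {len(result.cropped_cbct_crown)} / {len(cbct_tooth)} "
      "CBCT points on the occlusal side")
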