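"""Measure a muscle cross-sectional area and convert it to a peak force.

Voxelizes a synthetic elliptic-cylinder 'muscle', applies the two-plane
sectioning protocol (P1 plus a second plane 2 mm above) and multiplies
the resulting CSA_max by the 37 N cm^-2 muscle stress factor.
"""

import numpy as np

from cranioload import SectioningProtocol, csa_max, make_muscle_mask, peak_force

mask = make_muscle_mask("elliptic_cylinder", dims=(10.0, 5.0, 40.0), pitch=0.25)
protocol = SectioningProtocol(normal=(0.0, 0.0, 1.0), p1_offset_mm=15.0)

area = csa_max(mask, protocol)
force = peak_force(area)

print(f"analytic section area : {np.pi * 10 * 5 / 100:.4f} cm^2 (pi*a*b)")
print(f"measured CSA_max      : {area:.4f} cm^2 "
      f"(mean of P1 at {protocol.p1_offset_mm} mm and P2 at {protocol.p2_offset_mm} mm)")
print(f"peak muscle force     : {force:.2f} N  (CSA_max x 37 N/cm^2)")
print("A 1 cm^2 muscle yields", peak_force(1.0), "N by the same conversion.")
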