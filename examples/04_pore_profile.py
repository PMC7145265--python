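"""Maximal-inscribed-sphere pore-radius profile of an analytic channel.

An hourglass test geometry with a 1.5 A waist stands in for a channel
pore; the profiler scans slices along the conduction axis and reports
the largest probe sphere that fits at each position.  The stretch
narrower than the 1.8 A chloride radius measures how much of the
pathway is closed to the ion.
"""

import numpy as np

import clcgating as cg
from clcgating.structure import CL_ION_RADIUS

fixture = cg.make_pore_fixture("hourglass", waist=1.5, curvature=0.05,
                               length=24.0, z_step=0.25, atoms_per_ring=36)
profile = cg.pore_profile(fixture.coords, fixture.radii,
                          start_point=[0, 0, 0], axis=[0, 0, 1],
                          extent=6.0, step=0.5, max_radius=2.5)

s_star, r_star = profile.bottleneck
total, longest = cg.subthreshold_extent(profile, threshold=CL_ION_RADIUS)
print("s (A) :", np.round(profile.s, 1))
print("r (A) :", np.round(profile.radius, 2))
print(f"\nbottleneck: r = {r_star:.2f} A at s = {s_star:+.2f} A "
      f"(analytic waist: {fixture.params['waist']:.2f} A)")
print(f"stretch narrower than a Cl- ion ({CL_ION_RADIUS} A): "
      f"{longest:.1f} A contiguous")
# A bottleneck below 1.8 A means a chloride ion cannot pass this
# conformation; the contiguous sub-threshold length is the quantity that
# distinguishes closed from open-like pore shapes.
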