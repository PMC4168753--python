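"""Anatomy of one high-load indentation.

Generates a single synthetic force-distance curve with the C2C12 preset
(membrane rupture forces ~N(672, 100) nN), runs the full curve analysis,
and prints every derived mechanical feature next to the generator's
ground truth.
"""

import numpy as np

from mechanoca import analyze_curve, gen_force_curve, load_preset

config = load_preset("c2c12")
rng = np.random.default_rng(1)

curve, truth = gen_force_curve(config.curve, "high_load", rng)
features = analyze_curve(curve)

print(f"load class          {features.load_class}")
print(f"contact point       {features.contact_z:.3f} um   (truth {truth['contact_z_um']:.3f})")
print(f"max force           {features.max_force:.0f} nN    (target ~2800)")
print(f"rupture force       {features.rupture.force_before:.1f} nN  (truth {truth['rupture_force_nN']:.1f})")
print(f"deformation extent  {features.deformation_extent:.3f} um  (truth {truth['deformation_extent_um']:.3f})")
print(f"penetration depth   {features.penetration_depth:.3f} um  (truth {truth['penetration_depth_um']:.3f})")
print(f"hysteresis energy   {features.hysteresis_energy:.0f} fJ")
print(f"contact time        {features.contact_time:.3f} s   (truth {truth['contact_time_s']:.3f})")
print()
print("The rupture force is the cell-resistance force just before the sudden")
print("drop that marks tip penetration of the plasma membrane; the hysteresis")
print("energy is the area between approach and retraction (energy dissipated")
print("deforming and penetrating the cell).")
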