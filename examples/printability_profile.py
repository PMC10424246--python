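"""Printability profile of a water-like culture medium.

Builds the jet configuration used for valve-based droplet printing — a
250 µm nozzle expelling a low-viscosity cell medium at ~2 m/s — and prints
its dimensionless-number profile.
"""

from epidrop import printability as pr

spec = pr.FluidJetSpec(
    viscosity=1.0e-3,        # Pa·s — water-like medium
    surface_tension=0.0728,  # N/m
    density=998.0,           # kg/m³
    orifice_diameter=250e-6, # m — nozzle inner diameter
    droplet_velocity=2.0,    # m/s
)
profile = pr.profile(spec)

for name, value in profile.to_dict().items():
    print(f"{name:>20}: {value}")

print()
print("Z between ~4 and ~100 jets stable droplets; Bo < 1 means gravity is")
print("negligible during spreading; K_sp < 57.7 means impacts do not splash.")
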