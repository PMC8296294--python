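"""Convert the palm resistance grid into drag coefficients.

Loads the packaged resistance table (force on the palm at five flow
speeds and four finger-spread angles, from CFD of a palm held square to
the flow) and inverts the quadratic drag law Cd = 2*Fd/(rho*A*V^2) with
rho = 998.2 kg/m^3 and the 0.015 m^2 reference palm area.
"""

import numpy as np

from swimdyn import FluidEnvironment, coefficient_grid
from swimdyn.io import fixture_path, read_resistance_grid

grid = coefficient_grid(
    read_resistance_grid(fixture_path("palm_resistance_grid.csv")),
    FluidEnvironment(),
    area=0.015,
)

header = "speed " + "  ".join(f"{a:>5.0f}deg" for a in grid.spread_angles)
print(header)
for v, row in zip(grid.speeds, grid.coefficient):
    print(f"{v:5.1f} " + "  ".join(f"{c:8.3f}" for c in row))

print()
print("Coefficients fall with speed (steeply at low speed) and, at fixed")
print("speed, fall slightly as the fingers spread: a wider spread presents")
print("a leakier paddle, so less resistance and hence less propulsion.")
print(f"Range: {grid.coefficient.min():.2f}-{grid.coefficient.max():.2f}")
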