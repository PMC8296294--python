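"""Evaluate the closed-form swimming-speed representation model.

V = Z*m / (t*rho*A*(Z+N)*(Cd+Cl)): cycle speed from stroke work Z,
body mass m, cycle time t, water density rho, frontal cross-section A,
non-propulsive energy N and the drag/propulsion coefficients.  The
script also rebuilds V through the component equations to show they
agree.
"""

from swimdyn import SpeedModelInput, s2r_speed, speed_from_energy, stroke_length

inp = SpeedModelInput(
    propulsive_work=180.0,  # J per cycle
    body_mass=72.0,  # kg
    cycle_time=1.2,  # s
    density=998.2,  # kg/m^3
    cross_section=0.08,  # m^2
    non_propulsive_energy=60.0,  # J lost to entrained water
    drag_coefficient=0.9,
    propulsion_coefficient=0.4,
)

v = s2r_speed(inp)
v_energy = speed_from_energy(
    inp.propulsive_work, inp.non_propulsive_energy, inp.body_mass
)
force = 0.5 * inp.density * inp.cross_section * 1.3 * v_energy**2
length = stroke_length(inp.propulsive_work, force)

print(f"energy-balance speed  V_e = {v_energy:.3f} m/s")
print(f"cycle-average force   F   = {force:.1f} N")
print(f"stroke length         L   = {length:.4f} m")
print(f"cycle speed           V   = {v:.4f} m/s  (= L / t)")
print()
print("V responds as the physics dictates: longer cycles, denser water,")
print("larger frontal area or higher drag all slow the swimmer; only the")
print("share of work that is propulsive (Z vs N) and body mass raise V.")
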