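"""Benchmark: implied coupling direction for four damped-oscillator scenarios.

Simulates two linear damped oscillators under no coupling, each one-way
coupling, and competitive two-way coupling, then runs the full
inter-system recurrence analysis on the standardized (position, velocity)
states: thresholds calibrated to 5% auto / 3% cross recurrence, global
cross-clustering pair, and the implied direction from the +-.01 rule.
"""

from irnet import analyze_pair, scenario_params, simulate

print(f"{'scenario':14s} {'eps_X':>6s} {'eps_Y':>6s} {'eps_XY':>6s} "
      f"{'C_XY':>6s} {'C_YX':>6s} {'dC':>7s}  direction")
for name in ("uncoupled", "x_drives_y", "y_drives_x", "bidirectional"):
    traj = simulate(scenario_params(name))
    s = analyze_pair(
        traj.state_x(), traj.state_y(), rr_auto=0.05, rr_cross=0.03
    )
    ex, ey, exy = s.thresholds
    print(
        f"{name:14s} {ex:6.3f} {ey:6.3f} {exy:6.3f} "
        f"{s.c_xy:6.3f} {s.c_yx:6.3f} {s.delta_c:+7.3f}  {s.direction}"
    )

print(
    "\nA negative dC = C_XY - C_YX reads as 'X leads' (X drives Y), a"
    "\npositive one as 'Y leads'; |dC| <= .01 is bidirectional or uncoupled."
    "\nThe uncoupled pair is exactly symmetric, and each one-way scenario"
    "\nputs the larger coefficient on the driven side."
)
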