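"""Lateral migration of a single RBC surrogate in a periodic pipe.

One particle is released at r* = 0.5 in a 50 um channel at Re = 0.5.  The
deformability-induced lift (positive lift coefficient) drives it toward the
axis; printing the radial coordinate over time shows the monotone centerward
drift.  Rerun with lift_enabled=False and the drift disappears — the lift
closure is the only mechanism for cross-stream motion here.
"""

import warnings

import numpy as np

from rbcdem import ParticleSet, Simulation, straight_channel_case
from rbcdem.grid import sample_fields

warnings.filterwarnings("ignore")

for lift in (True, False):
    cfg = straight_channel_case(D=50e-6, L=100e-6, Re=0.5, Ht_c=0.0, seed=0,
                                lift_enabled=lift)
    sim = Simulation(cfg)
    p = ParticleSet([[12.5e-6, 0.0, 50e-6]], d_p=cfg.d_p, rho_p=cfg.rho_p)
    p.vel = sample_fields(sim.fluid, sim.grid, p.pos)["u"].copy()
    sim.particles = p
    print(f"\nlift {'on' if lift else 'off'}:")
    print(f"{'t [ms]':>8} {'r* = r/R_c':>12} {'DI':>8}")
    for k in range(300):
        sim.step()
        if k % 60 == 59:
            r_star = np.hypot(p.pos[0, 0], p.pos[0, 1]) / cfg.channel.R_c
            print(f"{sim.t * 1e3:>8.2f} {r_star:>12.4f} {p.DI[0]:>8.4f}")

print("\nWith the lift active the radial position decreases steadily "
      "(centerward migration, the mechanism behind the cell-free layer); "
      "without it the particle simply follows its streamline.")
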