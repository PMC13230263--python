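"""Cell deformation through an axisymmetric stenosis.

A 50 um channel constricted to a 25 um throat (a scaled model of a partially
occluded vessel) is run briefly with ~130 cells at 3% hematocrit.  The
deformation index follows the local shear, so the spatially averaged <DI>
profile along the channel peaks in the throat — the same pattern used to judge
membrane stress (hence hemolysis risk) in occluded-vessel studies.
"""

import warnings

import numpy as np

from rbcdem import Simulation, stenosis_case
from rbcdem.dem import ContactParams
from rbcdem.metrics import di_statistics
from rbcdem.scenarios import CaseConfig

warnings.filterwarnings("ignore")

spec = stenosis_case(D=50e-6, throat=25e-6, L=200e-6, Re=0.5, Ht_c=0.03)
cfg = CaseConfig(channel=spec, contacts=ContactParams(young=100.0), seed=2,
                 recycle_inlet=True)
sim = Simulation(cfg)
print(f"{len(sim.particles)} cells, throat/diameter = "
      f"{spec.stenosis.throat / spec.D:.2f}")
for _ in range(150):
    sim.step()

out = di_statistics(sim.particles, n_stream_bins=8, L=spec.L)
print(f"\n{'z [um]':>8} {'<DI>':>8}   wall radius [um]")
for zc, di in zip(out["stream_bin_centers"], out["stream_profile"]):
    rw = float(spec.wall_radius(np.array([zc]))[0])
    bar = "#" * int(0 if np.isnan(di) else di * 400)
    print(f"{zc * 1e6:>8.0f} {di:>8.4f}   {rw * 1e6:>6.1f}  {bar}")
print("\n<DI> peaks in the constriction (z around 100 um), where the shear "
      "rate is highest: cells are worked hardest passing the throat.")
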