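"""Monte-Carlo simulation of post-Golgi carrier departure.

Central geometry: carriers on a ring around the centrosome are removed when
a randomly directed microtubule growth event reaches their arc.  Fragmented
geometry: ministacks scattered in the cell are removed when a random
membrane-hovering event lands within the capture radius.  In both cases the
trial-averaged remaining count follows the geometric decay y = a*(1-r)^x,
i.e. fluorescence leaves the Golgi zone exponentially even though no single
carrier "diffuses" out.
"""

import numpy as np

from golgikin import (CentralConfig, FragmentedConfig, fit_decay_law,
                      simulate_central, simulate_fragmented)

central = CentralConfig(n_gpc=20, arc_width_rad=2 * np.pi * 0.05,
                        n_events=60, n_trials=1000, seed=42)
res = simulate_central(central)
fit = fit_decay_law(res)
print("central Golgi (microtubule hits):")
print(f"  analytic per-event hit probability = {central.hit_prob:.3f}")
print(f"  fitted decay law y = {fit.a:.2f} * (1 - {fit.r:.4f})^x, "
      f"R^2 = {fit.r2:.5f}")

frag = FragmentedConfig(cell_radius=10.0, n_ministacks=30,
                        hit_radius=10.0 * np.sqrt(0.02), n_events=60,
                        n_trials=1000, seed=43)
fres = simulate_fragmented(frag)
ffit = fit_decay_law(fres)
print("fragmented Golgi (membrane hovering):")
print(f"  analytic area-fraction hit probability = {frag.hit_prob:.3f}")
print(f"  fitted decay law y = {ffit.a:.2f} * (1 - {ffit.r:.4f})^x, "
      f"R^2 = {ffit.r2:.5f}")
print("Fitted r matches the geometric hit probability in both geometries;")
print("the curve shape is exponential regardless of the parameter values.")
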