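"""Synthetic wet-lab readouts: immunoblot markers and an apoptotic index.

Maps a simulated high-stress population onto the observables an experiment
would measure — LC3II / p62 blots for autophagy, procaspase-3 / cleaved PARP
for apoptosis, and an Annexin-style percentage of apoptotic cells counted
from 1000 cells — including densitometry-style multiplicative noise.
"""

import numpy as np

from erfate import ModelParameters, constant_stress, ensemble_mean, simulate_ensemble
from erfate.observables import apoptotic_index, markers_from_trajectory

params = ModelParameters()
ens = simulate_ensemble(params, constant_stress(5.0, 240.0), n_cells=50, master_seed=1)

markers = markers_from_trajectory(ensemble_mean(ens), noise_cv=0.15, seed=2)
grid = np.arange(0, 241, 30)
index = apoptotic_index(ens, grid, n_counted=1000, seed=3)

print("t(min)  LC3II   p62  procasp3  clPARP   apoptotic index (%)")
for t, idx in zip(grid, index):
    i = int(t)
    print(f"{t:5.0f}  {markers.LC3II[i]:6.2f} {markers.p62[i]:5.2f} "
          f"{markers.procaspase3[i]:8.2f} {markers.cleavedPARP[i]:7.2f}   {idx:6.1f}")

# LC3II rises and falls with the autophagy transient, p62 decays with
# cumulative autophagic flux, procaspase-3 is consumed as cleaved PARP and
# the counted apoptotic index climb — the blot pattern of a lethal stress.
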