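"""Build the synthetic host-guest complex and sample its bound state.

The fixture emulates the statistical structure of a riboswitch-like
binding site: an anionic two-ring pocket, three restrained divalent-ion
beads, and a flexible two-arm cationic guest.
"""

import numpy as np

from lambdabf.analysis import InteractionDefinition, interaction_summary
from lambdabf.systems import (LangevinSettings, make_host_guest_fixture,
                              potential_energy, run_langevin)

system, reference = make_host_guest_fixture(seed=1)
displaced = reference.copy()
displaced[system.ligand] += np.array([0.0, 0.0, 20.0])
print(f"{system.n_particles} particles; bound pose energy "
      f"{potential_energy(system, reference):.1f} kcal/mol vs "
      f"{potential_energy(system, displaced):.1f} with the guest displaced "
      "20 A -> a clear binding basin.")

settings = LangevinSettings(temperature=300.0, friction=5.0, timestep=1.5,
                            n_steps=20000, seed=4, save_stride=20)
traj = run_langevin(system, settings)
print(f"sampled {traj.n_frames} frames; mean kinetic temperature "
      f"{traj.scalars['temperature'][50:].mean():.1f} K (target 300 K)")

site = np.where(system.mask("site"))[0]
lig = np.where(system.ligand)[0]
rows = interaction_summary(
    traj.positions, system.masses,
    [InteractionDefinition("SITEcom-LIGcom", "com_distance", site, lig,
                           window=(0.0, 6.0))])
row = rows[0]
print(f"site-guest COM distance: mode {row['mode']:.2f} A, occupancy "
      f"{row['occupancy']:.2f} inside 6 A -> the guest stays in the pocket.")
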