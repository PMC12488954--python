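"""Deep-LDA machine-learned collective variable on an Apo/Holo toy system.

A mobile particle hops between two conformational basins separated along
y; the observer only measures distances to three anchor beads (as one
would measure P-Mg distances in an RNA). Deep-LDA learns a CV from short
unbiased runs in each basin; OPES along that learned CV drives
transitions that biasing a naively chosen coordinate (x) cannot produce.
"""

import numpy as np

from lambdabf.mlcv import (DescriptorDefinition, LdaCv, compute_descriptors,
                           fit_deep_lda, fit_lda)
from lambdabf.opes import AxisPositionCV, OpesBias, run_opes
from lambdabf.systems import (AxisHarmonicRestraint, DoubleWell1D,
                              LangevinSettings, ParticleSystem, run_langevin)

anchors = np.array([[3.0, 0, 0], [0, 3.0, 0], [-2.0, -2, 0]])


def make(y0):
    pos = np.vstack([anchors, [[0.0, y0, 0.0]]])
    return ParticleSystem(
        positions=pos, masses=np.array([30.0] * 3 + [6.0]),
        charges=np.zeros(4), lj_epsilon=np.zeros(4),
        lj_sigma=np.full(4, 3.0),
        roles=np.asarray(["site"] * 3 + ["ligand"], dtype=object),
        frozen=np.array([True] * 3 + [False]))


well = DoubleWell1D(particle=3, axis=1, height=5.0, half_distance=1.2)
confine = AxisHarmonicRestraint(3, (0, 2), k=2.0)


def unbiased_run(y0, seed):
    st = LangevinSettings(temperature=300.0, friction=3.0, timestep=2.0,
                          n_steps=4000, seed=seed, save_stride=4)
    return run_langevin(make(y0), st, attachments=[well, confine])


defs = [DescriptorDefinition("distance", (3, i)) for i in range(3)]
x_apo = compute_descriptors(unbiased_run(-1.2, 21).positions, defs)
x_holo = compute_descriptors(unbiased_run(1.2, 22).positions, defs)
print(f"plain LDA Fisher ratio: {fit_lda(x_apo, x_holo).fisher():.2f}")
model = fit_deep_lda(x_apo, x_holo, hidden=(16, 8), seed=5, epochs=200)
print(f"Deep-LDA Fisher ratio on hidden layer: {model.fisher():.2f}")
cv = LdaCv(model, defs)

s_apo = np.array([cv.value(p) for p in unbiased_run(-1.2, 21).positions[::10]])
sigma = max(float(s_apo.std()), 1e-3)


def crossings(y):
    yf = y[np.abs(y) > 0.6]
    return int(np.sum(np.abs(np.diff(np.sign(yf))) > 0))


settings = LangevinSettings(temperature=300.0, friction=3.0, timestep=2.0,
                            n_steps=30000, seed=31, save_stride=10)
bias = OpesBias(sigma=sigma, barrier=12.0, temperature=300.0, pace=300)
traj, _ = run_opes(make(-1.2), cv, bias, settings,
                   attachments=[well, confine])
print(f"OPES on the learned CV: {crossings(traj.positions[:, 3, 1])} "
      "Apo<->Holo transitions")

bias_x = OpesBias(sigma=0.3, barrier=12.0, temperature=300.0, pace=300)
traj_x, _ = run_opes(make(-1.2), AxisPositionCV(3, 0), bias_x, settings,
                     attachments=[well, confine])
print(f"OPES on the x coordinate:  {crossings(traj_x.positions[:, 3, 1])} "
      "transitions")
print("the learned combination of anchor distances resolves the slow")
print("y motion; the hand-picked x coordinate is orthogonal to it.")
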