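"""Toy particle systems and a BAOAB Langevin engine.

Every sampling method in the package (lambda-ABF, OPES, restraint TI) runs
on the same minimal molecular model: point particles with harmonic bonds
and angles, Lennard-Jones and Coulomb nonbonded terms, no cutoff and no
periodic boundary (particle counts are small by design). Host/guest
fixtures emulate the statistical structure of a riboswitch-like binding
site — an anionic pocket organised around restrained divalent-ion beads,
holding a flexible polycationic guest — without any claim of atomistic
realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .units import COULOMB, KB, MASS_ENERGY

ROLES = ("host", "site", "ion", "ligand", "bath")

#: Pair distances below this (Å) make the unscaled potential meaningless.
OVERLAP_GUARD = 0.1


class ConfigurationError(ValueError):
    """Invalid system construction parameters."""


class OverlapError(ValueError):
    """Particles closer than the numerical guard distance."""


class IntegrationError(RuntimeError):
    """Energy divergence during dynamics; carries the failing step."""


@dataclass
class HarmonicBond:
    i: int
    j: int
    k: float          # kcal/mol/Å²
    r0: float         # Å


@dataclass
class HarmonicAngle:
    i: int
    j: int            # apex
    k: int
    k_theta: float    # kcal/mol/rad²
    theta0: float     # rad


@dataclass
class ParticleSystem:
    """Positions, topology and nonbonded parameters of a toy system.

    ``frozen`` particles are excluded from integration (their velocities
    stay zero); they still exert forces on mobile particles.
    """

    positions: np.ndarray          # (N, 3) Å
    masses: np.ndarray             # (N,) amu
    charges: np.ndarray            # (N,) e
    lj_epsilon: np.ndarray         # (N,) kcal/mol
    lj_sigma: np.ndarray           # (N,) Å
    roles: np.ndarray              # (N,) str
    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    exclusions: set = field(default_factory=set)   # frozenset({i, j})
    velocities: np.ndarray | None = None           # (N, 3) Å/fs
    frozen: np.ndarray | None = None               # (N,) bool
    #: distance-independent dielectric screening of all Coulomb terms;
    #: fixtures use values > 1 to emulate aqueous screening implicitly
    dielectric: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        n = self.n_particles
        for name in ("masses", "charges", "lj_epsilon", "lj_sigma"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ConfigurationError(
                    f"{name} has shape {arr.shape}, expected ({n},)")
            setattr(self, name, arr)
        self.roles = np.asarray(self.roles, dtype=object)
        if self.roles.shape != (n,):
            raise ConfigurationError("roles must have one entry per particle")
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise ConfigurationError(f"unknown roles: {sorted(bad)}")
        if self.velocities is None:
            self.velocities = np.zeros((n, 3))
        else:
            self.velocities = np.asarray(self.velocities, dtype=float)
        if self.frozen is None:
            self.frozen = np.zeros(n, dtype=bool)
        else:
            self.frozen = np.asarray(self.frozen, dtype=bool)
        self._tables = None

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def mask(self, *roles: str) -> np.ndarray:
        return np.isin(self.roles, roles)

    @property
    def ligand(self) -> np.ndarray:
        return self.mask("ligand")

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            positions=self.positions.copy(),
            masses=self.masses.copy(),
            charges=self.charges.copy(),
            lj_epsilon=self.lj_epsilon.copy(),
            lj_sigma=self.lj_sigma.copy(),
            roles=self.roles.copy(),
            bonds=list(self.bonds),
            angles=list(self.angles),
            exclusions=set(self.exclusions),
            velocities=self.velocities.copy(),
            frozen=self.frozen.copy(),
            dielectric=self.dielectric,
        )

    # -- cached pair tables -------------------------------------------------

    def pair_tables(self) -> "PairTables":
        if self._tables is None:
            self._tables = PairTables.build(self)
        return self._tables


class PairTables:
    """Precomputed i<j pair index arrays with mixed LJ/Coulomb parameters."""

    def __init__(self, ii, jj, eps, sig, qq, lig_env):
        self.ii = ii
        self.jj = jj
        self.eps = eps
        self.sig = sig
        self.qq = qq
        #: boolean mask over pairs: exactly one member is a ligand particle
        self.lig_env = lig_env

    @classmethod
    def build(cls, system: ParticleSystem) -> "PairTables":
        n = system.n_particles
        ii, jj = np.triu_indices(n, k=1)
        if system.exclusions:
            keep = np.array(
                [frozenset((int(a), int(b))) not in system.exclusions
                 for a, b in zip(ii, jj)])
            ii, jj = ii[keep], jj[keep]
        eps = np.sqrt(system.lj_epsilon[ii] * system.lj_epsilon[jj])
        sig = 0.5 * (system.lj_sigma[ii] + system.lj_sigma[jj])
        qq = (COULOMB / system.dielectric
              * system.charges[ii] * system.charges[jj])
        is_lig = system.ligand
        lig_env = is_lig[ii] ^ is_lig[jj]
        return cls(ii, jj, eps, sig, qq, lig_env)


# ---------------------------------------------------------------------------
# energies and forces


def _pair_geometry(positions: np.ndarray, tables: PairTables):
    d = positions[tables.jj] - positions[tables.ii]
    r2 = np.einsum("ij,ij->i", d, d)
    return d, r2


def _bonded_energy_forces(system: ParticleSystem, positions: np.ndarray):
    e = 0.0
    f = np.zeros_like(positions)
    for b in system.bonds:
        d = positions[b.j] - positions[b.i]
        r = float(np.linalg.norm(d))
        e += 0.5 * b.k * (r - b.r0) ** 2
        if r > 1e-12:
            g = b.k * (r - b.r0) * d / r
            f[b.i] += g
            f[b.j] -= g
    for a in system.angles:
        rij = positions[a.i] - positions[a.j]
        rkj = positions[a.k] - positions[a.j]
        nij = float(np.linalg.norm(rij))
        nkj = float(np.linalg.norm(rkj))
        c = float(np.dot(rij, rkj) / (nij * nkj))
        c = min(1.0, max(-1.0, c))
        theta = np.arccos(c)
        e += 0.5 * a.k_theta * (theta - a.theta0) ** 2
        # F = -dU/dθ · dθ/dr with dθ/dr = -(1/sinθ)·dc/dr
        s = np.sqrt(max(1.0 - c * c, 1e-12))
        du = a.k_theta * (theta - a.theta0)
        gi = (du / s) * (rkj / (nij * nkj) - c * rij / (nij * nij))
        gk = (du / s) * (rij / (nij * nkj) - c * rkj / (nkj * nkj))
        f[a.i] += gi
        f[a.k] += gk
        f[a.j] -= gi + gk
    return e, f


def nonbonded_energy_forces(system: ParticleSystem,
                            positions: np.ndarray | None = None,
                            guard: bool = True):
    """Full LJ + Coulomb over non-excluded pairs; returns (E, F)."""
    if positions is None:
        positions = system.positions
    t = system.pair_tables()
    d, r2 = _pair_geometry(positions, t)
    if guard and np.any(r2 < OVERLAP_GUARD ** 2):
        k = int(np.argmin(r2))
        raise OverlapError(
            f"particles {t.ii[k]} and {t.jj[k]} closer than {OVERLAP_GUARD} Å")
    r2 = np.maximum(r2, 1e-12)
    inv_r2 = 1.0 / r2
    sr6 = (t.sig ** 2 * inv_r2) ** 3
    e_lj = 4.0 * t.eps * (sr6 ** 2 - sr6)
    r = np.sqrt(r2)
    e_c = t.qq / r
    # dU/dr per pair divided by r, for vector assembly
    dudr_over_r = (
        4.0 * t.eps * (-12.0 * sr6 ** 2 + 6.0 * sr6) * inv_r2
        - t.qq / (r2 * r)
    )
    pair_f = dudr_over_r[:, None] * d      # force on j
    f = np.zeros_like(positions)
    np.add.at(f, t.jj, -pair_f)
    np.add.at(f, t.ii, pair_f)
    return float(np.sum(e_lj) + np.sum(e_c)), f


def potential_energy(system: ParticleSystem,
                     positions: np.ndarray | None = None) -> float:
    """Total potential energy (kcal/mol): bonded + LJ + Coulomb."""
    if positions is None:
        positions = system.positions
    e_nb, _ = nonbonded_energy_forces(system, positions)
    e_b, _ = _bonded_energy_forces(system, positions)
    return e_nb + e_b


def forces(system: ParticleSystem,
           positions: np.ndarray | None = None,
           attachments: Sequence = ()) -> np.ndarray:
    """Analytic forces (kcal/mol/Å), including attached restraints/biases."""
    if positions is None:
        positions = system.positions
    e_nb, f = nonbonded_energy_forces(system, positions)
    _, fb = _bonded_energy_forces(system, positions)
    f += fb
    for att in attachments:
        _, fa = att.energy_forces(positions)
        f += fa
    return f


def total_energy_forces(system: ParticleSystem, positions: np.ndarray,
                        attachments: Sequence = ()):
    e_nb, f = nonbonded_energy_forces(system, positions)
    e_b, fb = _bonded_energy_forces(system, positions)
    e = e_nb + e_b
    f = f + fb
    for att in attachments:
        ea, fa = att.energy_forces(positions)
        e += ea
        f += fa
    return e, f


# ---------------------------------------------------------------------------
# attachments (restraints / external potentials / biases)


class PositionalRestraint:
    """Harmonic tether U = ½ k Σ|r_i − r_i⁰|² on selected particles.

    Default k of 1 kcal/mol/Å² mirrors the light restraints placed on
    backbone-phosphate and divalent-ion particles during decoupling so the
    receptor end state of the thermodynamic cycle stays fixed.
    """

    def __init__(self, indices: Iterable[int], centers: np.ndarray,
                 k: float = 1.0, label: str = "positional"):
        self.indices = np.asarray(list(indices), dtype=int)
        self.centers = np.asarray(centers, dtype=float)
        self.k = float(k)
        self.label = label

    def energy_forces(self, positions: np.ndarray):
        d = positions[self.indices] - self.centers
        e = 0.5 * self.k * float(np.sum(d * d))
        f = np.zeros_like(positions)
        f[self.indices] = -self.k * d
        return e, f


class DoubleWell1D:
    """Quartic double well U = h·((x²−a²)/a²)² + tilt·x on one coordinate.

    Minima near ±a (Å) separated by a barrier of height ≈h (kcal/mol) at
    0; a non-zero ``tilt`` (kcal/mol/Å) makes the two wells inequivalent
    so the inter-well free-energy difference is non-trivial.
    """

    def __init__(self, particle: int = 0, axis: int = 0,
                 height: float = 3.0, half_distance: float = 1.0,
                 tilt: float = 0.0, label: str = "double_well"):
        self.particle = particle
        self.axis = axis
        self.h = float(height)
        self.a = float(half_distance)
        self.tilt = float(tilt)
        self.label = label

    def energy(self, x) -> float:
        u = (np.asarray(x) ** 2 - self.a * self.a) / (self.a * self.a)
        return self.h * u * u + self.tilt * np.asarray(x)

    def energy_forces(self, positions: np.ndarray):
        x = positions[self.particle, self.axis]
        a2 = self.a * self.a
        u = (x * x - a2) / a2
        e = self.h * u * u + self.tilt * x
        dedx = self.h * 2.0 * u * 2.0 * x / a2 + self.tilt
        f = np.zeros_like(positions)
        f[self.particle, self.axis] = -dedx
        return e, f


class AxisHarmonicRestraint:
    """Harmonic confinement U = ½k·Σ_axes x_axis² on selected axes of one
    particle (e.g. restrict motion to a line or plane)."""

    def __init__(self, particle: int, axes: tuple[int, ...], k: float,
                 label: str = "axis_confinement"):
        self.particle = particle
        self.axes = tuple(axes)
        self.k = float(k)
        self.label = label

    def energy_forces(self, positions: np.ndarray):
        f = np.zeros_like(positions)
        e = 0.0
        for ax in self.axes:
            x = positions[self.particle, ax]
            e += 0.5 * self.k * x * x
            f[self.particle, ax] = -self.k * x
        return e, f


class FlatBottomDistanceRestraint:
    """Zero inside radius r0 around a fixed point, harmonic beyond."""

    def __init__(self, particle: int, center: np.ndarray, r0: float,
                 k: float, label: str = "flat_bottom"):
        self.particle = particle
        self.center = np.asarray(center, dtype=float)
        self.r0 = float(r0)
        self.k = float(k)
        self.label = label

    def energy_forces(self, positions: np.ndarray):
        d = positions[self.particle] - self.center
        r = float(np.linalg.norm(d))
        f = np.zeros_like(positions)
        if r <= self.r0 or r < 1e-12:
            return 0.0, f
        e = 0.5 * self.k * (r - self.r0) ** 2
        f[self.particle] = -self.k * (r - self.r0) * d / r
        return e, f


# ---------------------------------------------------------------------------
# Langevin dynamics


@dataclass
class LangevinSettings:
    """BAOAB Langevin integrator settings.

    friction is in 1/ps, timestep in fs. ``save_stride`` thins the stored
    trajectory; every step still contributes to attached accumulators.
    """

    temperature: float = 300.0
    friction: float = 1.0
    timestep: float = 1.0
    n_steps: int = 10000
    seed: int = 0
    save_stride: int = 10

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ConfigurationError("timestep must be > 0")
        if self.friction < 0:
            raise ConfigurationError("friction must be ≥ 0")
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be > 0")


@dataclass
class Trajectory:
    """Stored frames: times (ps), positions and named per-frame scalars."""

    times: np.ndarray
    positions: np.ndarray          # (F, N, 3)
    scalars: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        nf = len(self.times)
        for name, s in self.scalars.items():
            if len(s) != nf:
                raise ValueError(f"scalar series {name!r} length mismatch")
        if nf > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def write_columns(self, path) -> None:
        """Colvars-style columnar text export with a # header line."""
        names = ["time_ps"] + sorted(self.scalars)
        cols = [self.times] + [self.scalars[n] for n in names[1:]]
        data = np.column_stack(cols)
        header = " ".join(names)
        np.savetxt(path, data, header=header)


def maxwell_boltzmann_velocities(system: ParticleSystem, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    sigma = np.sqrt(KB * temperature / (system.masses * MASS_ENERGY))
    v = rng.standard_normal((system.n_particles, 3)) * sigma[:, None]
    v[system.frozen] = 0.0
    return v


def kinetic_temperature(system: ParticleSystem,
                        velocities: np.ndarray) -> float:
    free = ~system.frozen
    ke = 0.5 * MASS_ENERGY * float(
        np.sum(system.masses[free, None] * velocities[free] ** 2))
    ndof = 3 * int(np.sum(free))
    return 2.0 * ke / (ndof * KB)


def run_langevin(system: ParticleSystem, settings: LangevinSettings,
                 attachments: Sequence = (),
                 recorders: dict[str, Callable[[np.ndarray], float]] | None = None,
                 initialize_velocities: bool = True) -> Trajectory:
    """Propagate BAOAB Langevin dynamics and record a thinned trajectory.

    ``attachments`` contribute energies and forces each step (restraints,
    external wells, biases); their energies are stored under their labels.
    ``recorders`` are extra named scalar functions of the positions.
    Identical settings and seed reproduce the trajectory bit-for-bit.
    """
    rng = np.random.default_rng(settings.seed)
    pos = system.positions.copy()
    free = ~system.frozen
    if initialize_velocities:
        vel = maxwell_boltzmann_velocities(system, settings.temperature, rng)
    else:
        vel = system.velocities.copy()

    dt = settings.timestep
    inv_m = 1.0 / (system.masses[:, None] * MASS_ENERGY)
    inv_m[system.frozen] = 0.0
    gamma_dt = settings.friction * dt * 1e-3      # friction 1/ps, dt fs
    c1 = np.exp(-gamma_dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    sig_v = np.sqrt(KB * settings.temperature /
                    (system.masses * MASS_ENERGY))[:, None]

    e, f = total_energy_forces(system, pos, attachments)
    times, frames = [], []
    series: dict[str, list] = {"potential_energy": [], "temperature": []}
    for att in attachments:
        series.setdefault(att.label, [])
    recorders = recorders or {}
    for name in recorders:
        series.setdefault(name, [])

    def record(step: int) -> None:
        times.append(step * dt * 1e-3)
        frames.append(pos.copy())
        e_atts = {}
        e_total = 0.0
        e_nb, _ = nonbonded_energy_forces(system, pos)
        e_b, _ = _bonded_energy_forces(system, pos)
        e_total = e_nb + e_b
        for att in attachments:
            ea, _ = att.energy_forces(pos)
            e_atts[att.label] = e_atts.get(att.label, 0.0) + ea
            e_total += ea
        series["potential_energy"].append(e_total)
        series["temperature"].append(kinetic_temperature(system, vel))
        for label, val in e_atts.items():
            series[label].append(val)
        for name, fn in recorders.items():
            series[name].append(fn(pos))

    record(0)
    for step in range(1, settings.n_steps + 1):
        vel += 0.5 * dt * f * inv_m
        pos[free] += 0.5 * dt * vel[free]
        if settings.friction > 0:
            noise = rng.standard_normal(pos.shape)
            vel[free] = (c1 * vel[free] + c2 * sig_v[free] * noise[free])
        pos[free] += 0.5 * dt * vel[free]
        e, f = total_energy_forces(system, pos, attachments)
        if not np.isfinite(e) or abs(e) > 1e8:
            raise IntegrationError(f"energy diverged at step {step}: E={e}")
        vel += 0.5 * dt * f * inv_m
        if step % settings.save_stride == 0:
            record(step)

    return Trajectory(
        times=np.asarray(times),
        positions=np.asarray(frames),
        scalars={k: np.asarray(v) for k, v in series.items()},
    )


# ---------------------------------------------------------------------------
# fixtures


def _relax_mobile(system: ParticleSystem, max_iter: int = 300) -> None:
    """Deterministic L-BFGS relaxation of the mobile particles in place."""
    from scipy.optimize import minimize as _minimize

    mobile = np.where(~system.frozen)[0]
    if len(mobile) == 0:
        return
    pos0 = system.positions.copy()

    def fun(x):
        p = pos0.copy()
        p[mobile] = x.reshape(-1, 3)
        e, f = total_energy_forces(system, p)
        return e, -f[mobile].ravel()

    res = _minimize(fun, pos0[mobile].ravel(), jac=True, method="L-BFGS-B",
                    options={"maxiter": max_iter})
    system.positions[mobile] = res.x.reshape(-1, 3)


def make_host_guest_fixture(seed: int, n_site: int = 8, arm_length: int = 3,
                            guest_charge: int = 2,
                            add_counterions: bool = False):
    """Synthetic host–guest complex with a bound basin.

    Builds an anionic two-ring pocket (roles: the upper ring is ``site``,
    the lower ``host``), three divalent ``ion`` beads at the back of the
    cavity, and a flexible two-arm polycationic guest (role ``ligand``)
    whose scaffold bead sits inside the pocket in the returned reference
    pose. Different seeds jitter coordinates; topology is seed-independent.

    Returns (system, reference_bound_positions).
    """
    if n_site < 4:
        raise ConfigurationError("n_site must be ≥ 4")
    if guest_charge not in (2, 3):
        raise ConfigurationError("guest_charge must be 2 or 3")
    if arm_length < 1:
        raise ConfigurationError("arm_length must be ≥ 1")
    rng = np.random.default_rng(seed)

    pos, chg, eps, sig, mass, roles = [], [], [], [], [], []

    def add(p, q, e, s, m, role):
        pos.append(p)
        chg.append(q)
        eps.append(e)
        sig.append(s)
        mass.append(m)
        roles.append(role)

    r_ring = 4.0
    for k in range(n_site):
        th = 2 * np.pi * k / n_site
        add([r_ring * np.cos(th), r_ring * np.sin(th), 0.0],
            -1.0, 0.15, 3.2, 30.0, "site")
    for k in range(n_site):
        th = 2 * np.pi * (k + 0.5) / n_site
        add([r_ring * np.cos(th), r_ring * np.sin(th), -2.5],
            -1.0, 0.15, 3.2, 30.0, "host")
    # three divalent ions at the back of the cavity
    for k in range(3):
        th = 2 * np.pi * k / 3
        add([1.6 * np.cos(th), 1.6 * np.sin(th), -3.5],
            2.0, 0.1, 2.2, 24.0, "ion")

    n_env = len(pos)
    # guest: scaffold bead + two bonded arms pointing up and outward
    i_scaffold = n_env
    tip_charge = (guest_charge - 1.0) / 2.0
    add([0.0, 0.0, -0.3], 1.0, 0.25, 3.5, 40.0, "ligand")
    bonds, angles = [], []
    arm_dirs = [np.array([0.6, 0.0, 0.8]), np.array([-0.6, 0.0, 0.8])]
    for arm, u in enumerate(arm_dirs):
        u = u / np.linalg.norm(u)
        prev = i_scaffold
        for k in range(arm_length):
            idx = len(pos)
            q = tip_charge if k == arm_length - 1 else 0.0
            add(np.array(pos[i_scaffold]) + (k + 1) * 1.5 * u,
                q, 0.12, 3.0, 14.0, "ligand")
            bonds.append(HarmonicBond(prev, idx, k=150.0, r0=1.5))
            prev = idx
    # straightening angles along each arm, anchored at the scaffold
    for arm in range(2):
        base = i_scaffold + 1 + arm * arm_length
        chain = [i_scaffold] + list(range(base, base + arm_length))
        for a, b, c in zip(chain, chain[1:], chain[2:]):
            angles.append(HarmonicAngle(a, b, c, k_theta=8.0, theta0=np.pi))

    if add_counterions:
        # neutralising bath beads far from the pocket ("physiological"
        # concept flag; no realism claimed)
        net = sum(chg)
        n_ci = int(round(abs(net)))
        qi = -np.sign(net)
        for k in range(n_ci):
            th = 2 * np.pi * k / max(n_ci, 1)
            add([18.0 * np.cos(th), 18.0 * np.sin(th), 6.0],
                qi, 0.1, 2.5, 23.0, "bath")

    positions = np.asarray(pos, dtype=float)
    positions += 0.02 * rng.standard_normal(positions.shape)

    exclusions = {frozenset((b.i, b.j)) for b in bonds}
    for a in angles:
        exclusions.add(frozenset((a.i, a.k)))
    # structural ions: mutual repulsion screened out (they are held by the
    # pocket field, not by each other)
    ion_idx = [k for k, r in enumerate(roles) if r == "ion"]
    for a_i in ion_idx:
        for b_i in ion_idx:
            if a_i < b_i:
                exclusions.add(frozenset((a_i, b_i)))

    roles_arr = np.asarray(roles, dtype=object)
    system = ParticleSystem(
        positions=positions,
        masses=np.asarray(mass),
        charges=np.asarray(chg),
        lj_epsilon=np.asarray(eps),
        lj_sigma=np.asarray(sig),
        roles=roles_arr,
        bonds=bonds,
        angles=angles,
        exclusions=exclusions,
        frozen=np.isin(roles_arr, ("host", "site")),
        dielectric=10.0,
    )
    _relax_mobile(system)
    return system, system.positions.copy()


def make_mini_complex_fixture(seed: int = 0):
    """Frozen 4-bead pocket plus a one-bead cationic ligand (3 DOF).

    Small enough that the binding free energy can be cross-checked by
    direct numerical integration of the configuration integral.

    Returns (system, reference_bound_positions).
    """
    rng = np.random.default_rng(seed)
    host = np.array([
        [2.6, 0.0, -1.0],
        [-1.3, 2.25, -1.0],
        [-1.3, -2.25, -1.0],
        [0.0, 0.0, -2.8],
    ])
    host = host + 0.01 * rng.standard_normal(host.shape)
    pos = np.vstack([host, [[0.0, 0.0, 0.2]]])
    system = ParticleSystem(
        positions=pos,
        masses=np.array([30.0] * 4 + [20.0]),
        charges=np.array([-0.35] * 4 + [1.0]),
        lj_epsilon=np.array([0.15] * 4 + [0.2]),
        lj_sigma=np.array([3.0] * 4 + [3.0]),
        roles=np.asarray(["site"] * 4 + ["ligand"], dtype=object),
        frozen=np.array([True] * 4 + [False]),
        dielectric=10.0,
    )
    _relax_mobile(system)
    return system, system.positions.copy()


def ligand_only_system(system: ParticleSystem) -> ParticleSystem:
    """Extract the ligand particles as a standalone (solvent-phase) system.

    With no explicit solvent particles the bulk phase contains only the
    ligand itself; its decoupling legs then measure exactly the removal of
    ligand–environment terms, which is the quantity the cycle needs.
    """
    idx = np.where(system.ligand)[0]
    remap = {int(old): new for new, old in enumerate(idx)}
    bonds = [HarmonicBond(remap[b.i], remap[b.j], b.k, b.r0)
             for b in system.bonds if b.i in remap and b.j in remap]
    angles = [HarmonicAngle(remap[a.i], remap[a.j], remap[a.k],
                            a.k_theta, a.theta0)
              for a in system.angles
              if a.i in remap and a.j in remap and a.k in remap]
    exclusions = {frozenset((remap[i], remap[j]))
                  for pair in system.exclusions
                  for i, j in [tuple(pair)]
                  if i in remap and j in remap}
    return ParticleSystem(
        positions=system.positions[idx].copy(),
        masses=system.masses[idx].copy(),
        charges=system.charges[idx].copy(),
        lj_epsilon=system.lj_epsilon[idx].copy(),
        lj_sigma=system.lj_sigma[idx].copy(),
        roles=system.roles[idx].copy(),
        bonds=bonds,
        angles=angles,
        exclusions=exclusions,
        frozen=system.frozen[idx].copy(),
        dielectric=system.dielectric,
    )


def make_two_particle_fixture(well_depth: float = 2.0, sigma: float = 3.0,
                              charge: float = 0.5):
    """One frozen host bead at the origin plus one mobile ligand bead.

    The pair interaction (LJ depth ``well_depth`` via ε, plus opposite
    charges ±``charge``) is the complete ligand–environment coupling, so
    the decoupling free energy has a one-dimensional radial closed form.
    """
    pos = np.array([[0.0, 0.0, 0.0], [sigma * 2 ** (1 / 6), 0.0, 0.0]])
    system = ParticleSystem(
        positions=pos,
        masses=np.array([40.0, 20.0]),
        charges=np.array([-charge, charge]),
        lj_epsilon=np.array([well_depth, well_depth]),
        lj_sigma=np.array([sigma, sigma]),
        roles=np.asarray(["site", "ligand"], dtype=object),
        frozen=np.array([True, False]),
        dielectric=10.0,
    )
    return system, pos.copy()
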