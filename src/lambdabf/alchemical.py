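"""lambda-ABF alchemical decoupling.

The alchemical coupling parameter λ is treated as a dynamical variable
with a fictitious mass, thermostatted at the system temperature and
confined to [0, 1] by reflective walls. An adaptive biasing force (ABF)
estimate of the mean force ⟨∂U/∂λ⟩, accumulated on a λ grid and shared by
several concurrent walkers, is applied as an opposing force so λ diffuses
freely along the whole alchemical path — no fixed λ schedule and no
post-processing estimator are needed; the free-energy profile is the
integral of the accumulated mean force.

Ligand–environment van der Waals interactions are scaled through a
Beutler-style r⁶ soft core (finite at particle overlap for intermediate
λ), electrostatics linearly. The two interactions are decoupled
sequentially in separate legs: the electrostatic (ELE) leg discharges the
ligand at full vdW coupling, then the vdW (VDW) leg removes the remaining
dispersion-repulsion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .systems import (LangevinSettings, ParticleSystem, _bonded_energy_forces,
                      maxwell_boltzmann_velocities)
from .units import KB, MASS_ENERGY

LEGS = ("ELE", "VDW")
PHASES = ("complex", "solvent")


class SamplingWarning(UserWarning):
    pass


class IncompleteSamplingError(RuntimeError):
    """λ bins never visited; the profile cannot be integrated."""


@dataclass
class SoftcoreParams:
    """Soft-core scaling of ligand–environment nonbonded terms.

    LJ: U(λ) = λ^vdw_power · 4ε [D⁻² − D⁻¹], D = α(1−λ) + (r/σ)⁶.
    Coulomb: U(λ) = λ^ele_power · C·q_iq_j/r.
    The exact functional form used by production engines is not unique;
    these choices are standard and recorded in output metadata.
    """

    alpha: float = 0.5
    vdw_power: int = 1
    ele_power: int = 1

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be ≥ 0")
        if self.vdw_power < 1 or self.ele_power < 1:
            raise ValueError("coupling powers must be ≥ 1")


def _check_lambda(value: float, name: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return float(value)


def _scaled_terms(system: ParticleSystem, positions: np.ndarray,
                  lambda_vdw: float, lambda_ele: float, sc: SoftcoreParams):
    """Energy, forces and both λ-gradients of the scaled nonbonded terms."""
    t = system.pair_tables()
    d = positions[t.jj] - positions[t.ii]
    r2 = np.einsum("ij,ij->i", d, d)
    r2 = np.maximum(r2, 1e-12)
    r = np.sqrt(r2)
    inv_r2 = 1.0 / r2

    env = ~t.lig_env
    # untouched pairs: plain LJ + Coulomb (env–env and intra-ligand)
    sr6 = (t.sig ** 2 * inv_r2) ** 3
    e_plain = np.sum(4.0 * t.eps[env] * (sr6[env] ** 2 - sr6[env])
                     + t.qq[env] / r[env])
    dudr_over_r = np.zeros_like(r)
    dudr_over_r[env] = (4.0 * t.eps[env]
                        * (-12.0 * sr6[env] ** 2 + 6.0 * sr6[env])
                        * inv_r2[env]
                        - t.qq[env] / (r2[env] * r[env]))

    # ligand–environment: soft-core LJ + linearly scaled Coulomb
    le = t.lig_env
    lam_v = lambda_vdw ** sc.vdw_power
    dlam_v = sc.vdw_power * lambda_vdw ** (sc.vdw_power - 1)
    lam_e = lambda_ele ** sc.ele_power
    dlam_e = sc.ele_power * lambda_ele ** (sc.ele_power - 1)

    x6 = (r2[le] / t.sig[le] ** 2) ** 3          # (r/σ)⁶
    dd = sc.alpha * (1.0 - lambda_vdw) + x6
    inv_d = 1.0 / dd
    lj_core = 4.0 * t.eps[le] * (inv_d ** 2 - inv_d)
    e_lj = lam_v * np.sum(lj_core)
    e_c = lam_e * np.sum(t.qq[le] / r[le])

    # dU/dr for lig–env pairs (divided by r)
    dcore_dD = 4.0 * t.eps[le] * (-2.0 * inv_d ** 3 + inv_d ** 2)
    dD_dr2 = 3.0 * x6 / r2[le]                   # d[(r/σ)⁶]/d(r²)·... = 3x6/r²
    dudr_over_r[le] = (lam_v * dcore_dD * dD_dr2 * 2.0
                       - lam_e * t.qq[le] / (r2[le] * r[le]))

    du_dlam_v = (dlam_v * np.sum(lj_core)
                 - lam_v * sc.alpha * np.sum(dcore_dD))
    du_dlam_e = dlam_e * np.sum(t.qq[le] / r[le])

    pair_f = dudr_over_r[:, None] * d
    f = np.zeros_like(positions)
    np.add.at(f, t.jj, -pair_f)
    np.add.at(f, t.ii, pair_f)
    energy = float(e_plain + e_lj + e_c)
    return energy, f, float(du_dlam_v), float(du_dlam_e)


def scaled_nonbonded_energy(system: ParticleSystem, lambda_vdw: float,
                            lambda_ele: float,
                            sc: SoftcoreParams | None = None,
                            positions: np.ndarray | None = None) -> float:
    """Nonbonded energy with ligand–environment terms scaled by λ.

    (1, 1) reproduces the unscaled nonbonded energy exactly; (0, 0) equals
    the energy with all ligand–environment terms deleted. Intra-ligand and
    environment–environment terms are never scaled.
    """
    sc = sc or SoftcoreParams()
    _check_lambda(lambda_vdw, "lambda_vdw")
    _check_lambda(lambda_ele, "lambda_ele")
    if positions is None:
        positions = system.positions
    e, _, _, _ = _scaled_terms(system, positions, lambda_vdw, lambda_ele, sc)
    return e


def lambda_gradient(system: ParticleSystem, lambda_vdw: float,
                    lambda_ele: float, leg: str,
                    sc: SoftcoreParams | None = None,
                    positions: np.ndarray | None = None) -> float:
    """Instantaneous ∂U/∂λ of the active leg (kcal/mol)."""
    if leg not in LEGS:
        raise ValueError(f"leg must be one of {LEGS}")
    sc = sc or SoftcoreParams()
    _check_lambda(lambda_vdw, "lambda_vdw")
    _check_lambda(lambda_ele, "lambda_ele")
    if positions is None:
        positions = system.positions
    _, _, gv, ge = _scaled_terms(system, positions, lambda_vdw, lambda_ele, sc)
    return gv if leg == "VDW" else ge


@dataclass
class LambdaState:
    """Dynamical λ with fictitious inertia and reflective bounds."""

    value: float = 1.0
    mass: float = 20.0              # amu·Å²-equivalent
    velocity: float = 0.0
    bounds: tuple[float, float] = (0.0, 1.0)

    def reflect(self) -> None:
        lo, hi = self.bounds
        if self.value < lo:
            self.value = 2 * lo - self.value
            self.velocity = -self.velocity
        elif self.value > hi:
            self.value = 2 * hi - self.value
            self.velocity = -self.velocity
        self.value = min(max(self.value, lo), hi)


@dataclass
class AbfAccumulator:
    """Shared per-bin mean-force statistics for the ABF bias.

    The applied bias is the per-bin average ∂U/∂λ scaled by the linear
    ramp min(1, count/n_full), so it can never exceed the current
    mean-force estimate in magnitude.
    """

    n_bins: int = 100
    n_full: int = 200
    sums: np.ndarray = None
    counts: np.ndarray = None

    def __post_init__(self) -> None:
        if self.sums is None:
            self.sums = np.zeros(self.n_bins)
        if self.counts is None:
            self.counts = np.zeros(self.n_bins, dtype=np.int64)

    def bin_index(self, lam: float) -> int:
        return min(int(lam * self.n_bins), self.n_bins - 1)

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) / self.n_bins

    def mean_force(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.counts > 0, self.sums /
                            np.maximum(self.counts, 1), 0.0)

    def bias_force(self, lam: float) -> float:
        """Opposing force applied to λ (cancels the estimated mean force)."""
        b = self.bin_index(lam)
        c = self.counts[b]
        if c == 0:
            return 0.0
        ramp = min(1.0, c / self.n_full)
        return ramp * self.sums[b] / c

    def deposit(self, lam: float, du_dlam: float) -> None:
        b = self.bin_index(lam)
        self.sums[b] += du_dlam
        self.counts[b] += 1

    def merge(self, other: "AbfAccumulator") -> None:
        self.sums += other.sums
        self.counts += other.counts


@dataclass
class FreeEnergyProfile:
    """Integrated alchemical free-energy profile A(λ), A(0) = 0."""

    lambda_centers: np.ndarray
    mean_force: np.ndarray
    counts: np.ndarray
    n_walkers: int
    leg: str
    phase: str
    temperature: float
    direction: str = "couple"       # sign convention of delta_g()
    metadata: dict = field(default_factory=dict)

    @property
    def free_energy(self) -> np.ndarray:
        """A at the bin centers, A(0) ≡ 0 (piecewise-constant mean force)."""
        dl = 1.0 / len(self.lambda_centers)
        a = np.cumsum(self.mean_force) * dl - 0.5 * self.mean_force * dl
        return a

    def write_columns(self, path) -> None:
        data = np.column_stack([self.lambda_centers, self.mean_force,
                                self.free_energy, self.counts])
        header = (f"leg={self.leg} phase={self.phase} "
                  f"T={self.temperature} walkers={self.n_walkers} "
                  f"direction={self.direction}\n"
                  "lambda mean_force free_energy count")
        np.savetxt(path, data, header=header)

    @classmethod
    def read_columns(cls, path) -> "FreeEnergyProfile":
        meta = {}
        with open(path) as fh:
            first = fh.readline().lstrip("# ").strip()
        for tok in first.split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
        data = np.loadtxt(path)
        return cls(lambda_centers=data[:, 0], mean_force=data[:, 1],
                   counts=data[:, 3],
                   n_walkers=int(meta.get("walkers", 1)),
                   leg=meta.get("leg", "VDW"),
                   phase=meta.get("phase", "complex"),
                   temperature=float(meta.get("T", 300.0)),
                   direction=meta.get("direction", "couple"))


def integrate_profile(profile: FreeEnergyProfile) -> float:
    """Leg free energy ΔG (kcal/mol) in the direction of the leg.

    Integral of the mean force over λ ∈ [0, 1]; for ``direction ==
    "decouple"`` the sign is flipped (ΔG of going λ: 1 → 0).
    """
    unvisited = np.where(profile.counts == 0)[0]
    if len(unvisited):
        raise IncompleteSamplingError(
            f"unvisited λ bins: {unvisited.tolist()}")
    dl = 1.0 / len(profile.lambda_centers)
    dg = float(np.sum(profile.mean_force) * dl)
    return -dg if profile.direction == "decouple" else dg


def run_lambda_abf(system: ParticleSystem, leg: str, n_walkers: int,
                   settings: LangevinSettings, abf: AbfAccumulator,
                   restraints=(), sc: SoftcoreParams | None = None,
                   phase: str = "complex",
                   lambda_state: LambdaState | None = None,
                   lambda_friction: float | None = None,
                   sync_interval: int = 500) -> FreeEnergyProfile:
    """Multiple-walker lambda-ABF run for one decoupling leg.

    Each walker propagates the particles (BAOAB Langevin) together with
    its own dynamical λ starting from the coupled end (λ = 1). The
    instantaneous ∂U/∂λ is accumulated into the shared λ-grid; the
    opposing ramped mean force is applied to λ. Walker-local statistics
    merge into the shared accumulator every ``sync_interval`` steps.

    During the ELE leg λ_vdw is held at 1; during the VDW leg λ_ele is 0.
    ``settings.n_steps`` is the per-walker step count.
    """
    if leg not in LEGS:
        raise ValueError(f"leg must be one of {LEGS}")
    if n_walkers < 1:
        raise ValueError("need at least one walker")
    sc = sc or SoftcoreParams()
    lambda_state = lambda_state or LambdaState()
    dt = settings.timestep
    gamma_dt = (lambda_friction if lambda_friction is not None
                else settings.friction) * dt * 1e-3
    c1_l = np.exp(-gamma_dt)
    c2_l = np.sqrt(max(0.0, 1.0 - c1_l * c1_l))
    kbt = KB * settings.temperature
    sig_vl = np.sqrt(kbt / (lambda_state.mass * MASS_ENERGY))
    inv_ml = 1.0 / (lambda_state.mass * MASS_ENERGY)

    free = ~system.frozen
    inv_m = 1.0 / (system.masses[:, None] * MASS_ENERGY)
    inv_m[system.frozen] = 0.0
    gamma_dt_p = settings.friction * dt * 1e-3
    c1 = np.exp(-gamma_dt_p)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    sig_v = np.sqrt(kbt / (system.masses * MASS_ENERGY))[:, None]

    seeds = np.random.SeedSequence(settings.seed).spawn(n_walkers)
    walkers = []
    for w in range(n_walkers):
        rng = np.random.default_rng(seeds[w])
        pos = system.positions.copy()
        vel = maxwell_boltzmann_velocities(system, settings.temperature, rng)
        lam = LambdaState(value=lambda_state.value, mass=lambda_state.mass,
                          velocity=float(rng.standard_normal()) * sig_vl,
                          bounds=lambda_state.bounds)
        walkers.append({"rng": rng, "pos": pos, "vel": vel, "lam": lam})

    def lambdas(lam_val: float):
        if leg == "ELE":
            return 1.0, lam_val
        return lam_val, 0.0

    def eval_state(pos, lam_val):
        lv, le = lambdas(lam_val)
        e, f, gv, ge = _scaled_terms(system, pos, lv, le, sc)
        eb, fb = _bonded_energy_forces(system, pos)
        e += eb
        f = f + fb
        for att in restraints:
            ea, fa = att.energy_forces(pos)
            e += ea
            f += fa
        g = gv if leg == "VDW" else ge
        return e, f, g

    boundary_hits = 0
    total_steps = 0
    n_chunks = max(1, int(np.ceil(settings.n_steps / sync_interval)))
    for chunk in range(n_chunks):
        steps = min(sync_interval, settings.n_steps - chunk * sync_interval)
        if steps <= 0:
            break
        for wk in walkers:
            local = AbfAccumulator(n_bins=abf.n_bins, n_full=abf.n_full)
            pos, vel, lam, rng = wk["pos"], wk["vel"], wk["lam"], wk["rng"]
            e, f, g = eval_state(pos, lam.value)
            for _ in range(steps):
                total_steps += 1
                # deposit instantaneous force; bias from shared + local
                local.deposit(lam.value, g)
                b = abf.bin_index(lam.value)
                c = abf.counts[b] + local.counts[b]
                ramp = min(1.0, c / abf.n_full) if c else 0.0
                mean = ((abf.sums[b] + local.sums[b]) / c) if c else 0.0
                f_lambda = -g + ramp * mean

                # B (half kick)
                vel += 0.5 * dt * f * inv_m
                lam.velocity += 0.5 * dt * f_lambda * inv_ml
                # A (half drift)
                pos[free] += 0.5 * dt * vel[free]
                lam.value += 0.5 * dt * lam.velocity
                lam.reflect()
                # O
                noise = rng.standard_normal(pos.shape)
                vel[free] = c1 * vel[free] + c2 * sig_v[free] * noise[free]
                lam.velocity = (c1_l * lam.velocity
                                + c2_l * sig_vl * rng.standard_normal())
                # A
                pos[free] += 0.5 * dt * vel[free]
                lam.value += 0.5 * dt * lam.velocity
                lam.reflect()
                edge = 0.5 / abf.n_bins
                if (lam.value - lam.bounds[0] < edge
                        or lam.bounds[1] - lam.value < edge):
                    boundary_hits += 1
                # B with refreshed forces
                e, f, g = eval_state(pos, lam.value)
                f_lambda = -g + abf.bias_force(lam.value)
                vel += 0.5 * dt * f * inv_m
                lam.velocity += 0.5 * dt * f_lambda * inv_ml
            abf.merge(local)

    if total_steps and boundary_hits / total_steps > 0.5:
        warnings.warn(
            "λ spent more than half of all steps pinned at a reflective "
            "bound; sampling is likely pathological", SamplingWarning)

    return FreeEnergyProfile(
        lambda_centers=abf.centers,
        mean_force=abf.mean_force(),
        counts=abf.counts.copy(),
        n_walkers=n_walkers,
        leg=leg, phase=phase,
        temperature=settings.temperature,
        direction="decouple",
        metadata={"softcore": sc.__dict__.copy(),
                  "lambda_mass": lambda_state.mass},
    )


@dataclass
class AbfeResult:
    """Assembled raw absolute binding free energy and its components.

    ``delta_g_raw`` is the raw computed ΔG of the thermodynamic cycle
    (before any Apo–Holo calibration shift); more favourable binding is
    more negative. Components are stored signed so that their sum equals
    the total exactly.
    """

    components: dict[str, float]
    delta_g_raw: float
    temperature: float
    replica: int = 0

    def audit_sum(self) -> float:
        return float(sum(self.components.values()))


def assemble_abfe(complex_legs: dict[str, float],
                  solvent_legs: dict[str, float],
                  dbc_release: float,
                  standard_state: float,
                  temperature: float = 300.0,
                  replica: int = 0,
                  leg_temperatures: dict[str, float] | None = None
                  ) -> AbfeResult:
    """Close the double-decoupling thermodynamic cycle.

    ``complex_legs`` / ``solvent_legs`` map leg name (ELE, VDW) to the
    *decoupling* free energy of that leg and phase. ``dbc_release`` is the
    gas-phase TI result oriented DBC → harmonic; ``standard_state`` the
    analytic harmonic ↔ 1 M volume term as returned by
    :func:`lambdabf.restraints.standard_state_correction`. The raw binding
    free energy is

        ΔG_raw = Σ ΔG_dec^solv − Σ ΔG_dec^cplx − ΔG_DBC→harm + ΔG_std

    which telescopes to −k_B T ln(Z_bound/V°) for a one-bead ligand.
    """
    if leg_temperatures:
        temps = set(round(t, 6) for t in leg_temperatures.values())
        temps.add(round(temperature, 6))
        if len(temps) > 1:
            raise ValueError(f"inconsistent leg temperatures: {sorted(temps)}")
    components = {}
    for name, dg in solvent_legs.items():
        components[f"solvent_{name}"] = float(dg)
    for name, dg in complex_legs.items():
        components[f"complex_{name}"] = -float(dg)
    components["dbc_to_harmonic"] = -float(dbc_release)
    components["standard_state"] = float(standard_state)
    total = float(sum(components.values()))
    return AbfeResult(components=components, delta_g_raw=total,
                      temperature=temperature, replica=replica)
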