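"""On-the-fly probability enhanced sampling (OPES) along a collective variable.

Gaussian kernels deposited at the visited CV values reconstruct the
well-tempered target distribution p^tg(s) ∝ [P(s)]^{1/γ}; the bias applied
to the system is

    V(s) = (1 − 1/γ)·k_B·T·log(p^tg(s)/Z + ε)

with normalization Z computed on a grid over the explored CV interval and
the regularization ε = exp(−ΔE/(k_B·T·(1 − 1/γ))). The barrier parameter
ΔE caps the maximum bias the method can deposit (far from all kernels the
bias tends to −ΔE, so max V − min V ≤ ΔE), and the bias factor is
typically chosen as γ = ΔE/(k_B·T).

Only the fixed-bandwidth estimate above is implemented; the adaptive
bandwidth-shrinking refinements of the exploratory variant are not
reproduced. Kernels are isotropic; 1D and 2D CVs are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .systems import (IntegrationError, LangevinSettings, ParticleSystem,
                      Trajectory, maxwell_boltzmann_velocities,
                      total_energy_forces)
from .units import KB, MASS_ENERGY


def opes_epsilon(delta_e: float, temperature: float, gamma: float) -> float:
    """Regularization ε = exp(−ΔE/(k_B·T·(1−1/γ)))."""
    if gamma <= 1.0:
        raise ValueError("bias factor γ must be > 1")
    if delta_e <= 0.0:
        raise ValueError("barrier parameter ΔE must be > 0")
    return float(np.exp(-delta_e / (KB * temperature * (1.0 - 1.0 / gamma))))


def gamma_from_barrier(delta_e: float, temperature: float) -> float:
    """Default bias factor γ = ΔE/(k_B·T)."""
    return delta_e / (KB * temperature)


@dataclass
class OpesKernel:
    center: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        if self.sigma <= 0:
            raise ValueError("kernel width σ must be > 0")


class OpesBias:
    """Kernel list plus (γ, ΔE, ε, Z, T) defining the OPES bias potential."""

    def __init__(self, sigma: float, barrier: float,
                 temperature: float = 300.0, gamma: float | None = None,
                 pace: int = 500, grid_points: int = 1001, ndim: int = 1):
        if ndim not in (1, 2):
            raise ValueError("only 1D and 2D CVs are supported")
        self.sigma = float(sigma)
        self.barrier = float(barrier)
        self.temperature = float(temperature)
        self.gamma = float(gamma) if gamma is not None else max(
            gamma_from_barrier(barrier, temperature), 1.0 + 1e-9)
        if self.gamma <= 1.0:
            raise ValueError("bias factor γ must be > 1")
        self.pace = int(pace)
        self.grid_points = int(grid_points)
        self.ndim = ndim
        self.centers = np.empty((0, ndim))
        self.z = 1.0

    @property
    def epsilon(self) -> float:
        return opes_epsilon(self.barrier, self.temperature, self.gamma)

    @property
    def prefactor(self) -> float:
        return (1.0 - 1.0 / self.gamma) * KB * self.temperature

    @property
    def n_kernels(self) -> int:
        return len(self.centers)

    @property
    def kernels(self) -> list[OpesKernel]:
        return [OpesKernel(c, self.sigma) for c in self.centers]

    # -- target-distribution estimate --------------------------------------

    def _norm(self) -> float:
        return (1.0 / (self.sigma * np.sqrt(2.0 * np.pi))) ** self.ndim

    def p_tg(self, s) -> np.ndarray:
        """Kernel estimate p^tg(s) = (1/n)·Σ_k G_k(s, s_k)."""
        s = np.atleast_2d(np.asarray(s, dtype=float))
        if s.shape[1] != self.ndim:
            s = s.reshape(-1, self.ndim)
        if self.n_kernels == 0:
            return np.zeros(len(s))
        d2 = ((s[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        g = self._norm() * np.exp(-0.5 * d2 / self.sigma ** 2)
        return g.mean(axis=1)

    def _grid(self) -> np.ndarray:
        lo = self.centers.min(axis=0) - 5 * self.sigma
        hi = self.centers.max(axis=0) + 5 * self.sigma
        if self.ndim == 1:
            return np.linspace(lo[0], hi[0], self.grid_points)[:, None]
        n = max(int(np.sqrt(self.grid_points)), 51)
        axes = [np.linspace(lo[d], hi[d], n) for d in range(2)]
        gx, gy = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    def update(self, s_new) -> None:
        """Deposit a kernel at the current CV value and refresh Z.

        Z is the average of p^tg over the explored CV interval, evaluated
        by trapezoidal quadrature on the internal grid, so the grid
        average of p^tg/Z is exactly one.
        """
        s_new = np.atleast_1d(np.asarray(s_new, dtype=float))
        self.centers = np.vstack([self.centers, s_new[None, :]])
        grid = self._grid()
        p = self.p_tg(grid)
        if self.ndim == 1:
            x = grid[:, 0]
            self.z = float(np.trapezoid(p, x) / (x[-1] - x[0]))
        else:
            self.z = float(np.mean(p))

    # -- bias potential -----------------------------------------------------

    def energy(self, s) -> float:
        """V(s) (kcal/mol)."""
        if self.n_kernels == 0:
            return 0.0
        p = float(self.p_tg(s)[0])
        return self.prefactor * np.log(p / self.z + self.epsilon)

    def gradient(self, s) -> np.ndarray:
        """dV/ds (kcal/mol per CV unit)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if self.n_kernels == 0:
            return np.zeros(self.ndim)
        d = s[None, :] - self.centers                   # (n, ndim)
        d2 = (d ** 2).sum(axis=1)
        g = self._norm() * np.exp(-0.5 * d2 / self.sigma ** 2)
        p = g.mean()
        dp = -(g[:, None] * d / self.sigma ** 2).mean(axis=0)
        return self.prefactor * dp / self.z / (p / self.z + self.epsilon)

    def write_kernels(self, path) -> None:
        cols = [np.arange(self.n_kernels)] + [
            self.centers[:, d] for d in range(self.ndim)]
        cols.append(np.full(self.n_kernels, self.sigma))
        header = ("index " + " ".join(f"center_{d}"
                                      for d in range(self.ndim)) + " sigma")
        np.savetxt(path, np.column_stack(cols), header=header)


def opes_update(bias: OpesBias, s_new) -> OpesBias:
    """Functional wrapper around :meth:`OpesBias.update`."""
    bias.update(s_new)
    return bias


def opes_bias_energy(bias: OpesBias, s) -> float:
    return bias.energy(s)


def run_opes(system: ParticleSystem, cv, bias: OpesBias,
             settings: LangevinSettings, attachments=(),
             deposit_until: int | None = None):
    """Biased BAOAB Langevin run depositing OPES kernels every ``pace`` steps.

    ``cv`` must expose ``value(positions) -> float | 1D array`` and
    ``gradient(positions) -> (ndim, N, 3)`` (or (N, 3) for a 1D CV).
    Returns (Trajectory, OpesBias); the trajectory records the CV value
    and the instantaneous bias energy per saved frame.

    ``deposit_until`` stops kernel deposition after that step while the
    (then static) bias keeps acting — the tail of the run is sampled
    under a strictly stationary bias, which makes reweighting of that
    segment exact.
    """
    rng = np.random.default_rng(settings.seed)
    pos = system.positions.copy()
    free = ~system.frozen
    vel = maxwell_boltzmann_velocities(system, settings.temperature, rng)
    dt = settings.timestep
    inv_m = 1.0 / (system.masses[:, None] * MASS_ENERGY)
    inv_m[system.frozen] = 0.0
    gamma_dt = settings.friction * dt * 1e-3
    c1 = np.exp(-gamma_dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    sig_v = np.sqrt(KB * settings.temperature
                    / (system.masses * MASS_ENERGY))[:, None]

    def cv_value(p) -> np.ndarray:
        v = np.atleast_1d(np.asarray(cv.value(p), dtype=float))
        if not np.all(np.isfinite(v)):
            raise IntegrationError("collective variable returned non-finite "
                                   "value")
        return v

    def bias_forces(p, s):
        if bias.n_kernels == 0:
            return np.zeros_like(p)
        dv = bias.gradient(s)                  # (ndim,)
        grad = np.asarray(cv.gradient(p))      # (ndim, N, 3) or (N, 3)
        if grad.ndim == 2:
            grad = grad[None, :, :]
        return -np.tensordot(dv, grad, axes=(0, 0))

    def forces_at(p, s):
        e, f = total_energy_forces(system, p, attachments)
        if not np.isfinite(e) or abs(e) > 1e8:
            raise IntegrationError(f"energy diverged: E={e}")
        return f + bias_forces(p, s)

    s = cv_value(pos)
    f = forces_at(pos, s)
    times, frames = [], []
    series = {"cv": [], "bias_energy": [], "temperature": []}
    if bias.ndim == 2:
        series["cv2"] = []

    def record(step):
        times.append(step * dt * 1e-3)
        frames.append(pos.copy())
        series["cv"].append(float(s[0]))
        if bias.ndim == 2:
            series["cv2"].append(float(s[1]))
        series["bias_energy"].append(bias.energy(s))
        ke = 0.5 * MASS_ENERGY * float(
            np.sum(system.masses[free, None] * vel[free] ** 2))
        series["temperature"].append(
            2 * ke / (3 * int(np.sum(free)) * KB))

    record(0)
    for step in range(1, settings.n_steps + 1):
        vel += 0.5 * dt * f * inv_m
        pos[free] += 0.5 * dt * vel[free]
        noise = rng.standard_normal(pos.shape)
        vel[free] = c1 * vel[free] + c2 * sig_v[free] * noise[free]
        pos[free] += 0.5 * dt * vel[free]
        s = cv_value(pos)
        if step % bias.pace == 0 and (deposit_until is None
                                      or step <= deposit_until):
            bias.update(s)
        f = forces_at(pos, s)
        vel += 0.5 * dt * f * inv_m
        if step % settings.save_stride == 0:
            record(step)

    traj = Trajectory(times=np.asarray(times), positions=np.asarray(frames),
                      scalars={k: np.asarray(v) for k, v in series.items()})
    return traj, bias


def reweight(trajectory: Trajectory, bias: OpesBias, bins: int = 60,
             range_: tuple[float, float] | None = None,
             discard_fraction: float = 0.2):
    """Importance-reweighted unbiased CV histogram and free-energy profile.

    Frames are weighted by exp(+V(s_t)/k_B·T) under the *final* bias (the
    bias must be quasi-stationary over the reweighted window; the leading
    ``discard_fraction`` of frames is dropped). Returns (centers, density,
    free_energy) with the density normalized to unit integral and the
    free-energy minimum shifted to zero.
    """
    import warnings as _warnings

    s = trajectory.scalars["cv"]
    n0 = int(len(s) * discard_fraction)
    s = s[n0:]
    kbt = KB * bias.temperature
    if bias.ndim == 2:
        s2 = trajectory.scalars["cv2"][n0:]
        pts = np.column_stack([s, s2])
    else:
        pts = s[:, None]
    v = bias.prefactor * np.log(bias.p_tg(pts) / bias.z + bias.epsilon)
    w = np.exp((v - v.max()) / kbt)
    ess = w.sum() ** 2 / np.sum(w ** 2)
    if ess < 10:
        _warnings.warn(f"effective sample size {ess:.1f} < 10; reweighted "
                       "estimate unreliable")
    if range_ is None:
        range_ = (float(s.min()), float(s.max()))
    hist, edges = np.histogram(s, bins=bins, range=range_, weights=w)
    centers = 0.5 * (edges[1:] + edges[:-1])
    width = edges[1] - edges[0]
    density = hist / (hist.sum() * width)
    with np.errstate(divide="ignore"):
        fes = -kbt * np.log(density)
    fes -= fes[np.isfinite(fes)].min()
    return centers, density, fes


class AxisPositionCV:
    """CV: one Cartesian coordinate of one particle."""

    def __init__(self, particle: int = 0, axis: int = 0):
        self.particle = particle
        self.axis = axis

    def value(self, positions: np.ndarray) -> float:
        return float(positions[self.particle, self.axis])

    def gradient(self, positions: np.ndarray) -> np.ndarray:
        g = np.zeros_like(positions)
        g[self.particle, self.axis] = 1.0
        return g
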