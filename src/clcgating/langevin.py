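"""Overdamped 1-D Langevin surrogate dynamics on analytic barrier potentials.

Used to validate free-energy-profile barrier recovery: the potentials have
barriers known in closed form, and the long-time law of the overdamped
Euler-Maruyama chain is Boltzmann, so `-kT*ln(histogram)` must reproduce
the potential up to an additive constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KT_300K

try:  # tight integration loop; falls back to NumPy blocks without numba
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = ["DoubleWellPotential", "HarmonicPotential", "LangevinSpec",
           "sample_langevin"]


@dataclass(frozen=True)
class DoubleWellPotential:
    """Two-basin potential with exact, independently tunable barrier.

    Piecewise C^1 construction: a cubic smoothstep rises from the left
    minimum at x=-1 (energy 0) to the barrier top at x=0 (energy
    ``barrier``), a second smoothstep descends to the right minimum at
    x=+1 (energy ``delta_g``), and harmonic walls continue outside
    [-1, 1] with the curvature of the adjoining well.

    The barrier measured from the left basin is exactly ``barrier``; from
    the right basin it is ``barrier - delta_g``.
    """

    barrier: float  # kcal/mol, top relative to the left minimum
    delta_g: float = 0.0  # kcal/mol, right minimum relative to left

    def __post_init__(self):
        if self.barrier <= 0 or self.barrier <= self.delta_g:
            raise ValueError("barrier must exceed both basin energies")

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        H, D = self.barrier, self.delta_g
        u = np.empty_like(x)
        left_wall = x < -1
        right_wall = x > 1
        up = (~left_wall) & (x <= 0)
        down = (~right_wall) & (x > 0)
        u[left_wall] = 3 * H * (x[left_wall] + 1) ** 2
        t = x[up] + 1
        u[up] = H * (3 * t**2 - 2 * t**3)
        s = x[down]
        u[down] = H - (H - D) * (3 * s**2 - 2 * s**3)
        u[right_wall] = D + 3 * (H - D) * (x[right_wall] - 1) ** 2
        return u

    def force(self, x):
        x = np.asarray(x, dtype=float)
        H, D = self.barrier, self.delta_g
        f = np.empty_like(x)
        left_wall = x < -1
        right_wall = x > 1
        up = (~left_wall) & (x <= 0)
        down = (~right_wall) & (x > 0)
        f[left_wall] = -6 * H * (x[left_wall] + 1)
        t = x[up] + 1
        f[up] = -6 * H * (t - t**2)
        s = x[down]
        f[down] = 6 * (H - D) * (s - s**2)
        f[right_wall] = -6 * (H - D) * (x[right_wall] - 1)
        return f

    @property
    def minima(self) -> tuple[float, float]:
        return (-1.0, 1.0)

    @property
    def max_curvature(self) -> float:
        return 6 * self.barrier


@dataclass(frozen=True)
class HarmonicPotential:
    """U(x) = 0.5 * kappa * x^2; stationary variance is kT/kappa."""

    kappa: float

    def energy(self, x):
        return 0.5 * self.kappa * np.asarray(x, dtype=float) ** 2

    def force(self, x):
        return -self.kappa * np.asarray(x, dtype=float)

    @property
    def minima(self) -> tuple[float, ...]:
        return (0.0,)

    @property
    def max_curvature(self) -> float:
        return self.kappa


@dataclass(frozen=True)
class LangevinSpec:
    """Parameters of an overdamped Euler-Maruyama run.

    Stability requires ``diffusion * max_curvature / kT * timestep <= 0.2``
    (the deterministic relaxation per step stays well below the well
    width); a spec violating the bound is refused.
    """

    potential: object
    diffusion: float = 1.0
    timestep: float = 1e-3
    n_steps: int = 1_000_000
    kT: float = KT_300K
    x0: float | None = None
    seed: int = 0

    def stability_factor(self) -> float:
        return self.diffusion * self.potential.max_curvature / self.kT * self.timestep


if _HAVE_NUMBA:

    @njit(cache=True)
    def _run_doublewell(n, x0, H, D, a, sigma, noise_seed):  # pragma: no cover
        np.random.seed(noise_seed)
        out = np.empty(n)
        x = x0
        for i in range(n):
            if x < -1:
                f = -6 * H * (x + 1)
            elif x <= 0:
                t = x + 1
                f = -6 * H * (t - t * t)
            elif x <= 1:
                f = 6 * (H - D) * (x - x * x)
            else:
                f = -6 * (H - D) * (x - 1)
            x = x + a * f + sigma * np.random.normal()
            out[i] = x
        return out

    @njit(cache=True)
    def _run_harmonic(n, x0, kappa, a, sigma, noise_seed):  # pragma: no cover
        np.random.seed(noise_seed)
        out = np.empty(n)
        x = x0
        for i in range(n):
            x = x + a * (-kappa * x) + sigma * np.random.normal()
            out[i] = x
        return out


def _run_generic(spec: LangevinSpec, x0: float) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    a = spec.diffusion * spec.timestep / spec.kT
    sigma = np.sqrt(2 * spec.diffusion * spec.timestep)
    out = np.empty(spec.n_steps)
    x = np.array([x0])
    block = 100_000
    i = 0
    while i < spec.n_steps:
        m = min(block, spec.n_steps - i)
        noise = rng.standard_normal(m) * sigma
        for j in range(m):
            x = x + a * spec.potential.force(x) + noise[j]
            out[i + j] = x[0]
        i += m
    return out


def sample_langevin(spec: LangevinSpec) -> np.ndarray:
    """Integrate overdamped Langevin dynamics, returning the position series.

    x_{t+1} = x_t + (D/kT) F(x_t) dt + sqrt(2 D dt) xi_t.

    Raises
    ------
    ValueError
        If the Euler step is unstable for the potential's maximal
        curvature (``stability_factor > 0.2``).
    """
    sf = spec.stability_factor()
    if spec.diffusion > 0 and sf > 0.2:
        raise ValueError(
            f"unstable timestep: diffusion*max_curvature/kT*dt = {sf:.3f} "
            "exceeds the stability bound 0.2")
    x0 = spec.x0 if spec.x0 is not None else spec.potential.minima[0]
    if spec.diffusion == 0.0 and np.all(
            np.isclose(spec.potential.force(np.array([x0])), 0.0)):
        return np.full(spec.n_steps, float(x0))
    a = spec.diffusion * spec.timestep / spec.kT
    sigma = np.sqrt(2 * spec.diffusion * spec.timestep)
    # numba's legacy RNG takes 32-bit seeds
    noise_seed = int(np.uint32(spec.seed * 2654435761 % (2**32 - 1)))
    if _HAVE_NUMBA and isinstance(spec.potential, DoubleWellPotential):
        return _run_doublewell(spec.n_steps, float(x0), spec.potential.barrier,
                               spec.potential.delta_g, a, sigma, noise_seed)
    if _HAVE_NUMBA and isinstance(spec.potential, HarmonicPotential):
        return _run_harmonic(spec.n_steps, float(x0), spec.potential.kappa,
                             a, sigma, noise_seed)
    return _run_generic(spec, float(x0))
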