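"""Reference macrostate kinetics and exact continuous-time sampling.

The conformational cycle of the CLC-2 selectivity filter is represented as
a continuous-time Markov jump process over the macrostates C_oi, C_o, O
and (when the external-gate glutamate is protonated) U.  Basin free
energies and transition barriers parameterize an Arrhenius-type generator

    k_ij = nu * exp(-dG_ij^/kT),   nu = 1 per frame,

with every reverse rate fixed by detailed balance against the Boltzmann
stationary law, so the generator's equilibrium distribution equals the
Boltzmann weights of the basin free energies by construction.

Trajectories are sampled with the exact Gillespie algorithm and then
discretized onto a regular frame grid; no time-step discretization error
enters the jump statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB_KCAL, MACROSTATE_LABELS

__all__ = ["ReferenceKineticModel", "build_reference_model", "sample_ctmc"]

#: Basin free energies (kcal/mol, global minimum = 0).  C_o sits <1 kcal/mol
#: above C_oi; O and U sit between 2 and 3 kcal/mol, giving each an
#: equilibrium population of ~1%.
REFERENCE_FREE_ENERGIES = {"C_oi": 0.0, "C_o": 0.59, "O": 2.55, "U": 2.55}

#: Transition barriers (kcal/mol) measured from the minimum of the edge's
#: origin basin.  The U->C_oi and U->O entries are the small direct escape
#: channels that open up only under protonation.
REFERENCE_BARRIERS = {
    ("C_oi", "C_o"): 2.0,
    ("C_o", "O"): 4.5,
    ("C_o", "U"): 5.0,
    ("U", "C_oi"): 5.0,
    ("U", "O"): 4.0,
}


@dataclass(frozen=True)
class ReferenceKineticModel:
    """Calibrated jump-process ground truth for the gating cycle.

    Attributes
    ----------
    state_labels
        Ordered macrostate names; U present only when ``protonated``.
    free_energies
        Basin free energies in kcal/mol, minimum exactly 0.
    barriers
        Directed-edge barriers in kcal/mol measured from the origin basin;
        only the independently specified (forward) edges are listed, the
        reverse rates being implied by detailed balance.
    rate_matrix
        Generator K in units of 1/frame; rows sum to zero.
    temperature
        Kelvin.
    protonated
        Whether the external glutamate is modeled as protonated.
    """

    state_labels: tuple[str, ...]
    free_energies: np.ndarray
    barriers: dict[tuple[str, str], float]
    rate_matrix: np.ndarray
    temperature: float
    protonated: bool
    prefactor: float = 1.0

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def stationary_distribution(self) -> np.ndarray:
        """Boltzmann weights of the basin free energies."""
        w = np.exp(-self.free_energies / self.kT)
        return w / w.sum()

    def index(self, label: str) -> int:
        return self.state_labels.index(label)


def build_reference_model(
    protonated: bool,
    temperature: float = 300.0,
    free_energies: dict[str, float] | None = None,
    barriers: dict[tuple[str, str], float] | None = None,
    prefactor: float = 1.0,
) -> ReferenceKineticModel:
    """Build the calibrated macrostate generator.

    Parameters
    ----------
    protonated
        If True the occluded U state and its edges are included; otherwise
        the model has the three states C_oi, C_o, O.
    temperature
        Kelvin; must be positive.
    free_energies, barriers
        Optional overrides of the calibrated defaults (same conventions).
    prefactor
        Arrhenius prefactor nu in 1/frame.

    Raises
    ------
    ValueError
        If ``temperature <= 0`` or any barrier lies below the free-energy
        difference across its edge (the barrier top would be below the
        destination basin).
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    G = dict(REFERENCE_FREE_ENERGIES if free_energies is None else free_energies)
    B = dict(REFERENCE_BARRIERS if barriers is None else barriers)

    labels = tuple(s for s in MACROSTATE_LABELS
                   if s in G and (protonated or s != "U"))
    if not protonated:
        G.pop("U", None)
        B = {(a, b): v for (a, b), v in B.items() if "U" not in (a, b)}

    kT = KB_KCAL * temperature
    g = np.array([G[s] for s in labels], dtype=float)
    g -= g.min()

    n = len(labels)
    K = np.zeros((n, n))
    pi = np.exp(-g / kT)
    pi /= pi.sum()
    for (a, b), dG in B.items():
        i, j = labels.index(a), labels.index(b)
        if dG < g[j] - g[i] - 1e-12:
            raise ValueError(
                f"barrier {a}->{b} ({dG} kcal/mol) lies below the "
                f"free-energy difference across the edge ({g[j] - g[i]:.3f})")
        k_fwd = prefactor * np.exp(-dG / kT)
        K[i, j] = k_fwd
        # reverse rate from detailed balance: pi_i k_ij = pi_j k_ji
        K[j, i] = k_fwd * pi[i] / pi[j]
    np.fill_diagonal(K, 0.0)
    np.fill_diagonal(K, -K.sum(axis=1))

    return ReferenceKineticModel(
        state_labels=labels,
        free_energies=g,
        barriers=B,
        rate_matrix=K,
        temperature=temperature,
        protonated=protonated,
        prefactor=prefactor,
    )


def sample_ctmc(
    model: ReferenceKineticModel,
    n_traj: int,
    n_steps: int,
    dt: float = 1.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Sample discrete state paths of the jump process on a regular grid.

    Each trajectory starts from the stationary distribution, evolves by
    exact Gillespie dynamics, and is recorded at times 0, dt, ..., for
    ``n_steps`` frames.  Because the continuous jump times are sampled
    exactly, the discretized chain is an exact sample of the process at
    the grid times.

    Parameters
    ----------
    dt
        Grid spacing in the generator's time unit (frames by default).
        Must satisfy ``max|K_ii| * dt <= 0.1`` so that the grid resolves
        individual jumps; a coarser grid is refused.

    Returns
    -------
    list of int ndarray, each of length ``n_steps``.
    """
    K = model.rate_matrix
    max_exit = float(np.max(-np.diag(K)))
    if max_exit * dt > 0.1 + 1e-12:
        raise ValueError(
            f"dt={dt} too coarse: max|K_ii|*dt = {max_exit * dt:.4f} "
            "exceeds the bound 0.1; reduce dt or the rates")
    rng = np.random.default_rng(seed)
    pi = model.stationary_distribution()
    n = model.n_states
    exit_rates = -np.diag(K)
    jump_probs = K.copy()
    np.fill_diagonal(jump_probs, 0.0)
    with np.errstate(invalid="ignore"):
        jump_probs = np.where(exit_rates[:, None] > 0,
                              jump_probs / np.where(exit_rates[:, None] > 0,
                                                    exit_rates[:, None], 1.0),
                              0.0)
    t_end = n_steps * dt
    paths = []
    for _ in range(n_traj):
        path = np.empty(n_steps, dtype=np.int64)
        state = int(rng.choice(n, p=pi))
        t = 0.0
        frame = 0
        while frame < n_steps:
            rate = exit_rates[state]
            t_next = t + (rng.exponential(1.0 / rate) if rate > 0 else t_end + dt)
            # frames strictly before the jump keep the current state
            last = min(n_steps, int(np.ceil(t_next / dt)))
            last = max(last, frame)
            path[frame:last] = state
            frame = last
            if t_next >= t_end:
                break
            state = int(rng.choice(n, p=jump_probs[state]))
            t = t_next
        paths.append(path)
    return paths
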