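"""Kinetic coarse-graining: PCCA+ macrostates and a continuous-time
rate-matrix model of their interconversion.

PCCA+ maps the span of the top right eigenvectors of a reversible MSM to
a probability simplex: an inner-simplex vertex search picks n microstates
as provisional simplex vertices, and the resulting linear map A is then
optimized (under the feasibility constraints chi >= 0, rows summing to 1)
to maximize the crispness objective trace(diag(1/w) A^T A), w = A[0, :].
The fuzzy memberships chi = X A give each microstate's degree of
belonging to each metastable macrostate.

Macrostate kinetics are estimated as a continuous-time rate matrix K:
the maximum-likelihood generator under the constraints off-diag >= 0,
zero row sums and detailed balance, obtained by maximizing the
likelihood of the observed lag-tau macrostate transitions under
expm(K tau), initialized from the matrix logarithm of the macrostate
transition matrix projected onto the feasible cone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .msm import MSModel, count_transitions, mle_reversible

logger = logging.getLogger(__name__)

__all__ = ["MacroModel", "pcca_plus", "choose_n_macrostates",
           "estimate_rate_matrix", "kinetic_network_summary",
           "network_json"]


@dataclass
class MacroModel:
    """PCCA+ coarse-graining of a microstate MSM.

    ``memberships`` is the (n_micro_active, n_macro) fuzzy matrix chi;
    ``assignments`` its row-wise argmax; ``populations`` the summed
    stationary weights.  ``rate_matrix`` (per physical time unit) and the
    bootstrap ``rate_bands`` are filled by :func:`estimate_rate_matrix`.
    """

    n_macrostates: int
    memberships: np.ndarray
    assignments: np.ndarray
    populations: np.ndarray
    msmodel: MSModel
    labels: list[str] = field(default_factory=list)
    rate_matrix: np.ndarray | None = None
    rate_bands: np.ndarray | None = None
    observed_counts: np.ndarray | None = None

    def macro_dtrajs(self, dtrajs) -> list[np.ndarray]:
        """Map microstate trajectories to crisp macrostate trajectories.

        Frames in trimmed microstates get -1.
        """
        f2a = self.msmodel.full_to_active
        lut = np.full(self.msmodel.n_states_full, -1, dtype=np.int64)
        ok = f2a >= 0
        lut[ok] = self.assignments[f2a[ok]]
        return [lut[np.asarray(d)] for d in dtrajs]


def _inner_simplex_vertices(X: np.ndarray, n: int) -> np.ndarray:
    """Deterministic vertex search: greedily pick rows spanning the simplex."""
    Xw = X.copy()
    idx = np.empty(n, dtype=np.int64)
    # first vertex: row farthest from the origin
    norms = np.einsum("ij,ij->i", Xw, Xw)
    idx[0] = int(np.argmax(norms))
    Xw = Xw - Xw[idx[0]]
    for k in range(1, n):
        norms = np.einsum("ij,ij->i", Xw, Xw)
        idx[k] = int(np.argmax(norms))
        v = Xw[idx[k]]
        nv = np.dot(v, v)
        if nv > 0:
            Xw = Xw - np.outer(Xw @ v, v) / nv
    return idx


def _fill_A(A: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Project A onto the feasible set (chi >= 0, partition of unity)."""
    n = A.shape[0]
    A = A.copy()
    # rows 1.. keep their free part; first column balances row sums
    A[1:, 0] = -A[1:, 1:].sum(axis=1)
    # first row enforces positivity of chi = X A
    for j in range(n):
        A[0, j] = -np.min(X[:, 1:] @ A[1:, j])
    s = A[0, :].sum()
    if s <= 0:
        raise RuntimeError("PCCA+ feasibility projection failed (degenerate A)")
    return A / s


def _crispness(A: np.ndarray) -> float:
    w = A[0, :]
    return float(np.sum(A**2 / w[None, :]))


def pcca_plus(msmodel: MSModel, n_macrostates: int,
              optimize: bool = True) -> MacroModel:
    """PCCA+ fuzzy decomposition of a reversible MSM.

    Parameters
    ----------
    n_macrostates
        Number of metastable sets; requires n real eigenvalues near 1
        (an error cites the eigenvalue gap if the spectral support is
        insufficient, i.e. the n-th eigenvalue is not positive).
    optimize
        Refine the vertex-search initial guess by maximizing crispness
        over the feasible set (Nelder-Mead on the free block of A).
    """
    n = n_macrostates
    if n < 2 or n > msmodel.n_states:
        raise ValueError(f"n_macrostates={n} out of range")
    pi = msmodel.stationary
    s = np.sqrt(pi)
    sym = msmodel.transition_matrix * (s[:, None] / s[None, :])
    sym = 0.5 * (sym + sym.T)
    lam, u = scipy.linalg.eigh(sym)
    order = np.argsort(lam)[::-1]
    lam, u = lam[order][:n], u[:, order][:, :n]
    if lam[-1] <= 0:
        raise ValueError(
            f"requested {n} macrostates but eigenvalue {n} is "
            f"{lam[-1]:.4f} (spectral gap exhausted after "
            f"{int(np.sum(lam > 0))} positive eigenvalues)")
    # right eigenvectors of T, pi-orthonormal, first column constant
    X = u / s[:, None]
    X[:, 0] = 1.0
    for k in range(1, n):
        # deterministic sign convention (scale is fixed by pi-orthonormality)
        i = np.argmax(np.abs(X[:, k]))
        if X[i, k] < 0:
            X[:, k] = -X[:, k]

    idx = _inner_simplex_vertices(X, n)
    V = X[idx]
    A = np.linalg.inv(V)
    A = _fill_A(A, X)
    if optimize and n > 2:
        x0 = A[1:, 1:].ravel()

        def neg_obj(z):
            B = A.copy()
            B[1:, 1:] = z.reshape(n - 1, n - 1)
            try:
                B = _fill_A(B, X)
            except RuntimeError:
                return 1e6
            return -_crispness(B)

        res = scipy.optimize.minimize(neg_obj, x0, method="Nelder-Mead",
                                      options={"maxiter": 200 * (n - 1)**2,
                                               "xatol": 1e-8, "fatol": 1e-10})
        trial = A.copy()
        trial[1:, 1:] = res.x.reshape(n - 1, n - 1)
        try:
            trial = _fill_A(trial, X)
            if _crispness(trial) >= _crispness(A):
                A = trial
        except RuntimeError:
            pass
    chi = X @ A
    chi = np.clip(chi, 0.0, 1.0)
    chi /= chi.sum(axis=1)[:, None]
    assign = np.argmax(chi, axis=1)
    pops = np.array([pi[assign == j].sum() for j in range(n)])
    # order macrostates by decreasing population for determinism
    order = np.argsort(pops)[::-1]
    remap = np.empty(n, dtype=np.int64)
    remap[order] = np.arange(n)
    chi = chi[:, order]
    assign = remap[assign]
    pops = pops[order]
    return MacroModel(n_macrostates=n, memberships=chi, assignments=assign,
                      populations=pops, msmodel=msmodel)


def choose_n_macrostates(msmodel: MSModel, max_n: int = 6,
                         override: int | None = None) -> int:
    """Pick the macrostate count at the largest implied-timescale gap.

    Considers n in [2, max_n]; n groups the processes whose timescales
    precede the largest ratio t_{n-1}/t_n of successive implied
    timescales.  The full gap table is logged so a user can override
    (the override is honored and logged).
    """
    lam = msmodel.eigenvalues(max_n + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = np.where(lam[1:] > 0, -msmodel.lag / np.log(np.clip(lam[1:],
                                                                 1e-300, None)),
                      np.nan)
    # ts[i] is the timescale of process i+2; choosing n macrostates keeps
    # processes 2..n, so the gap examined for n is ts[n-2]/ts[n-1]
    gaps = {}
    for n in range(2, min(max_n, msmodel.n_states - 1) + 1):
        a = ts[n - 2] if n - 2 < len(ts) else np.nan
        b = ts[n - 1] if n - 1 < len(ts) else np.nan
        gaps[n] = a / b if np.isfinite(a) and np.isfinite(b) and b > 0 else np.inf
    logger.info("macrostate spectral-gap table (n: t_{n-1}/t_n): %s",
                {k: round(v, 2) if np.isfinite(v) else v
                 for k, v in gaps.items()})
    if override is not None:
        logger.info("macrostate count override: using n=%d", override)
        return override
    return max(gaps, key=lambda k: gaps[k])


def _detailed_balance_parametrization(theta, pi, n):
    """Rates from log symmetric fluxes: K_ij = exp(theta_ij)/pi_i."""
    K = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    s = np.exp(theta)
    K[iu] = s / pi[iu[0]]
    K.T[iu] = s / pi[iu[1]]
    np.fill_diagonal(K, -K.sum(axis=1))
    return K


def estimate_rate_matrix(macro_dtrajs, lag: int, n_states: int | None = None,
                         frame_time: float = 1.0,
                         zero_threshold: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood reversible generator from macrostate trajectories.

    Frames labelled -1 (trimmed microstates) break the trajectories into
    valid segments.  Returns ``(K, counts)`` with K in 1/(physical time)
    units (``frame_time`` per frame).

    The estimator maximizes sum_ij C_ij log [expm(K tau)]_ij over
    generators satisfying detailed balance with respect to the reversible
    MLE's stationary law, parameterized by log symmetric fluxes, and is
    initialized from the projected matrix logarithm of the transition
    matrix.  A non-embeddable T (negative off-diagonals in logm) only
    affects the initializer, which is projected and flagged.
    """
    segs = []
    for d in macro_dtrajs:
        d = np.asarray(d, dtype=np.int64)
        if (d < 0).any():
            breaks = np.flatnonzero(d < 0)
            prev = 0
            for b in list(breaks) + [len(d)]:
                if b - prev > lag:
                    segs.append(d[prev:b])
                prev = b + 1
        else:
            segs.append(d)
    if not segs:
        raise ValueError("no macrostate segments longer than the lag")
    if n_states is None:
        n_states = 1 + max(int(s.max()) for s in segs)
    C = count_transitions(segs, lag, n_states)
    if C.sum() - np.trace(C) == 0:
        # no inter-state transitions observed at all: zero rates
        return np.zeros((n_states, n_states)), C
    m = mle_reversible(C, lag=lag, frame_time=frame_time)
    if m.n_states < n_states:
        raise ValueError("macrostate trajectory not connected at this lag")
    pi = m.stationary
    T = m.transition_matrix
    tau = lag * frame_time
    try:
        K0 = scipy.linalg.logm(T).real / tau
        if (K0[~np.eye(n_states, dtype=bool)] < -zero_threshold).any():
            logger.info("matrix logarithm not a generator; projecting the "
                        "initializer onto the feasible cone")
    except Exception:  # pragma: no cover
        K0 = (T - np.eye(n_states)) / tau
    K0 = np.where(np.eye(n_states, dtype=bool), 0.0, np.maximum(K0, 1e-10))
    iu = np.triu_indices(n_states, 1)
    s0 = 0.5 * (pi[iu[0]] * K0[iu] + pi[iu[1]] * K0.T[iu])
    theta0 = np.log(np.maximum(s0, 1e-12))

    def negll(theta):
        K = _detailed_balance_parametrization(theta, pi, n_states)
        P = scipy.linalg.expm(K * tau)
        P = np.clip(P, 1e-300, None)
        return -float(np.sum(C * np.log(P)))

    res = scipy.optimize.minimize(negll, theta0, method="L-BFGS-B")
    theta = res.x if res.fun <= negll(theta0) else theta0
    K = _detailed_balance_parametrization(theta, pi, n_states)
    return K, C


def kinetic_network_summary(macro: MacroModel, kT: float | None = None,
                            count_floor: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables of the macrostate kinetic network.

    Nodes carry label, population and dG; edges carry the forward and
    backward rates (per physical time) with bootstrap bands when present.
    Edges whose observed transition count is below ``count_floor`` are
    listed with ``observed=False`` and the note "not observed at this
    sampling depth" — never as rate 0.
    """
    from .msm import free_energy
    from .constants import KT_300K

    if macro.rate_matrix is None:
        raise ValueError("estimate_rate_matrix has not been run on this model")
    kT = kT if kT is not None else KT_300K
    n = macro.n_macrostates
    labels = macro.labels or [f"M{i}" for i in range(n)]
    g = free_energy(macro.populations, kT)
    nodes = pd.DataFrame({"label": labels, "population": macro.populations,
                          "delta_g_kcal_mol": g})
    rows = []
    Cobs = macro.observed_counts
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            obs = int(Cobs[i, j]) if Cobs is not None else None
            observed = obs is None or obs >= count_floor
            band = (macro.rate_bands[i, j]
                    if macro.rate_bands is not None else np.nan)
            rows.append({
                "from": labels[i], "to": labels[j],
                "rate": macro.rate_matrix[i, j] if observed else np.nan,
                "rate_band_sd": band if observed else np.nan,
                "observed_transitions": obs,
                "observed": observed,
                "note": "" if observed else
                        "not observed at this sampling depth",
            })
    return nodes, pd.DataFrame(rows)


def network_json(nodes: pd.DataFrame, edges: pd.DataFrame) -> dict:
    """JSON-serializable graph of the kinetic network tables."""
    import numpy as _np

    def clean(v):
        if isinstance(v, (_np.floating, float)):
            return None if _np.isnan(v) else float(v)
        if isinstance(v, _np.integer):
            return int(v)
        return v

    return {
        "schema": "clcgating-network v1",
        "nodes": [{k: clean(v) for k, v in row.items()}
                  for row in nodes.to_dict("records")],
        "edges": [{k: clean(v) for k, v in row.items()}
                  for row in edges.to_dict("records")],
    }
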