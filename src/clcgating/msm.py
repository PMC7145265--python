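"""Reversible microstate Markov state models and derived thermodynamics.

Estimation pipeline: sliding-window transition counts at a lag, ergodic
trimming to the largest strongly connected component, and the standard
reversible maximum-likelihood estimator — the fixed-point iteration on
symmetric edge weights x_ij,

    x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j),

whose converged row sums give the stationary distribution and whose
normalized rows give the transition matrix satisfying detailed balance
exactly.  Uncertainties come from bootstrap resampling whole trajectories
(preserving autocorrelation), all replicas sharing the full-data state
definition.

Free energies are Boltzmann inversions of stationary weights,
dG_i = -kT ln(pi_i / max_j pi_j), and 1-D landscapes are stationary-
weighted histograms along a projected coordinate with barriers read from
bin maxima between basin minima (bias of order one bin width).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.sparse.csgraph import connected_components

from .constants import KT_300K

logger = logging.getLogger(__name__)

__all__ = ["MSModel", "FreeEnergyProfile", "count_transitions",
           "largest_connected_set", "mle_reversible", "implied_timescales",
           "bootstrap_msms", "free_energy", "project_free_energy",
           "chapman_kolmogorov"]


@dataclass
class MSModel:
    """Reversible microstate MSM on the active (connected) state set.

    ``active_set`` maps active indices to original microstate labels;
    ``full_to_active`` is -1 for trimmed states.
    """

    lag: int
    transition_matrix: np.ndarray
    stationary: np.ndarray
    active_set: np.ndarray
    n_states_full: int
    counts: np.ndarray
    frame_time: float = 1.0

    @property
    def lag_time(self) -> float:
        """Lag in physical time units (frame_time * lag frames)."""
        return self.lag * self.frame_time

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def full_to_active(self) -> np.ndarray:
        m = np.full(self.n_states_full, -1, dtype=np.int64)
        m[self.active_set] = np.arange(self.n_states)
        return m

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        """Real spectrum of T via the detailed-balance symmetrization."""
        pi = self.stationary
        s = np.sqrt(pi)
        sym = self.transition_matrix * (s[:, None] / s[None, :])
        sym = 0.5 * (sym + sym.T)
        lam = np.sort(scipy.linalg.eigvalsh(sym))[::-1]
        return lam if k is None else lam[:k]

    def timescales(self, k: int = 5) -> np.ndarray:
        """Implied timescales -lag/ln lambda_i in frames (NaN for lambda<=0)."""
        lam = self.eigenvalues(k + 1)[1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(lam > 0, -self.lag / np.log(np.clip(lam, 1e-300, None)),
                         np.nan)
        return t


def count_transitions(dtrajs, lag: int, n_states: int | None = None) -> np.ndarray:
    """Sliding-window transition counts at the given lag (integer matrix)."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    if n_states is None:
        n_states = 1 + max(int(d.max()) for d in dtrajs if d.size)
    if all(len(d) <= lag for d in dtrajs):
        raise ValueError(f"lag {lag} is >= every trajectory length")
    c = np.zeros(n_states * n_states, dtype=np.int64)
    for d in dtrajs:
        if len(d) <= lag:
            continue
        pair = d[:-lag] * n_states + d[lag:]
        c += np.bincount(pair, minlength=n_states * n_states)
    return c.reshape(n_states, n_states)


def largest_connected_set(counts: np.ndarray) -> np.ndarray:
    """States of the strongly connected component carrying the most counts.

    Connectivity is taken on the directed graph of positive counts; the
    winning component maximizes its total internal counts (ties break to
    more states, then lowest label). Trimmed states are logged.
    """
    counts = np.asarray(counts)
    n = counts.shape[0]
    graph = scipy.sparse.csr_matrix((counts > 0).astype(np.int8))
    n_comp, labels = connected_components(graph, directed=True,
                                          connection="strong")
    best, best_key = None, None
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        w = counts[np.ix_(members, members)].sum()
        key = (w, len(members), -members[0])
        if best_key is None or key > best_key:
            best, best_key = members, key
    dropped = n - len(best)
    if dropped:
        logger.info("ergodic trimming: dropped %d of %d states outside the "
                    "largest connected set", dropped, n)
    return best


def mle_reversible(counts: np.ndarray, tol: float = 1e-10,
                   max_iter: int = 100_000, lag: int = 1,
                   frame_time: float = 1.0) -> MSModel:
    """Reversible maximum-likelihood MSM from a count matrix.

    Trims to the largest connected set, then iterates the detailed-balance
    fixed point until the log-likelihood change per iteration falls below
    ``tol``.  The stationary distribution from the converged edge weights
    is verified against the leading left eigenvector of T.

    Raises
    ------
    RuntimeError
        If the iteration has not converged after ``max_iter`` steps.
    """
    counts = np.asarray(counts, dtype=np.float64)
    active = largest_connected_set(counts)
    c = counts[np.ix_(active, active)]
    n = c.shape[0]
    csym = c + c.T
    ci = c.sum(axis=1)
    x = csym / csym.sum()
    last_ll = -np.inf
    converged = False
    for it in range(max_iter):
        xi = x.sum(axis=1)
        q = ci / xi
        denom = q[:, None] + q[None, :]
        x = csym / np.where(denom > 0, denom, 1.0)
        x /= x.sum()
        xi = x.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = x / xi[:, None]
            ll = float(np.sum(c[csym > 0] * np.log(t[csym > 0])))
        if abs(ll - last_ll) < tol * max(1.0, abs(ll)):
            converged = True
            break
        last_ll = ll
    if not converged:
        raise RuntimeError(
            f"reversible MLE did not converge in {max_iter} iterations "
            f"(last log-likelihood change {abs(ll - last_ll):.3e})")
    pi = x.sum(axis=1)
    pi /= pi.sum()
    T = x / x.sum(axis=1)[:, None]
    # consistency: pi must be the leading left eigenvector of T
    resid = np.max(np.abs(pi @ T - pi))
    if resid > 1e-8:
        raise RuntimeError(f"stationary vector inconsistent with T "
                           f"(residual {resid:.2e})")
    return MSModel(lag=lag, transition_matrix=T, stationary=pi,
                   active_set=active, n_states_full=counts.shape[0],
                   counts=c.astype(np.int64), frame_time=frame_time)


def implied_timescales(dtrajs, lags, n_timescales: int = 5,
                       n_states: int | None = None, frame_time: float = 1.0,
                       rel_tol: float = 0.2) -> "pd.DataFrame":
    """Implied timescales t_i(tau) = -tau/ln lambda_i(tau) across lags.

    Returns a tidy DataFrame (lag, process, timescale_frames,
    timescale_time); non-positive eigenvalues yield NaN (a reported gap,
    not silently dropped).  A per-process ``converged`` flag marks
    agreement of the two largest lags within ``rel_tol``.
    """
    import pandas as pd

    rows = []
    for lag in lags:
        model = mle_reversible(count_transitions(dtrajs, lag, n_states),
                               lag=lag, frame_time=frame_time)
        ts = model.timescales(n_timescales)
        for i, t in enumerate(ts):
            rows.append({"lag": lag, "process": i + 2,
                         "timescale_frames": t,
                         "timescale_time": t * frame_time})
    df = pd.DataFrame(rows)
    last_two = sorted(set(df["lag"]))[-2:]
    conv = {}
    for p, grp in df.groupby("process"):
        vals = grp.set_index("lag")["timescale_frames"]
        if len(last_two) == 2 and all(l in vals.index for l in last_two):
            a, b = vals[last_two[0]], vals[last_two[1]]
            conv[p] = bool(np.isfinite(a) and np.isfinite(b)
                           and abs(b - a) <= rel_tol * max(abs(a), abs(b)))
        else:
            conv[p] = False
    df["converged"] = df["process"].map(conv)
    return df


def bootstrap_msms(dtrajs, lag: int, n_boot: int = 100, seed: int = 0,
                   n_states: int | None = None,
                   frame_time: float = 1.0) -> list[MSModel]:
    """Bootstrap ensemble of MSMs, resampling whole trajectories.

    All replicas share the full-data active-set definition: replica
    counts are restricted to the full-data largest connected set, and a
    replica that loses connectivity on that set is dropped (and the drop
    logged and counted).  Requires >= 2 trajectories.
    """
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    if len(dtrajs) < 2:
        raise ValueError("bootstrap needs >= 2 trajectories "
                         "(the resampling unit is the trajectory)")
    if n_states is None:
        n_states = 1 + max(int(d.max()) for d in dtrajs)
    full_counts = count_transitions(dtrajs, lag, n_states)
    active = largest_connected_set(full_counts)
    per_traj = [count_transitions([d], lag, n_states)
                if len(d) > lag else np.zeros((n_states, n_states), np.int64)
                for d in dtrajs]
    per_traj = np.stack([c[np.ix_(active, active)] for c in per_traj])
    rng = np.random.default_rng(seed)
    models, dropped = [], 0
    while len(models) < n_boot:
        pick = rng.integers(0, len(dtrajs), size=len(dtrajs))
        cb = per_traj[pick].sum(axis=0)
        sub_active = largest_connected_set(cb)
        if len(sub_active) < len(active):
            dropped += 1
            if dropped > 10 * n_boot:
                raise RuntimeError("bootstrap: too many disconnected replicas")
            continue
        m = mle_reversible(cb, lag=lag, frame_time=frame_time)
        # express on original microstate labels
        m.active_set = active[m.active_set]
        m.n_states_full = n_states
        models.append(m)
    if dropped:
        logger.info("bootstrap: dropped %d replicas that lost connectivity",
                    dropped)
    return models


def free_energy(pi: np.ndarray, kT: float = KT_300K) -> np.ndarray:
    """Boltzmann inversion dG_i = -kT ln(pi_i/max pi); minimum exactly 0.

    Zero-population states map to +inf (flagged by the caller's tooling).
    """
    pi = np.asarray(pi, dtype=np.float64)
    with np.errstate(divide="ignore"):
        g = -kT * np.log(pi / pi.max())
    return g


@dataclass
class FreeEnergyProfile:
    """1-D free-energy landscape along a projected coordinate."""

    centers: np.ndarray  # bin centers along the coordinate
    f: np.ndarray  # kcal/mol, min over valid bins = 0
    counts: np.ndarray  # raw frame counts per bin
    valid: np.ndarray  # bins above the count floor
    errors: np.ndarray | None = None  # bootstrap SD per bin

    def to_dataframe(self):
        """Tidy per-bin table (coordinate, free energy, counts, flags)."""
        import pandas as pd

        d = {"coordinate": self.centers, "free_energy_kcal_mol": self.f,
             "counts": self.counts, "sampled": self.valid}
        if self.errors is not None:
            d["free_energy_sd"] = self.errors
        return pd.DataFrame(d)

    def minima(self) -> np.ndarray:
        """Indices of interior local minima of the valid profile."""
        idx = np.flatnonzero(self.valid)
        f = self.f[idx]
        out = []
        for j in range(len(idx)):
            lo = f[j - 1] if j > 0 else np.inf
            hi = f[j + 1] if j < len(idx) - 1 else np.inf
            if f[j] < lo and f[j] <= hi:
                out.append(idx[j])
        return np.asarray(out, dtype=np.int64)

    def barrier(self, a: float, b: float) -> float:
        """Barrier from basin at coordinate ``a`` toward basin at ``b``.

        Nearest local minima to ``a`` and ``b`` define the basins; the
        barrier is the maximum of the profile between them minus the
        origin-basin minimum.  Unsampled bins inside the span raise.
        """
        mins = self.minima()
        if mins.size == 0:
            raise ValueError("no basin minima found in the profile")
        ia = mins[np.argmin(np.abs(self.centers[mins] - a))]
        ib = mins[np.argmin(np.abs(self.centers[mins] - b))]
        if ia == ib:
            raise ValueError("origin and destination map to the same basin; "
                             "no barrier annotation")
        lo, hi = sorted((ia, ib))
        span = slice(lo, hi + 1)
        if not self.valid[span].all():
            raise ValueError("unsampled bins between the basins; "
                             "profile span is not continuous")
        return float(self.f[span].max() - self.f[ia])


def frame_weights(dtrajs, model: MSModel) -> list[np.ndarray]:
    """Per-frame stationary weights pi(state)/count(state); trimmed frames 0."""
    counts = np.zeros(model.n_states_full, dtype=np.int64)
    for d in dtrajs:
        counts += np.bincount(d, minlength=model.n_states_full)
    w_state = np.zeros(model.n_states_full)
    occupied = counts > 0
    f2a = model.full_to_active
    for s in np.flatnonzero(occupied):
        if f2a[s] >= 0:
            w_state[s] = model.stationary[f2a[s]] / counts[s]
    return [w_state[np.asarray(d)] for d in dtrajs]


def project_free_energy(series, weights=None, kT: float = KT_300K,
                        bins: int = 72, count_floor: int = 10,
                        bin_range=None,
                        bootstrap_weights=None) -> FreeEnergyProfile:
    """Weighted histogram free-energy profile along one coordinate.

    Parameters
    ----------
    series
        1-D coordinate values (list of arrays or one array).
    weights
        Per-frame weights matching ``series`` (e.g. from
        :func:`frame_weights`); uniform if None.
    count_floor
        Bins with fewer raw frames are flagged invalid, never
        interpolated silently.
    bootstrap_weights
        Optional list of alternative weight sets (one per bootstrap MSM);
        yields per-bin free-energy SDs.
    """
    xs = np.concatenate([np.ravel(s) for s in np.atleast_1d(series)]) \
        if isinstance(series, list) else np.ravel(series)
    if weights is None:
        w = np.ones_like(xs)
    else:
        w = np.concatenate([np.ravel(a) for a in weights]) \
            if isinstance(weights, list) else np.ravel(weights)
    rng = bin_range if bin_range is not None else (xs.min(), xs.max())
    hist, edges = np.histogram(xs, bins=bins, range=rng, weights=w)
    counts, _ = np.histogram(xs, bins=bins, range=rng)
    centers = 0.5 * (edges[:-1] + edges[1:])
    valid = counts >= count_floor
    f = np.full(bins, np.inf)
    with np.errstate(divide="ignore"):
        f[valid] = -kT * np.log(hist[valid] / hist[valid].sum())
    if valid.any():
        f -= f[valid].min()
    errors = None
    if bootstrap_weights is not None:
        fs = []
        for wb in bootstrap_weights:
            wbc = np.concatenate([np.ravel(a) for a in wb]) \
                if isinstance(wb, list) else np.ravel(wb)
            hb, _ = np.histogram(xs, bins=bins, range=rng, weights=wbc)
            fb = np.full(bins, np.nan)
            ok = valid & (hb > 0)
            with np.errstate(divide="ignore"):
                fb[ok] = -kT * np.log(hb[ok] / hb[ok].sum())
            if ok.any():
                fb -= np.nanmin(fb[ok])
            fs.append(fb)
        errors = np.nanstd(np.stack(fs), axis=0)
    return FreeEnergyProfile(centers=centers, f=f, counts=counts,
                             valid=valid, errors=errors)


def chapman_kolmogorov(dtrajs, lag: int, sets, n_states: int | None = None):
    """Residence-probability Chapman-Kolmogorov check.

    Compares, for each state set S, the model prediction
    ``[T(tau)^2]_SS`` against the directly estimated ``[T(2 tau)]_SS``
    (probability of being in S at time 2*tau given start in S, weighted
    by the stationary law restricted to S).  Returns a list of
    (predicted, estimated) pairs.
    """
    m1 = mle_reversible(count_transitions(dtrajs, lag, n_states), lag=lag)
    m2 = mle_reversible(count_transitions(dtrajs, 2 * lag, n_states),
                        lag=2 * lag)
    out = []
    for S in sets:
        a1 = m1.full_to_active[np.asarray(S)]
        a1 = a1[a1 >= 0]
        a2 = m2.full_to_active[np.asarray(S)]
        a2 = a2[a2 >= 0]
        w1 = m1.stationary[a1] / m1.stationary[a1].sum()
        T2 = m1.transition_matrix @ m1.transition_matrix
        pred = float(w1 @ T2[np.ix_(a1, a1)].sum(axis=1))
        w2 = m2.stationary[a2] / m2.stationary[a2].sum()
        est = float(w2 @ m2.transition_matrix[np.ix_(a2, a2)].sum(axis=1))
        out.append((pred, est))
    return out
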