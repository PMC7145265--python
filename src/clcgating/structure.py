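"""Pore-radius profiles, MSM-weighted ensembles, site occupancy, and
torus-aware Ramachandran densities.

The pore profiler follows the maximal-inscribed-sphere idea of tunnel
software: at each arc-length position s along a conduction pathway, the
pore radius is the largest clearance max_p min_i (|p - x_i| - R_i) over
probe positions p in the slice plane, located by a coarse in-plane grid
search refined by a local simplex optimization.  Profiles are reported
with signed s (0 at the reference point, e.g. the external-gate
glutamate), with separate extracellular/intracellular half-profiles
supported as two polylines sharing the origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

logger = logging.getLogger(__name__)

__all__ = ["PoreProfile", "SiteDefinition", "pore_profile",
           "subthreshold_extent", "sample_macrostate_ensemble",
           "occupancy_table", "ramachandran_density", "VDW_RADII"]

#: Van der Waals radii by element (angstrom), Bondi 1964 set.
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
             "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98}

#: Radius of a chloride ion (angstrom), the conduction threshold.
CL_ION_RADIUS = 1.8


@dataclass(frozen=True)
class SiteDefinition:
    """A spherical ion-binding site (e.g. S_ext, S_cen, S_int)."""

    name: str
    center: tuple
    radius: float = 2.5

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("site radius must be positive")


@dataclass
class PoreProfile:
    """Arc length (signed, angstrom) vs maximal-inscribed-sphere radius."""

    s: np.ndarray
    radius: np.ndarray
    impassable: np.ndarray  # radius <= 0 at this slice
    open_funnel: np.ndarray  # probe escaped the search disk

    @property
    def bottleneck(self) -> tuple[float, float]:
        """(s*, r*) at the global minimum of the profile."""
        i = int(np.argmin(self.radius))
        return float(self.s[i]), float(self.radius[i])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"s_angstrom": self.s,
                             "radius_angstrom": self.radius,
                             "impassable": self.impassable,
                             "open_funnel": self.open_funnel})


def _grid_best(point, e1, e2, sub, rsub, center_uv, half_width, spacing,
               max_radius):
    """Best clearance over a square grid of in-plane offsets (disk-clipped)."""
    g = np.arange(-half_width, half_width + 1e-9, spacing)
    uu = (center_uv[0] + g)[:, None] + np.zeros_like(g)[None, :]
    vv = center_uv[1] + np.zeros_like(g)[:, None] + g[None, :]
    keep = uu**2 + vv**2 <= max_radius**2
    if not keep.any():
        return center_uv, -np.inf
    pts = point[None, :] + uu[keep][:, None] * e1 + vv[keep][:, None] * e2
    clear = np.full(pts.shape[0], np.inf)
    for i in range(0, sub.shape[0], 2048):  # chunk over atoms
        d = np.linalg.norm(pts[:, None, :] - sub[None, i:i + 2048, :],
                           axis=2) - rsub[None, i:i + 2048]
        np.minimum(clear, d.min(axis=1), out=clear)
    best = int(np.argmax(clear))
    return np.array([uu[keep][best], vv[keep][best]]), float(clear[best])


def _slice_radius(coords, radii, point, axis, max_radius, grid, refine_tol):
    """Best probe clearance in the plane through ``point`` normal to ``axis``.

    Coarse 1 A scan of the search disk, fine ``grid`` scan around the
    coarse optimum, then a disk-constrained simplex refinement to
    ``refine_tol``.
    """
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    # only atoms within max_radius + R of the plane can bound a probe
    # whose clearance is within the search disk
    d_axis = (coords - point) @ axis
    near = np.abs(d_axis) <= (2 * max_radius + radii.max())
    sub = coords[near]
    rsub = radii[near]
    if sub.shape[0] == 0:
        return max_radius, True

    coarse = max(grid, min(1.0, max_radius / 2))
    uv, _ = _grid_best(point, e1, e2, sub, rsub, np.zeros(2), max_radius,
                       coarse, max_radius)
    if grid < coarse:
        uv, _ = _grid_best(point, e1, e2, sub, rsub, uv, coarse, grid,
                           max_radius)

    def clearance(uv):
        p = point + uv[0] * e1 + uv[1] * e2
        return float(np.min(np.linalg.norm(sub - p, axis=1) - rsub))

    def neg_obj(uv):
        # confine the probe to the search disk with a steep penalty
        excess = np.hypot(*uv) - max_radius
        return -clearance(uv) + (1e3 * excess if excess > 0 else 0.0)

    res = scipy.optimize.minimize(neg_obj, uv, method="Nelder-Mead",
                                  options={"xatol": refine_tol,
                                           "fatol": refine_tol / 10})
    if -res.fun >= clearance(uv):
        uv = res.x
    rho = float(np.hypot(*uv))
    if rho > max_radius:  # project a penalty-boundary point back
        uv = uv * (max_radius / rho)
        rho = max_radius
    r = clearance(uv)
    escaped = rho >= max_radius - grid
    return float(r), bool(escaped)


def pore_profile(coords, radii, path=None, start_point=None, axis=None,
                 extent: float | None = None, step: float = 0.5,
                 max_radius: float = 8.0, grid: float = 0.25,
                 refine_tol: float = 0.01) -> PoreProfile:
    """Maximal-inscribed-sphere radius along a conduction pathway.

    Parameters
    ----------
    coords, radii
        Atom centers (N, 3) and their radii (angstrom).
    path
        (M, 3) polyline of pathway points; arc length is measured along
        it with s=0 at the first vertex.  Alternatively give
        ``start_point`` + ``axis`` + ``extent`` for a straight pathway
        sampled at ``step`` spacing in both directions ([-extent, extent]).
    max_radius
        Probe search confined to a disk of this radius per slice; an
        optimum on the disk boundary is flagged ``open_funnel``.

    Raises
    ------
    ValueError
        For fewer than 4 atoms or a non-positive step.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.shape[0] < 4:
        raise ValueError("need at least 4 atoms")
    if step <= 0:
        raise ValueError("step must be positive")
    if path is None:
        if start_point is None or axis is None or extent is None:
            raise ValueError("give either path or start_point+axis+extent")
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        svals = np.arange(-extent, extent + 1e-9, step)
        points = np.asarray(start_point)[None, :] + svals[:, None] * axis[None, :]
        tangents = np.tile(axis, (len(svals), 1))
    else:
        path = np.asarray(path, dtype=float)
        seg = np.diff(path, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        svals = np.arange(0.0, cum[-1] + 1e-9, step)
        points = np.empty((len(svals), 3))
        tangents = np.empty((len(svals), 3))
        for i, s in enumerate(svals):
            j = min(np.searchsorted(cum, s, side="right") - 1, len(seg) - 1)
            t = (s - cum[j]) / seglen[j] if seglen[j] > 0 else 0.0
            points[i] = path[j] + t * seg[j]
            tangents[i] = seg[j] / seglen[j]
    r = np.empty(len(svals))
    funnel = np.zeros(len(svals), dtype=bool)
    for i in range(len(svals)):
        r[i], funnel[i] = _slice_radius(coords, radii, points[i], tangents[i],
                                        max_radius, grid, refine_tol)
    return PoreProfile(s=svals, radius=r, impassable=r <= 0.0,
                       open_funnel=funnel)


def subthreshold_extent(profile: PoreProfile,
                        threshold: float = CL_ION_RADIUS) -> tuple[float, float]:
    """Total and longest contiguous pathway length with radius < threshold.

    Crossings between grid points are located by linear interpolation.
    """
    s, r = profile.s, profile.radius
    if len(s) == 0:
        raise ValueError("empty profile")
    total = 0.0
    longest = 0.0
    run = 0.0
    below = r < threshold

    def crossing(i):
        # s where r == threshold between i and i+1
        return s[i] + (threshold - r[i]) / (r[i + 1] - r[i]) * (s[i + 1] - s[i])

    start = s[0] if below[0] else None
    for i in range(len(s) - 1):
        if below[i] != below[i + 1]:
            x = crossing(i)
            if below[i]:  # run ends
                run = x - start
                total += run
                longest = max(longest, run)
                start = None
            else:  # run starts
                start = x
    if start is not None:
        run = s[-1] - start
        total += run
        longest = max(longest, run)
    return total, longest


def sample_macrostate_ensemble(msmodel, macromodel, frame_index, state: int,
                               n: int = 1000, seed: int = 0):
    """Draw conformations of one macrostate, microstates weighted by pi.

    ``frame_index`` maps microstate -> sequence of frame identifiers (any
    objects).  Within the chosen macrostate, a microstate is drawn with
    probability proportional to its stationary weight, then a frame
    uniformly within the microstate.

    Raises
    ------
    ValueError
        If the macrostate is empty or holds no indexed frames.
    """
    rng = np.random.default_rng(seed)
    members_active = np.flatnonzero(macromodel.assignments == state)
    if members_active.size == 0:
        raise ValueError(f"macrostate {state} has no microstates")
    micro_full = msmodel.active_set[members_active]
    weights = msmodel.stationary[members_active]
    usable = np.array([len(frame_index.get(int(m), [])) > 0
                       for m in micro_full])
    if not usable.any():
        raise ValueError(f"macrostate {state} has no indexed frames")
    micro_full = micro_full[usable]
    weights = weights[usable]
    weights = weights / weights.sum()
    picks = rng.choice(len(micro_full), size=n, p=weights)
    out = []
    for p in picks:
        frames = frame_index[int(micro_full[p])]
        out.append(frames[rng.integers(len(frames))])
    return out


def occupancy_table(ensembles: dict, sites: list[SiteDefinition]) -> pd.DataFrame:
    """Empirical ion occupancy frequency per macrostate and binding site.

    ``ensembles`` maps state label -> list of (n_ions, 3) ion coordinate
    arrays (one per conformation).  The frequency is the fraction of
    conformations with at least one ion center inside the site sphere.
    """
    if not sites:
        raise ValueError("no sites given")
    rows = {}
    for state, confs in ensembles.items():
        freqs = []
        for site in sites:
            c = np.asarray(site.center, dtype=float)
            hits = 0
            for ions in confs:
                ions = np.asarray(ions, dtype=float).reshape(-1, 3)
                if ions.size and (np.linalg.norm(ions - c, axis=1)
                                  <= site.radius).any():
                    hits += 1
            freqs.append(hits / len(confs))
        rows[state] = freqs
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[s.name for s in sites])


def ramachandran_density(phi, psi, weights=None, bins: int = 60,
                         contour_mass=(0.5, 0.8, 0.95)):
    """Weighted 2-D dihedral probability mass on the torus.

    Angles are wrapped to [-180, 180) before binning, so +-360 degree
    shifts leave the density unchanged.  Returns ``(H, edges, levels)``
    where H sums to 1 and ``levels[m]`` is the density level whose
    superlevel set carries probability mass m (for contour drawing).
    """
    from .featurize import wrap_degrees

    phi = wrap_degrees(np.ravel(phi))
    psi = wrap_degrees(np.ravel(psi))
    w = None if weights is None else np.ravel(weights)
    H, xe, ye = np.histogram2d(phi, psi, bins=bins,
                               range=[[-180, 180], [-180, 180]], weights=w)
    total = H.sum()
    if total <= 0:
        raise ValueError("empty or zero-weight input")
    H = H / total
    flat = np.sort(H.ravel())[::-1]
    cum = np.cumsum(flat)
    levels = {}
    for m in contour_mass:
        j = int(np.searchsorted(cum, m))
        levels[m] = float(flat[min(j, len(flat) - 1)])
    return H, (xe, ye), levels
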