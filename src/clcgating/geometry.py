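"""Analytic structural fixtures: pore geometries, ion ensembles, peptides.

These generators provide ground truth for the structural analyses: pore
fixtures are rings of spherical atoms around the z-axis whose true
maximal-inscribed-sphere radius is known in closed form; ion fixtures
place ions in binding-site spheres with prescribed Bernoulli occupancy;
the peptide builder places backbone/side-chain atoms at prescribed
internal coordinates (NeRF construction) so dihedral featurization can be
checked against its inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["PoreFixture", "make_pore_fixture", "make_ion_fixture",
           "build_chain", "write_pore_pdb"]


@dataclass
class PoreFixture:
    """Atom coordinates + radii with the analytic pore-radius profile."""

    coords: np.ndarray  # (N, 3)
    radii: np.ndarray  # (N,)
    kind: str
    params: dict

    def true_radius(self, z):
        """Analytic pore radius of the generating surface at height z.

        For the cylinder this is ``ring_radius - atom_radius`` everywhere.
        For the hourglass the on-axis inscribed sphere may be tangent to
        the sloping wall above or below the slice, so the exact radius is
        the minimum over wall height z' of

            sqrt(r(z')^2 + (z'-z)^2) - atom_radius,

        with generating curve r(z') = (waist + atom_radius) +
        curvature * z'^2; the minimum is evaluated on a fine offset grid.
        At the waist (z=0) it reduces to exactly ``waist``.
        """
        z = np.asarray(z, dtype=float)
        p = self.params
        if self.kind == "cylinder":
            return np.full_like(z, p["ring_radius"] - p["atom_radius"])
        if self.kind == "hourglass":
            delta = np.linspace(-10.0, 10.0, 4001)
            ring = (p["waist"] + p["atom_radius"]) + \
                p["curvature"] * (z[..., None] + delta) ** 2
            dist = np.sqrt(ring**2 + delta**2)
            return dist.min(axis=-1) - p["atom_radius"]
        raise ValueError(f"no closed form for kind {self.kind!r}")


def _rings(z_values, ring_radii, atoms_per_ring, atom_radius):
    coords = []
    for z, rr in zip(z_values, ring_radii):
        ang = np.linspace(0, 2 * np.pi, atoms_per_ring, endpoint=False)
        ring = np.stack([rr * np.cos(ang), rr * np.sin(ang),
                         np.full(atoms_per_ring, z)], axis=1)
        coords.append(ring)
    coords = np.vstack(coords)
    return coords, np.full(len(coords), atom_radius)


def make_pore_fixture(kind: str, ring_radius: float = 4.5,
                      atom_radius: float = 1.5, length: float = 20.0,
                      waist: float = 1.5, curvature: float = 0.05,
                      z_step: float = 0.5, atoms_per_ring: int = 24,
                      block_z: float = 0.0) -> PoreFixture:
    """Build an analytic channel geometry.

    kinds
    -----
    ``cylinder``
        Rings of radius ``ring_radius``; true pore radius is
        ``ring_radius - atom_radius`` everywhere.
    ``hourglass``
        Ring radius ``(waist + atom_radius) + curvature * z**2``; the true
        pore radius is ``waist + curvature * z**2`` with minimum ``waist``
        at z=0.
    ``blocked``
        A cylinder with one extra on-axis atom at ``block_z``; the slice
        through that atom is impassable (radius <= 0).
    """
    for name, v in (("ring_radius", ring_radius), ("atom_radius", atom_radius),
                    ("length", length), ("waist", waist), ("z_step", z_step)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    z = np.arange(-length / 2, length / 2 + 1e-9, z_step)
    if kind == "cylinder":
        coords, radii = _rings(z, np.full_like(z, ring_radius),
                               atoms_per_ring, atom_radius)
        params = {"ring_radius": ring_radius, "atom_radius": atom_radius}
    elif kind == "hourglass":
        ring = (waist + atom_radius) + curvature * z**2
        coords, radii = _rings(z, ring, atoms_per_ring, atom_radius)
        params = {"waist": waist, "curvature": curvature,
                  "atom_radius": atom_radius}
    elif kind == "blocked":
        coords, radii = _rings(z, np.full_like(z, ring_radius),
                               atoms_per_ring, atom_radius)
        coords = np.vstack([coords, [[0.0, 0.0, block_z]]])
        radii = np.append(radii, atom_radius)
        params = {"ring_radius": ring_radius, "atom_radius": atom_radius,
                  "block_z": block_z}
    else:
        raise ValueError(f"unknown pore fixture kind {kind!r}")
    return PoreFixture(coords=coords, radii=radii, kind=kind, params=params)


def write_pore_pdb(fixture: PoreFixture, pdb_path, radii_csv_path=None) -> None:
    """Write the fixture as a PDB (carbon HETATMs) + sidecar radii CSV."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(fixture.coords)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(fixture.coords, dtype=np.float32)
    atoms.atom_name = np.array(["C"] * n)
    atoms.element = np.array(["C"] * n)
    atoms.res_name = np.array(["POR"] * n)
    atoms.res_id = np.arange(1, n + 1)
    atoms.chain_id = np.array(["A"] * n)
    atoms.hetero = np.array([True] * n)
    f = PDBFile()
    f.set_structure(atoms)
    f.write(str(pdb_path))
    if radii_csv_path is not None:
        import pandas as pd
        pd.DataFrame({"atom_index": np.arange(n),
                      "radius_angstrom": fixture.radii}).to_csv(
            radii_csv_path, index=False)


def make_ion_fixture(site_centers: dict, occupancy_probs: dict,
                     n_samples: int = 1000, site_radius: float = 2.5,
                     seed: int = 0) -> dict:
    """Per-state conformation ensembles with stochastic ion placement.

    Parameters
    ----------
    site_centers
        Mapping site name -> (3,) center coordinates.
    occupancy_probs
        Mapping state label -> {site name: probability in [0, 1]} that a
        conformation of that state holds an ion in the site.
    site_radius
        Ions are placed uniformly inside a sphere of this radius around
        the site center.

    Returns
    -------
    dict state -> list of (n_ions_i, 3) ion-coordinate arrays, one per
    sampled conformation.

    Warns if two site spheres overlap (occupancies may correlate in a
    real analysis; here sites are still sampled independently).
    """
    names = list(site_centers)
    centers = np.array([site_centers[s] for s in names], dtype=float)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            if np.linalg.norm(centers[a] - centers[b]) < 2 * site_radius:
                warnings.warn(
                    f"sites {names[a]} and {names[b]} overlap; "
                    "occupancies may correlate", stacklevel=2)
    rng = np.random.default_rng(seed)
    out = {}
    for state, probs in occupancy_probs.items():
        bad = [s for s, p in probs.items() if not 0 <= p <= 1]
        if bad:
            raise ValueError(f"probabilities outside [0,1] for sites {bad}")
        ensembles = []
        for _ in range(n_samples):
            ions = []
            for s in names:
                p = probs.get(s, 0.0)
                if rng.random() < p:
                    # uniform in the sphere: rejection-free radial sampling
                    direction = rng.normal(size=3)
                    direction /= np.linalg.norm(direction)
                    r = site_radius * rng.random() ** (1 / 3)
                    ions.append(site_centers[s] + r * direction)
            ensembles.append(np.array(ions).reshape(-1, 3))
        out[state] = ensembles
    return out


# -- internal-coordinate chain construction (NeRF) --------------------------

def _place_atom(a, b, c, bond: float, angle_deg: float,
                dihedral_deg: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates."""
    angle = np.deg2rad(angle_deg)
    dihed = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(angle),
                        bond * np.sin(angle) * np.cos(dihed),
                        bond * np.sin(angle) * np.sin(dihed)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain(internal) -> np.ndarray:
    """Build Cartesian coordinates from internal-coordinate rows.

    ``internal`` is a list of (bond, angle_deg, dihedral_deg) tuples; the
    first three atoms are seeded canonically, each later atom is placed
    relative to the three preceding ones.  The dihedral passed for atom i
    is exactly the signed dihedral of atoms (i-3, i-2, i-1, i).
    """
    coords = [np.array([0.0, 0.0, 0.0])]
    if len(internal) >= 1:
        b0 = internal[0][0]
        coords.append(np.array([b0, 0.0, 0.0]))
    if len(internal) >= 2:
        b1, a1 = internal[1][0], np.deg2rad(internal[1][1])
        coords.append(coords[1] + np.array([-b1 * np.cos(a1),
                                            b1 * np.sin(a1), 0.0]))
    for bond, angle, dihed in internal[2:]:
        coords.append(_place_atom(coords[-3], coords[-2], coords[-1],
                                  bond, angle, dihed))
    return np.array(coords)
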