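"""Signed dihedral featurization of channel structures.

Angle conventions
-----------------
All dihedrals are signed, in degrees, wrapped to the half-open interval
[-180, 180), with the sign given by the right-hand rule about the central
(p2->p3) bond axis.  phi(i) is C(i-1)-N(i)-CA(i)-C(i); psi(i) is
N(i)-CA(i)-C(i)-N(i+1); chi angles follow the IUPAC side-chain atom
quadruples.  Backbone feature names encode the two residues the dihedral
spans ("psi:I170-G169" is psi of G169, whose fourth atom is the amide
nitrogen of I170); side-chain names carry one residue ("chi1:E211").
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import SF_RESIDUES

logger = logging.getLogger(__name__)

__all__ = ["dihedral", "wrap_degrees", "ResidueSpec", "FeatureMatrix",
           "featurize_trajectory", "load_features", "write_features"]

FEATURES_FORMAT_HEADER = "# clcgating-features v1"

#: chi1/chi2 atom quadruples by residue (three-letter code).  chi1 is
#: N-CA-CB-XG; chi2 is CA-CB-XG-XD.  Residues not listed lack the angle.
CHI1_ATOMS = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}
CHI2_ATOMS = {
    "ARG": ("CG", "CD"), "ASN": ("CG", "OD1"), "ASP": ("CG", "OD1"),
    "GLN": ("CG", "CD"), "GLU": ("CG", "CD"), "HIS": ("CG", "ND1"),
    "ILE": ("CG1", "CD1"), "LEU": ("CG", "CD1"), "LYS": ("CG", "CD"),
    "MET": ("CG", "SD"), "PHE": ("CG", "CD1"), "PRO": ("CG", "CD"),
    "TRP": ("CG", "CD1"), "TYR": ("CG", "CD1"),
}
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def wrap_degrees(angle):
    """Wrap angles (degrees) to the half-open interval [-180, 180)."""
    return np.mod(np.asarray(angle) + 180.0, 360.0) - 180.0


def dihedral(p1, p2, p3, p4, degenerate_tol: float = 1e-10) -> float:
    """Signed dihedral angle (degrees) of four points, in [-180, 180).

    The sign follows the right-hand rule about the p2->p3 axis: looking
    down that axis, a positive angle rotates the p1 projection
    counter-clockwise onto the p4 projection.

    Raises
    ------
    ValueError
        If consecutive points coincide or a bonded triple is collinear
        (the plane normals vanish); the message names the offending triple.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for i, b in enumerate((b1, b2, b3)):
        if np.dot(b, b) < degenerate_tol**2:
            raise ValueError(f"coincident points p{i + 1} and p{i + 2}")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.dot(n1, n1) < degenerate_tol**2:
        raise ValueError("collinear triple (p1, p2, p3)")
    if np.dot(n2, n2) < degenerate_tol**2:
        raise ValueError("collinear triple (p2, p3, p4)")
    b2n = b2 / np.linalg.norm(b2)
    m1 = np.cross(b2n, n1)
    ang = np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    return float(wrap_degrees(ang))


@dataclass(frozen=True)
class ResidueSpec:
    """Which residues and dihedral kinds to featurize.

    The default residue set is the 17 selectivity-filter residues of
    rCLC-2.  Residues lacking a requested side-chain angle (e.g. glycine
    chi1) are dropped from that angle kind with a logged notice.
    """

    residues: tuple[int, ...] = SF_RESIDUES
    kinds: tuple[str, ...] = ("phi", "psi", "chi1", "chi2")

    def __post_init__(self):
        bad = set(self.kinds) - {"phi", "psi", "chi1", "chi2"}
        if bad:
            raise ValueError(f"unknown angle kinds: {sorted(bad)}")


@dataclass
class FeatureMatrix:
    """A per-trajectory T x F array of signed dihedral angles (degrees).

    Attributes
    ----------
    values : (T, F) float array, every entry in [-180, 180), no NaN.
    names : unique feature column names.
    traj_id : trajectory identifier.
    frame_time : physical time per frame, arbitrary units (ns by default
        convention in this package).
    """

    values: np.ndarray
    names: list[str]
    traj_id: str = "traj"
    frame_time: float = 1.0

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values))
        if self.values.shape[1] != len(self.names):
            raise ValueError("column count does not match names")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite angle values")
        if self.values.size and (self.values.min() < -180.0
                                 or self.values.max() >= 180.0):
            raise ValueError("angles outside [-180, 180)")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)


def _atom_lookup(array, res_id: int, atom_name: str):
    mask = (array.res_id == res_id) & (array.atom_name == atom_name)
    idx = np.flatnonzero(mask)
    return int(idx[0]) if idx.size else None


def featurize_trajectory(structure, spec: ResidueSpec | None = None,
                         traj_id: str = "traj",
                         frame_time: float = 1.0) -> FeatureMatrix:
    """Compute the dihedral FeatureMatrix of a multi-model structure.

    Parameters
    ----------
    structure
        A biotite ``AtomArrayStack`` (or single ``AtomArray``), or a path
        to a (multi-model) PDB file.
    spec
        Residues and angle kinds; defaults to the 17 SF residues with all
        four kinds.  Column order is residue-major, angle-kind-minor.

    Raises
    ------
    ValueError
        If a required backbone atom is missing (message names residue and
        atom).  Missing side-chain atoms only drop that chi column, with
        a logged notice.
    """
    import biotite.structure as struc

    if isinstance(structure, (str, Path)):
        from biotite.structure.io.pdb import PDBFile
        structure = PDBFile.read(str(structure)).get_structure()
    if not isinstance(structure, struc.AtomArrayStack):
        structure = struc.stack([structure])
    spec = spec or ResidueSpec()

    template = structure[0]
    present = set(template.res_id.tolist())
    columns: list[tuple[str, tuple[int, int, int, int]]] = []

    def resname(rid):
        return template.res_name[np.flatnonzero(template.res_id == rid)[0]]

    def short(rid):
        return THREE_TO_ONE.get(resname(rid), "X") + str(rid)

    for r in spec.residues:
        if r not in present:
            raise ValueError(f"residue {r} missing from structure")
        rn = resname(r)
        for kind in spec.kinds:
            if kind == "phi":
                if r - 1 not in present:
                    logger.info("phi of residue %d skipped: no predecessor", r)
                    continue
                quad = [(r - 1, "C"), (r, "N"), (r, "CA"), (r, "C")]
                name = f"phi:{short(r)}-{short(r - 1)}"
            elif kind == "psi":
                if r + 1 not in present:
                    logger.info("psi of residue %d skipped: no successor", r)
                    continue
                quad = [(r, "N"), (r, "CA"), (r, "C"), (r + 1, "N")]
                name = f"psi:{short(r + 1)}-{short(r)}"
            elif kind == "chi1":
                if rn not in CHI1_ATOMS:
                    logger.info("chi1 of %s%d not defined; dropped", rn, r)
                    continue
                quad = [(r, "N"), (r, "CA"), (r, "CB"), (r, CHI1_ATOMS[rn])]
                name = f"chi1:{short(r)}"
            else:
                if rn not in CHI2_ATOMS:
                    logger.info("chi2 of %s%d not defined; dropped", rn, r)
                    continue
                g, d = CHI2_ATOMS[rn]
                quad = [(r, "CA"), (r, "CB"), (r, g), (r, d)]
                name = f"chi2:{short(r)}"
            idx = []
            missing = None
            for rid, an in quad:
                k = _atom_lookup(template, rid, an)
                if k is None:
                    missing = (rid, an)
                    break
                idx.append(k)
            if missing is not None:
                if kind in ("phi", "psi"):
                    raise ValueError(
                        f"missing backbone atom {missing[1]} of residue "
                        f"{missing[0]} (needed for {name})")
                logger.info("side-chain atom %s of residue %d missing; "
                            "%s dropped", missing[1], missing[0], name)
                continue
            columns.append((name, tuple(idx)))

    n_frames = structure.stack_depth()
    values = np.empty((n_frames, len(columns)))
    coords = structure.coord  # (n_frames, n_atoms, 3)
    for j, (name, (i1, i2, i3, i4)) in enumerate(columns):
        for f in range(n_frames):
            try:
                values[f, j] = dihedral(coords[f, i1], coords[f, i2],
                                        coords[f, i3], coords[f, i4])
            except ValueError as e:
                raise ValueError(f"frame {f}, feature {name}: {e}") from e
    return FeatureMatrix(values=values, names=[c[0] for c in columns],
                         traj_id=traj_id, frame_time=frame_time)


def write_features(fm: FeatureMatrix, path, precision: int = 6) -> None:
    """Write a FeatureMatrix as versioned CSV (header = feature names)."""
    path = Path(path)
    # round-then-wrap so values printed at finite precision stay in range
    vals = wrap_degrees(np.round(np.asarray(fm.values, dtype=float), precision))
    with open(path, "w", newline="\n") as fh:
        fh.write(FEATURES_FORMAT_HEADER +
                 f" traj_id={fm.traj_id} frame_time={fm.frame_time!r}\n")
        pd.DataFrame(vals, columns=fm.names).to_csv(
            fh, index=False, float_format=f"%.{precision}f")


def write_features_npz(fm: FeatureMatrix, path) -> None:
    """Write a FeatureMatrix as a compressed columnar archive (full
    precision, unlike the 6-decimal CSV)."""
    np.savez_compressed(path, schema="clcgating-features-npz v1",
                        values=fm.values, names=np.array(fm.names),
                        traj_id=fm.traj_id, frame_time=fm.frame_time)


def load_features_npz(path) -> FeatureMatrix:
    arr = np.load(path, allow_pickle=False)
    schema = str(arr["schema"])
    if schema != "clcgating-features-npz v1":
        raise ValueError(f"{path}: unsupported features schema: {schema}")
    return FeatureMatrix(values=arr["values"],
                         names=[str(n) for n in arr["names"]],
                         traj_id=str(arr["traj_id"]),
                         frame_time=float(arr["frame_time"]))


def load_features(path) -> FeatureMatrix:
    """Read a FeatureMatrix CSV written by :func:`write_features`.

    Validates the version header, the angle range, uniqueness of column
    names, and rejects empty or ragged files.
    """
    path = Path(path)
    with open(path, "r") as fh:
        first = fh.readline().strip()
        if not first.startswith("# clcgating-features"):
            raise ValueError(f"{path}: missing clcgating-features header")
        if not first.startswith(FEATURES_FORMAT_HEADER):
            raise ValueError(f"{path}: unsupported features schema: {first}")
        meta = dict(tok.split("=", 1) for tok in first.split()[2:]
                    if "=" in tok)
        try:
            df = pd.read_csv(fh)
        except pd.errors.EmptyDataError:
            raise ValueError(f"{path}: no frames (empty feature file)")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no frames")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values (ragged rows?)")
    values = df.to_numpy(dtype=float)
    if values.min() < -180.0 or values.max() >= 180.0:
        raise ValueError(f"{path}: angle outside [-180, 180)")
    return FeatureMatrix(values=values, names=list(df.columns),
                         traj_id=meta.get("traj_id", path.stem),
                         frame_time=float(meta.get("frame_time", 1.0)))
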