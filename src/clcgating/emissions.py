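"""State-conditional von Mises dihedral emissions for the SF feature set.

Each macrostate emits, independently per frame and per feature, a signed
dihedral angle from a von Mises law wrapped to [-180, 180).  Only a small
set of discriminative features differ between states, mirroring the
dynamical-mode loadings of the gating analysis:

* ``psi:I170-G169`` and ``psi:G169-S168`` separate C_oi (inner gate
  closed) from C_o/O/U (inner-gate backbone rotated);
* ``chi1:E211`` (the external-gate glutamate rotamer) takes three modes:
  one shared by C_oi/C_o, one for O, one for U;
* ``phi:S168-G167`` shifts in U and ``phi:G169-S168`` shifts in O, the
  secondary loadings of the two glutamate-flip modes.

Every other dihedral in the 17-residue x {phi, psi, chi1, chi2} set is
state-independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import SF_RESIDUES, SF_RESIDUE_NAMES, MACROSTATE_LABELS
from .featurize import FeatureMatrix, wrap_degrees

__all__ = ["EmissionModel", "default_emission_model", "emit_features",
           "DISCRIMINATIVE_FEATURES"]

#: Map feature -> {state: mean angle in degrees} for the discriminative set.
DISCRIMINATIVE_FEATURES = {
    "psi:I170-G169": {"C_oi": -45.0, "C_o": 140.0, "O": 140.0, "U": 140.0},
    "psi:G169-S168": {"C_oi": -30.0, "C_o": 120.0, "O": 120.0, "U": 120.0},
    "chi1:E211": {"C_oi": -65.0, "C_o": -65.0, "O": 65.0, "U": -160.0},
    "phi:S168-G167": {"C_oi": -60.0, "C_o": -60.0, "O": -60.0, "U": -150.0},
    "phi:G169-S168": {"C_oi": 70.0, "C_o": 70.0, "O": 150.0, "U": 70.0},
}

#: Default concentration: kappa ~= 14.6 gives a circular SD of ~15 degrees,
#: small enough that states are separable but with realistic overlap.
DEFAULT_KAPPA = 14.6

#: Residues with no chi1 (glycine) in the default name table.
_NO_CHI1 = {"G"}
#: Residues modeled without a chi2 in the default table.
_NO_CHI2 = {"G", "S", "C", "V", "T", "A"}


def _default_feature_names() -> list[str]:
    names: list[str] = []
    resseq = list(SF_RESIDUES)
    for i, r in enumerate(resseq):
        nm = SF_RESIDUE_NAMES[r]
        prev = resseq[i - 1] if i > 0 else None
        nxt = resseq[i + 1] if i < len(resseq) - 1 else None
        # phi spans the previous residue's carbonyl; named only when the
        # previous SF residue is the true sequence predecessor
        if prev is not None and prev == r - 1:
            names.append(f"phi:{nm}{r}-{SF_RESIDUE_NAMES[prev]}{prev}")
        if nxt is not None and nxt == r + 1:
            names.append(f"psi:{SF_RESIDUE_NAMES[nxt]}{nxt}-{nm}{r}")
        if nm not in _NO_CHI1:
            names.append(f"chi1:{nm}{r}")
        if nm not in _NO_CHI1 and nm not in _NO_CHI2:
            names.append(f"chi2:{nm}{r}")
    return names


@dataclass(frozen=True)
class EmissionModel:
    """Per-state circular emission laws over a named dihedral feature set.

    ``means`` has shape (n_states, n_features) in degrees; ``kappas`` the
    same shape.  Features whose mean column is state-independent are noise
    features.
    """

    state_labels: tuple[str, ...]
    feature_names: tuple[str, ...]
    means: np.ndarray
    kappas: np.ndarray

    def __post_init__(self):
        assert self.means.shape == (len(self.state_labels),
                                    len(self.feature_names))
        assert self.kappas.shape == self.means.shape

    @property
    def noise_features(self) -> tuple[str, ...]:
        same = np.all(self.means == self.means[0], axis=0)
        return tuple(np.asarray(self.feature_names)[same])

    def archetype(self, state: str) -> dict[str, float]:
        """Mean angles of the discriminative features for one state."""
        i = self.state_labels.index(state)
        return {f: float(self.means[i, j])
                for j, f in enumerate(self.feature_names)
                if f not in self.noise_features}

    def restrict(self, states: tuple[str, ...]) -> "EmissionModel":
        idx = [self.state_labels.index(s) for s in states]
        return EmissionModel(tuple(states), self.feature_names,
                             self.means[idx], self.kappas[idx])


def default_emission_model(
    protonated: bool = True,
    kappa: float = DEFAULT_KAPPA,
    seed: int = 1234,
) -> EmissionModel:
    """Construct the SF-mimetic emission model.

    Noise-feature means are drawn once (from ``seed``) from typical
    backbone/side-chain dihedral regions and shared across states.
    """
    states = MACROSTATE_LABELS if protonated else tuple(
        s for s in MACROSTATE_LABELS if s != "U")
    names = _default_feature_names()
    rng = np.random.default_rng(seed)
    means = np.empty((len(states), len(names)))
    for j, f in enumerate(names):
        if f in DISCRIMINATIVE_FEATURES:
            for i, s in enumerate(states):
                means[i, j] = DISCRIMINATIVE_FEATURES[f][s]
        else:
            kind = f.split(":")[0]
            base = {"phi": -65.0, "psi": -40.0,
                    "chi1": 60.0, "chi2": 170.0}[kind]
            m = wrap_degrees(base + rng.normal(0.0, 20.0))
            means[:, j] = m
    kappas = np.full_like(means, kappa)
    return EmissionModel(tuple(states), tuple(names), means, kappas)


def emit_features(
    paths: list[np.ndarray],
    emission: EmissionModel,
    seed: int = 0,
    state_labels: tuple[str, ...] | None = None,
    frame_time: float = 1.0,
    dtype=np.float32,
) -> list[FeatureMatrix]:
    """Draw one dihedral feature row per frame of each discrete path.

    Parameters
    ----------
    paths
        Integer state paths; values index ``state_labels`` (defaults to
        the emission model's own ordering).
    state_labels
        Label for each integer state in ``paths``; every label must exist
        in the emission model.

    Returns
    -------
    One FeatureMatrix per path, angles wrapped to [-180, 180).
    """
    labels = emission.state_labels if state_labels is None else state_labels
    try:
        state_rows = np.array([emission.state_labels.index(s) for s in labels])
    except ValueError as e:
        raise ValueError(f"state label not in emission model: {e}") from e
    rng = np.random.default_rng(seed)
    out = []
    means_rad = np.deg2rad(emission.means)
    for t, path in enumerate(paths):
        path = np.asarray(path)
        if path.min() < 0 or path.max() >= len(labels):
            raise ValueError(f"path {t} contains states outside the label set")
        rows = state_rows[path]
        mu = means_rad[rows]  # (T, F)
        kap = emission.kappas[rows]
        finite = np.isfinite(kap)
        ang = np.empty(mu.shape)
        if finite.all():
            ang = rng.vonmises(mu, kap)
        else:  # infinite concentration -> degenerate at the mean
            ang[finite] = rng.vonmises(mu[finite], kap[finite])
            ang[~finite] = mu[~finite]
        deg = wrap_degrees(np.rad2deg(ang)).astype(dtype)
        # casting can round values just below 180 up to exactly 180
        deg[deg >= 180.0] -= np.asarray(360.0, dtype=dtype)
        out.append(FeatureMatrix(values=deg,
                                 names=list(emission.feature_names),
                                 traj_id=f"traj{t:04d}",
                                 frame_time=frame_time))
    return out
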