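"""Time-lagged independent component analysis with kinetic mapping.

tICA finds linear combinations of the input features that decorrelate
most slowly: the generalized eigenproblem

    C_tau v = lambda (C_0 + eps*I) v,

where C_0 is the instantaneous covariance of the mean-free features, and
C_tau the lag-tau cross-covariance symmetrized as (C + C^T)/2 so the
spectrum is real.  Eigenvalues approximate the autocorrelation of each
component at the lag; the "kinetic map" scales each projected component
by its eigenvalue so Euclidean distances approximate kinetic distances.

The symmetrized estimator and the ridge eps (default 1e-6*tr(C0)/F, to
tolerate collinear dihedral columns) are deliberate, documented choices.
Near-degenerate eigenvalue pairs are reported with a warning; the sign of
each eigenvector is fixed by making its largest-magnitude coefficient
positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .featurize import FeatureMatrix

__all__ = ["TICAModel", "fit_tica", "transform", "top_loadings",
           "save_tica", "load_tica"]


@dataclass
class TICAModel:
    """Fitted tICA estimator.

    eigenvectors are stored column-wise and are (C0+eps*I)-orthonormal;
    eigenvalues are sorted descending.
    """

    lag: int
    mean: np.ndarray
    c0: np.ndarray
    ctau: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    ridge: float
    feature_names: list[str]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def timescales(self) -> np.ndarray:
        """Implied relaxation time (frames) of each component, -lag/ln lambda."""
        lam = np.clip(self.eigenvalues, 1e-300, 1 - 1e-12)
        return -self.lag / np.log(lam)


def _as_array(f) -> np.ndarray:
    return f.values if isinstance(f, FeatureMatrix) else np.atleast_2d(f)


def fit_tica(features, lag: int, ridge: float | None = None) -> TICAModel:
    """Estimate a tICA model over one or more trajectories.

    Parameters
    ----------
    features
        List of FeatureMatrix (or plain (T, F) arrays) sharing columns.
    lag
        Lag in frames; every trajectory must be longer than the lag.
    ridge
        Regularization added to C0; defaults to ``1e-6 * trace(C0) / F``.

    Raises
    ------
    ValueError
        For an all-constant feature (named in the message), fewer than 2
        features, or a lag not shorter than the shortest trajectory.
    """
    if isinstance(features, (FeatureMatrix, np.ndarray)):
        features = [features]
    first = np.atleast_2d(_as_array(features[0]))
    names = (features[0].names if isinstance(features[0], FeatureMatrix)
             else [f"f{i}" for i in range(first.shape[1])])
    F = first.shape[1]
    if F < 2:
        raise ValueError("tICA requires at least 2 features")
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")

    def as64(f):
        # per-trajectory float64 view/copy keeps the peak footprint at
        # one trajectory, not the whole dataset
        return np.asarray(np.atleast_2d(_as_array(f)), dtype=np.float64)

    for f in features:
        if np.atleast_2d(_as_array(f)).shape[0] <= lag:
            raise ValueError(
                f"lag {lag} is not shorter than a trajectory of "
                f"{np.atleast_2d(_as_array(f)).shape[0]} frames")

    # pass 1: mean over the frames entering the lagged pairs
    n_pairs = 0
    s = np.zeros(F)
    for f in features:
        a = as64(f)
        x0, xt = a[:-lag], a[lag:]
        n_pairs += x0.shape[0]
        s += x0.sum(axis=0) + xt.sum(axis=0)
    mean = s / (2 * n_pairs)

    c0 = np.zeros((F, F))
    ctau = np.zeros((F, F))
    for f in features:
        a = as64(f)
        x0 = a[:-lag] - mean
        xt = a[lag:] - mean
        c0 += x0.T @ x0 + xt.T @ xt
        ctau += x0.T @ xt
    c0 /= 2 * n_pairs
    ctau /= n_pairs
    ctau = 0.5 * (ctau + ctau.T)

    var = np.diag(c0)
    if np.any(var <= 1e-300):
        dead = [names[i] for i in np.flatnonzero(var <= 1e-300)]
        raise ValueError(f"all-constant feature(s): {dead}")

    eps = float(ridge) if ridge is not None else 1e-6 * np.trace(c0) / F
    lam, vec = scipy.linalg.eigh(ctau, c0 + eps * np.eye(F))
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    # deterministic sign: largest-magnitude coefficient positive
    for k in range(vec.shape[1]):
        i = np.argmax(np.abs(vec[:, k]))
        if vec[i, k] < 0:
            vec[:, k] = -vec[:, k]
    gaps = np.abs(np.diff(lam))
    close = np.flatnonzero(gaps < 1e-3 * max(1.0, abs(lam[0])))
    for i in close[:3]:
        if lam[i] > 0.1:  # only flag meaningful slow components
            warnings.warn(
                f"near-degenerate tICA eigenvalues {i} and {i + 1} "
                f"({lam[i]:.4f}, {lam[i + 1]:.4f}); their span is well "
                "defined but individual components are not",
                RuntimeWarning, stacklevel=2)
    return TICAModel(lag=lag, mean=mean, c0=c0, ctau=ctau, eigenvalues=lam,
                     eigenvectors=vec, ridge=eps, feature_names=list(names))


def transform(model: TICAModel, features, kinetic_map: bool = True):
    """Project features onto all tICs, optionally eigenvalue-scaled.

    Accepts a single FeatureMatrix/array or a list; returns projections of
    matching structure.  Feature columns must match the model.
    """
    single = isinstance(features, (FeatureMatrix, np.ndarray))
    if single:
        features = [features]
    out = []
    scale = model.eigenvalues if kinetic_map else np.ones_like(model.eigenvalues)
    for f in features:
        if isinstance(f, FeatureMatrix) and f.names != model.feature_names:
            raise ValueError("feature columns do not match the tICA model")
        a = np.asarray(_as_array(f), dtype=np.float64)
        if a.shape[1] != model.n_features:
            raise ValueError(
                f"feature dimension {a.shape[1]} does not match model "
                f"({model.n_features})")
        y = (a - model.mean) @ model.eigenvectors * scale
        out.append(y)
    return out[0] if single else out


def top_loadings(model: TICAModel, component: int,
                 threshold_sd: float = 2.0) -> pd.DataFrame:
    """Features loading a component more than ``threshold_sd`` SDs above mean.

    The loading of feature j on a component is its eigenvector coefficient;
    returned are features with ``|coeff| > mean(|coeff|) + threshold_sd *
    sd(|coeff|)``, sorted by magnitude (descending).
    """
    if component >= model.n_features:
        raise ValueError("component index out of range")
    v = model.eigenvectors[:, component]
    mag = np.abs(v)
    cut = mag.mean() + threshold_sd * mag.std()
    keep = np.flatnonzero(mag > cut)
    keep = keep[np.argsort(mag[keep])[::-1]]
    return pd.DataFrame({
        "feature": [model.feature_names[i] for i in keep],
        "coefficient": v[keep],
    })


def save_tica(model: TICAModel, prefix) -> None:
    """Serialize to ``<prefix>.json`` (metadata) + ``<prefix>.npz`` (arrays)."""
    prefix = Path(prefix)
    meta = {"schema": "clcgating-tica v1", "lag": model.lag,
            "ridge": model.ridge, "feature_names": model.feature_names}
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    np.savez(prefix.with_suffix(".npz"), mean=model.mean, c0=model.c0,
             ctau=model.ctau, eigenvalues=model.eigenvalues,
             eigenvectors=model.eigenvectors)


def load_tica(prefix) -> TICAModel:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    if meta.get("schema") != "clcgating-tica v1":
        raise ValueError(f"unsupported tICA container schema: {meta.get('schema')}")
    arr = np.load(prefix.with_suffix(".npz"))
    return TICAModel(lag=meta["lag"], mean=arr["mean"], c0=arr["c0"],
                     ctau=arr["ctau"], eigenvalues=arr["eigenvalues"],
                     eigenvectors=arr["eigenvectors"], ridge=meta["ridge"],
                     feature_names=meta["feature_names"])
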