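"""End-to-end gating analysis: generate (or load) -> tICA -> cluster ->
MSM -> PCCA+ -> rates, for both protonation conditions with a shared
tICA model and state decomposition.

The default configuration reproduces the study conditions: 200
trajectories of 2e4 frames per condition, 9.6 ns per frame, tICA and MSM
lag 28.8 ns (3 frames), 324 microstates, 100 bootstrap MSMs, macrostate
count chosen by spectral gap.  Macrostates are named by matching their
circular-mean discriminative-dihedral signatures to the emission-model
archetypes (C_oi, C_o, O, U), so downstream code and tests can refer to
states by mechanistic name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cluster as _cluster
from . import macro as _macro
from . import msm as _msm
from . import tica as _tica
from .constants import FRAME_TIME_NS, KB_KCAL, MSM_LAG_NS
from .emissions import (DISCRIMINATIVE_FEATURES, default_emission_model,
                        emit_features)
from .featurize import load_features
from .kinetics import build_reference_model, sample_ctmc

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConditionResult", "GatingStudy", "run_pipeline",
           "label_macrostates"]


@dataclass
class PipelineConfig:
    """Configuration of the full analysis; round-trips through YAML."""

    n_traj: int = 200
    n_steps: int = 20_000
    frame_time_ns: float = FRAME_TIME_NS
    tica_lag_ns: float = MSM_LAG_NS
    msm_lag_ns: float = MSM_LAG_NS
    k: int = 324
    n_boot: int = 100
    n_macrostates: int | str = "auto"
    max_macrostates: int = 6
    temperature: float = 300.0
    emission_kappa: float = 14.6
    seed: int = 1
    conditions: tuple = ("protonated", "deprotonated")
    features_path: str | None = None  # load features instead of generating
    output_dir: str | None = None  # write manifest + result tables here
    batch_size: int = 1000
    kmeans_iter: int = 300

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature

    def _lag_frames(self, lag_ns: float) -> int:
        lag = lag_ns / self.frame_time_ns
        if abs(lag - round(lag)) > 1e-9:
            raise ValueError(
                f"lag {lag_ns} ns is not an integer number of "
                f"{self.frame_time_ns} ns frames")
        return int(round(lag))

    @property
    def tica_lag_frames(self) -> int:
        return self._lag_frames(self.tica_lag_ns)

    @property
    def msm_lag_frames(self) -> int:
        return self._lag_frames(self.msm_lag_ns)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["conditions"] = tuple(d.get("conditions", ()))
        return cls(**d)


@dataclass
class ConditionResult:
    """Per-protonation-condition results of the shared decomposition."""

    condition: str
    dtrajs: list
    msmodel: _msm.MSModel
    macromodel: _macro.MacroModel
    populations: dict  # label -> stationary population
    population_sd: dict  # label -> bootstrap SD (empty if n_boot < 2)
    delta_g: dict  # label -> kcal/mol above the global minimum state
    rate_matrix_per_ns: np.ndarray | None
    network_nodes: "object" = None
    network_edges: "object" = None


@dataclass
class GatingStudy:
    config: PipelineConfig
    tica_model: _tica.TICAModel
    clustering: _cluster.Clustering
    conditions: dict  # condition name -> ConditionResult
    manifest: dict

    def condition(self, name: str) -> ConditionResult:
        return self.conditions[name]


def _circular_mean_deg(x: np.ndarray) -> float:
    a = np.deg2rad(x)
    return float(np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean())))


def label_macrostates(macromodel, dtrajs, disc_features: dict,
                      emission) -> list[str]:
    """Name macrostates by nearest emission archetype.

    ``disc_features`` maps feature name -> list of per-trajectory angle
    arrays (matching ``dtrajs``).  Each macrostate's circular-mean
    signature over those features is matched to the archetype signatures
    with a one-to-one assignment minimizing total circular distance
    sum_f (1 - cos(delta)).
    """
    from scipy.optimize import linear_sum_assignment

    mdtrajs = macromodel.macro_dtrajs(dtrajs)
    md = np.concatenate(mdtrajs)
    names = list(disc_features)
    cols = {f: np.concatenate(disc_features[f]) for f in names}
    n = macromodel.n_macrostates
    states = list(emission.state_labels)
    cost = np.zeros((n, len(states)))
    for j in range(n):
        mask = md == j
        if not mask.any():
            cost[j, :] = 1e6
            continue
        for f in names:
            m = _circular_mean_deg(cols[f][mask])
            for si, s in enumerate(states):
                target = emission.archetype(s).get(f)
                if target is not None:
                    cost[j, si] += 1 - np.cos(np.deg2rad(m - target))
    rows, colsel = linear_sum_assignment(cost)
    labels = [""] * n
    for r, c in zip(rows, colsel):
        labels[r] = states[c]
    return labels


def _sha(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> GatingStudy:
    """Run the full gating analysis under the given configuration.

    Both protonation conditions are generated (or loaded), projected with
    one tICA model, discretized with one microstate decomposition, and
    modeled with separate MSMs; the returned :class:`GatingStudy` carries
    labeled macrostate populations, free energies and rate matrices per
    condition plus a reproducibility manifest.
    """
    t0 = time.time()
    stage = "generate"
    try:
        emission = default_emission_model(protonated=True,
                                          kappa=config.emission_kappa)
        cond_feats = {}
        cond_state_labels = {}
        if config.features_path is not None:
            stage = "load-features"
            base = Path(config.features_path)
            for cond in config.conditions:
                d = base / cond
                if not d.is_dir():
                    raise FileNotFoundError(
                        f"stage {stage}: missing input directory {d}")
                files = sorted(d.glob("*.csv"))
                if not files:
                    raise FileNotFoundError(
                        f"stage {stage}: no feature CSVs under {d}")
                cond_feats[cond] = [load_features(f) for f in files]
                cond_state_labels[cond] = None
        else:
            for i, cond in enumerate(config.conditions):
                protonated = cond == "protonated"
                model = build_reference_model(protonated, config.temperature)
                paths = sample_ctmc(model, config.n_traj, config.n_steps,
                                    dt=1.0, seed=config.seed + 11 * i)
                feats = emit_features(paths, emission,
                                      seed=config.seed + 101 + 11 * i,
                                      state_labels=model.state_labels,
                                      frame_time=config.frame_time_ns)
                cond_feats[cond] = feats
                cond_state_labels[cond] = model.state_labels
                logger.info("generated %s: %d trajectories x %d frames",
                            cond, config.n_traj, config.n_steps)

        stage = "tica"
        all_feats = [f for cond in config.conditions for f in cond_feats[cond]]
        tica_model = _tica.fit_tica(all_feats, lag=config.tica_lag_frames)
        logger.info("tICA fitted: top eigenvalues %s",
                    np.round(tica_model.eigenvalues[:5], 4))

        stage = "project"
        disc_names = [f for f in DISCRIMINATIVE_FEATURES
                      if f in tica_model.feature_names]
        # one preallocated float32 block for all projections keeps the
        # peak footprint at a single copy of the dataset
        traj_lengths = [fm.n_frames for cond in config.conditions
                        for fm in cond_feats[cond]]
        total = sum(traj_lengths)
        proj_all = np.empty((total, tica_model.n_features), dtype=np.float32)
        cond_disc = {}
        cond_counts = {cond: len(cond_feats[cond])
                       for cond in config.conditions}
        row = 0
        for cond in config.conditions:
            disc = {f: [] for f in disc_names}
            for fm in cond_feats[cond]:
                n = fm.n_frames
                proj_all[row:row + n] = _tica.transform(tica_model, fm,
                                                        kinetic_map=True)
                for f in disc_names:
                    disc[f].append(fm.column(f).copy())
                fm.values = np.empty((0, len(fm.names)))  # free memory
                row += n
            cond_disc[cond] = disc
        del cond_feats, all_feats

        stage = "cluster"
        clustering = _cluster.fit_minibatch_kmeans(
            proj_all, k=config.k, batch_size=config.batch_size,
            n_iter=config.kmeans_iter, seed=config.seed + 7)
        del proj_all
        # split the flat assignment back into per-condition trajectories
        flat = clustering.assignments[0]
        bounds = np.cumsum([0] + traj_lengths)
        all_dtrajs = [flat[bounds[i]:bounds[i + 1]]
                      for i in range(len(traj_lengths))]
        clustering.assignments = all_dtrajs
        offset = 0
        cond_dtrajs = {}
        for cond in config.conditions:
            m = cond_counts[cond]
            cond_dtrajs[cond] = all_dtrajs[offset:offset + m]
            offset += m

        results = {}
        manifest_cond = {}
        for ci, cond in enumerate(config.conditions):
            stage = f"msm[{cond}]"
            dtrajs = cond_dtrajs[cond]
            lag = config.msm_lag_frames
            counts = _msm.count_transitions(dtrajs, lag, n_states=config.k)
            msmodel = _msm.mle_reversible(counts, lag=lag,
                                          frame_time=config.frame_time_ns)
            stage = f"pcca[{cond}]"
            if config.n_macrostates == "auto":
                n_macro = _macro.choose_n_macrostates(
                    msmodel, max_n=config.max_macrostates)
            else:
                n_macro = int(config.n_macrostates)
            macromodel = _macro.pcca_plus(msmodel, n_macro)
            macromodel.labels = label_macrostates(macromodel, dtrajs,
                                                  cond_disc[cond], emission)
            stage = f"rates[{cond}]"
            mdtrajs = macromodel.macro_dtrajs(dtrajs)
            K, C = _macro.estimate_rate_matrix(
                mdtrajs, lag=lag, n_states=n_macro,
                frame_time=config.frame_time_ns)
            macromodel.rate_matrix = K
            macromodel.observed_counts = C

            stage = f"bootstrap[{cond}]"
            pop_sd = {}
            if config.n_boot >= 2:
                boots = _msm.bootstrap_msms(dtrajs, lag=lag,
                                            n_boot=config.n_boot,
                                            seed=config.seed + 17 + ci,
                                            n_states=config.k,
                                            frame_time=config.frame_time_ns)
                pops = []
                for b in boots:
                    # shared decomposition: map bootstrap pi through the
                    # full-data macrostate assignment
                    lut = np.full(config.k, -1, dtype=np.int64)
                    lut[msmodel.active_set] = macromodel.assignments
                    p = np.zeros(n_macro)
                    for ai, s in enumerate(b.active_set):
                        if lut[s] >= 0:
                            p[lut[s]] += b.stationary[ai]
                    pops.append(p / p.sum())
                pop_arr = np.stack(pops)
                sd = pop_arr.std(axis=0)
                pop_sd = {macromodel.labels[j]: float(sd[j])
                          for j in range(n_macro)}

            pops = {macromodel.labels[j]: float(macromodel.populations[j])
                    for j in range(n_macro)}
            g = _msm.free_energy(macromodel.populations, config.kT)
            dg = {macromodel.labels[j]: float(g[j]) for j in range(n_macro)}
            nodes, edges = _macro.kinetic_network_summary(macromodel,
                                                          kT=config.kT)
            results[cond] = ConditionResult(
                condition=cond, dtrajs=dtrajs, msmodel=msmodel,
                macromodel=macromodel, populations=pops,
                population_sd=pop_sd, delta_g=dg,
                rate_matrix_per_ns=K, network_nodes=nodes,
                network_edges=edges)
            manifest_cond[cond] = {
                "n_macrostates": n_macro,
                "labels": macromodel.labels,
                "populations": {k_: round(v, 6) for k_, v in pops.items()},
                "dtraj_hash": _sha(np.concatenate(dtrajs)),
                "transition_matrix_hash": _sha(msmodel.transition_matrix),
            }
    except Exception as e:
        raise type(e)(f"pipeline stage {stage!r} failed: {e}") from e

    from . import __version__

    cfg_json = json.dumps(dataclasses.asdict(config), sort_keys=True,
                          default=str)
    manifest = {
        "schema": "clcgating-manifest v1",
        "version": __version__,
        "config": json.loads(cfg_json),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "seed": config.seed,
        "tica_eigenvalues": [round(float(x), 8)
                             for x in tica_model.eigenvalues[:8]],
        "cluster_centers_hash": _sha(clustering.centers),
        "conditions": manifest_cond,
    }
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True) + "\n")
        for cond, r in results.items():
            r.network_nodes.to_csv(out / f"{cond}_populations.csv",
                                   index=False)
            r.network_edges.to_csv(out / f"{cond}_rates.csv", index=False)
    logger.info("pipeline done in %.1f s", time.time() - t0)
    return GatingStudy(config=config, tica_model=tica_model,
                       clustering=clustering, conditions=results,
                       manifest=manifest)
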