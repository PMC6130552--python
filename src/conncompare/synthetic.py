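"""Synthetic two-group cohorts of coupled structural/functional data.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage is testable without scan data:

* Structural connectomes start from a Watts-Strogatz ring lattice (N nodes,
  k ring neighbors, rewiring probability beta per group). Present edges
  carry integer streamline counts at or above the 3-streamline threshold
  plus occasional sub-threshold (1-2 count) false-positive edges, and
  FA-like weights drawn from a Beta law on (0, 1).
* A "disease-like" group uses a higher rewiring probability and down-scaled
  within-module weights (modules = contiguous ring blocks), so the pipeline
  should recover higher path length and lower clustering / small-worldness /
  modularity while edge density stays matched between groups — isolating
  topology effects, which is what the density-covaried group model intends.
* Functional time series are a stable first-order diffusion recursion on
  the structural graph, x_t = c * P x_{t-1} + noise, with row-normalized
  structural weights P and coupling c in [0, 1) per group, followed by a
  short moving-average filter that emulates restriction to slow
  fluctuations (as resting-state pipelines band-pass below 0.1 Hz) and
  turns lagged network covariance into zero-lag correlation. The resulting
  functional connectivity correlates with structural communication
  structure with strength increasing in c. This is a deliberately simple
  stand-in for hemodynamics, not a BOLD model.

Everything is reproducible from one master seed; per-subject seeds are
derived deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .build import (StreamlineTable, TimeSeriesMatrix,
                    build_functional_connectome, build_structural_connectome)
from .io import (CohortManifest, Connectome, SubjectRecord, ValidationError,
                 write_manifest, write_matrix)

logger = logging.getLogger("conncompare")


@dataclass(frozen=True)
class GroupParams:
    """Per-group generator knobs."""

    beta: float = 0.1                 # Watts-Strogatz rewiring probability
    within_module_scale: float = 1.0  # FA multiplier inside ring modules
    long_range_scale: float = 1.0     # FA multiplier on long-range edges
    coupling: float = 0.5             # functional diffusion coupling c

    def __post_init__(self) -> None:
        if not 0 <= self.beta <= 1:
            raise ValidationError("beta must lie in [0, 1]")
        if not 0 <= self.coupling < 1:
            raise ValidationError("coupling must lie in [0, 1): c >= 1 is unstable")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort-level generator configuration (defaults = study-like 4v4)."""

    n_nodes: int = 32
    n_per_group: int = 4
    ring_k: int = 18          # ring neighbors: structural density ~ k/(N-1)
    edge_dropout: float = 0.06  # chance a true edge loses its streamlines
    n_modules: int = 4
    fa_beta_a: float = 6.0    # Beta(a, b) FA-like weight law, mean 0.6
    fa_beta_b: float = 4.0
    streamline_mean: float = 7.0   # present-edge counts = 3 + Poisson(mean)
    subthreshold_prob: float = 0.05  # absent pairs acquiring 1-2 count noise
    n_timepoints: int = 450
    smoothing_window: int = 5  # moving-average width (slow-fluctuation band)
    global_demean: bool = True  # remove the across-region mean per timepoint
    noise_sd: float = 1.0
    group_a: GroupParams = field(default_factory=GroupParams)
    group_b: GroupParams = field(default_factory=GroupParams)
    group_names: tuple[str, str] = ("NTG", "TG")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ring_k >= self.n_nodes:
            raise ValidationError("ring_k must be smaller than n_nodes")


def null_config(seed: int = 0, **overrides) -> SyntheticCohortConfig:
    """Both groups statistically exchangeable (type-I-error conditions)."""
    return SyntheticCohortConfig(seed=seed, **overrides)


def fad_like_config(effect: str = "large", seed: int = 0,
                    **overrides) -> SyntheticCohortConfig:
    """Disease-like group B: more ring rewiring and weakened long-range
    weights (less clustered topology yet costlier weighted paths) plus
    stronger structure-function coupling (hyper-correlation)."""
    presets = {
        "large": (GroupParams(coupling=0.45),
                  GroupParams(beta=0.85, long_range_scale=0.35, coupling=0.85)),
        "moderate": (GroupParams(coupling=0.5),
                     GroupParams(beta=0.4, long_range_scale=0.6, coupling=0.7)),
    }
    if effect not in presets:
        raise ValidationError(f"unknown effect preset {effect!r}")
    gp_a, gp_b = presets[effect]
    return SyntheticCohortConfig(group_a=gp_a, group_b=gp_b, seed=seed,
                                 **overrides)


def _module_of(config: SyntheticCohortConfig) -> np.ndarray:
    block = config.n_nodes // config.n_modules
    return np.minimum(np.arange(config.n_nodes) // block, config.n_modules - 1)


def gen_structural(
    config: SyntheticCohortConfig,
    group: str,
    subject_index: int,
    seed: int,
) -> StreamlineTable:
    """Streamline-count and mean-FA tables for one synthetic subject."""
    params = (config.group_a if group == config.group_names[0]
              else config.group_b)
    rng = np.random.default_rng(seed)
    g = nx.watts_strogatz_graph(config.n_nodes, config.ring_k, params.beta,
                                seed=int(rng.integers(2**31)))
    n = config.n_nodes
    counts = np.zeros((n, n), dtype=int)
    fa = np.zeros((n, n))
    module = _module_of(config)
    for i, j in g.edges():
        if rng.random() < config.edge_dropout:
            # tractography false negative: too few streamlines survive
            c = int(rng.integers(0, 3))
            if c == 0:
                continue
        else:
            c = 3 + rng.poisson(config.streamline_mean)
        w = rng.beta(config.fa_beta_a, config.fa_beta_b)
        if module[i] == module[j]:
            w *= params.within_module_scale
        ring_dist = min(abs(i - j), n - abs(i - j))
        if ring_dist > config.ring_k // 2:
            # long-range (shortcut) connection: weakened in disease-like groups
            w *= params.long_range_scale
        w = min(max(w, 1e-6), 1.0)
        counts[i, j] = counts[j, i] = c
        fa[i, j] = fa[j, i] = w
    # sub-threshold false-positive streamlines on a few absent pairs
    iu, ju = np.triu_indices(n, k=1)
    absent = counts[iu, ju] == 0
    noise = absent & (rng.random(iu.size) < config.subthreshold_prob)
    for i, j in zip(iu[noise], ju[noise]):
        counts[i, j] = counts[j, i] = int(rng.integers(1, 3))
        w = 0.05 + 0.3 * rng.random()
        fa[i, j] = fa[j, i] = w
    sid = f"{group}{subject_index + 1}"
    return StreamlineTable(counts, fa, subject_id=sid)


def gen_functional(
    sc: Connectome,
    config: SyntheticCohortConfig,
    group: str,
    subject_index: int,
    seed: int,
    burn_in: int = 50,
) -> TimeSeriesMatrix:
    """Diffusion-coupled time series on a structural connectome."""
    params = (config.group_a if group == config.group_names[0]
              else config.group_b)
    c = params.coupling
    w = sc.matrix
    row = w.sum(axis=1)
    if (row == 0).any():
        raise ValidationError("structural connectome has an isolated node")
    p = w / row[:, None]
    rng = np.random.default_rng(seed)
    n, t_len = sc.n_nodes, config.n_timepoints
    win = max(1, int(config.smoothing_window))
    n_raw = t_len + win - 1
    x = rng.normal(0.0, config.noise_sd, size=n)
    raw = np.empty((n, n_raw))
    for t in range(burn_in + n_raw):
        x = c * (p @ x) + rng.normal(0.0, config.noise_sd, size=n)
        if t >= burn_in:
            raw[:, t - burn_in] = x
    if win > 1:
        kernel = np.ones(win) / win
        series = np.vstack([np.convolve(row, kernel, mode="valid")
                            for row in raw])
    else:
        series = raw
    if config.global_demean:
        # analogous to global-component removal in resting-state pipelines:
        # without it a diffusion network's shared mode swamps pair structure
        series = series - series.mean(axis=0, keepdims=True)
    sid = f"{group}{subject_index + 1}"
    return TimeSeriesMatrix(series, subject_id=sid)


@dataclass
class SyntheticSubject:
    id: str
    group: str
    streamlines: StreamlineTable
    timeseries: TimeSeriesMatrix
    structural: Connectome
    functional: Connectome


def gen_cohort(
    config: SyntheticCohortConfig,
    out_dir: str | Path | None = None,
) -> tuple[CohortManifest, list[SyntheticSubject]]:
    """Generate the full two-group cohort (optionally written to disk).

    Subject seeds are spawned deterministically from the master seed, so the
    same configuration always yields byte-identical outputs.
    """
    ss = np.random.SeedSequence(config.seed)
    n_subj = 2 * config.n_per_group
    children = ss.spawn(n_subj)
    subjects: list[SyntheticSubject] = []
    records: list[SubjectRecord] = []
    idx = 0
    for group in config.group_names:
        for k in range(config.n_per_group):
            s_struct, s_func = children[idx].spawn(2)
            seed_s = int(s_struct.generate_state(1)[0] % 2**31)
            seed_f = int(s_func.generate_state(1)[0] % 2**31)
            st = gen_structural(config, group, k, seed_s)
            sc = build_structural_connectome(st)
            ts = gen_functional(sc, config, group, k, seed_f)
            fc = build_functional_connectome(ts)
            sid = st.subject_id
            subjects.append(SyntheticSubject(sid, group, st, ts, sc, fc))
            records.append(SubjectRecord(sid, group, {}))
            idx += 1
    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()):
            raise ValidationError(f"output directory {out_dir} is not empty")
        out_dir.mkdir(parents=True, exist_ok=True)
        for subj, rec in zip(subjects, records):
            paths = {
                "structural": out_dir / f"{subj.id}_structural.csv",
                "functional": out_dir / f"{subj.id}_functional.csv",
            }
            write_matrix(subj.structural, paths["structural"])
            write_matrix(subj.functional, paths["functional"])
            np.savetxt(out_dir / f"{subj.id}_timeseries.csv",
                       subj.timeseries.data, delimiter=",", fmt="%.10g")
            rec.paths = paths
        manifest = CohortManifest(records)
        write_manifest(manifest, out_dir / "manifest.yaml")
    else:
        manifest = CohortManifest(records)
    return manifest, subjects
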