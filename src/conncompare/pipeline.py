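"""End-to-end orchestration of the two-group connectome comparison.

Stage order is fixed: load/build connectomes -> minimum connection density
-> density-grid metric curves (binarized) -> small-world range + crossover
windows -> windowed AUC permutation tests -> weighted-network metric panel
with density-covaried GLM -> power-law degree-distribution fits and group
comparison -> NBS / FDR regional contrasts -> structure-function coupling.
Every stochastic stage derives its seed from the run seed, so a rerun with
the same configuration reproduces every number.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import density as dens
from . import metrics as gm
from . import nbs as nbsmod
from . import powerlaw as plmod
from . import stats as gs
from . import structfunc as sf
from .io import (CohortManifest, Connectome, DensityWindow, ValidationError,
                 density_grid, load_manifest, read_matrix)

logger = logging.getLogger("conncompare")


@dataclass
class RunConfig:
    """Parameters of a full pipeline run (defaults = study conditions)."""

    grid_step: float = 0.01
    max_density: float = 0.5
    n_random: int = 20
    n_perm: int = 2000
    n_restarts: int = 100
    nbs_threshold: float = 3.0
    measure_subsets: tuple[str, ...] = ("default", "all")
    sw_rule: str = "mean"
    seed: int = 0
    out_dir: Path | None = None


@dataclass
class Cohort:
    """In-memory two-group cohort of per-subject connectomes."""

    ids: list[str]
    groups: list[str]
    structural: dict[str, Connectome] = field(default_factory=dict)
    functional: dict[str, Connectome] = field(default_factory=dict)

    @property
    def group_names(self) -> list[str]:
        return list(dict.fromkeys(self.groups))

    def ids_in(self, group: str) -> list[str]:
        return [i for i, g in zip(self.ids, self.groups) if g == group]

    @classmethod
    def from_manifest(cls, manifest: CohortManifest | str | Path) -> "Cohort":
        if not isinstance(manifest, CohortManifest):
            manifest = load_manifest(manifest)
        cohort = cls(ids=[s.id for s in manifest.subjects],
                     groups=[s.group for s in manifest.subjects])
        for s in manifest.subjects:
            for modality, path in s.paths.items():
                conn = read_matrix(path, modality=modality, subject_id=s.id)
                getattr(cohort, modality)[s.id] = conn
        return cohort

    @classmethod
    def from_subjects(cls, subjects) -> "Cohort":
        cohort = cls(ids=[s.id for s in subjects],
                     groups=[s.group for s in subjects])
        for s in subjects:
            cohort.structural[s.id] = s.structural
            cohort.functional[s.id] = s.functional
        return cohort


@dataclass
class PipelineResult:
    min_density: dict[str, float]
    windows: dict[str, DensityWindow]
    crossover: float | None
    curves: dict[str, dict[str, dict[str, object]]]
    auc_tests: pd.DataFrame
    min_density_tests: pd.DataFrame
    weighted_glm: pd.DataFrame
    powerlaw_fits: pd.DataFrame
    powerlaw_comparison: pd.DataFrame
    nbs_results: pd.DataFrame
    fdr_results: pd.DataFrame
    coupling: pd.DataFrame
    coupling_tests: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "auc_tests": self.auc_tests,
            "min_density_tests": self.min_density_tests,
            "weighted_glm": self.weighted_glm,
            "powerlaw_fits": self.powerlaw_fits,
            "powerlaw_comparison": self.powerlaw_comparison,
            "nbs": self.nbs_results,
            "fdr": self.fdr_results,
            "coupling": self.coupling,
            "coupling_tests": self.coupling_tests,
        }


def _subject_seed(base: int, *tags: str) -> int:
    digests = [zlib.crc32(t.encode()) for t in tags]
    h = np.random.SeedSequence([base] + digests)
    return int(h.generate_state(1)[0] % 2**31)


GRID_METRICS = ("lambda", "gamma", "sigma", "Q", "Eglob", "Eloc")


def structural_density_analysis(
    cohort: Cohort, config: RunConfig
) -> tuple[float, dict[str, dict[str, object]], DensityWindow, float | None,
           pd.DataFrame]:
    """Density-grid metric curves and windowed AUC permutation tests."""
    conns = [cohort.structural[i] for i in cohort.ids]
    scan_grid = density_grid(config.grid_step, 1.0, config.grid_step)
    d_min = dens.minimum_connection_density(conns, scan_grid)
    grid = density_grid(d_min, config.max_density, config.grid_step)
    curves: dict[str, dict[str, object]] = {}
    for sid in cohort.ids:
        curves[sid] = gm.metrics_over_grid(
            cohort.structural[sid], grid, metrics=GRID_METRICS, binarize=True,
            n_random=config.n_random,
            seed=_subject_seed(config.seed, "grid", sid),
            n_restarts=config.n_restarts,
        )
    ga, gb = cohort.group_names
    sigma_all = [curves[sid]["sigma"] for sid in cohort.ids]
    window_full = dens.small_world_density_range(
        sigma_all, d_min, config.max_density, rule=config.sw_rule)
    mean_a = dens.group_mean_curve([curves[i]["sigma"] for i in cohort.ids_in(ga)])
    mean_b = dens.group_mean_curve([curves[i]["sigma"] for i in cohort.ids_in(gb)])
    crossover = dens.find_crossover(mean_a, mean_b)
    windows = {"full": window_full}
    if crossover is not None and window_full.d_lo < crossover < window_full.d_hi:
        windows["lower"] = DensityWindow(window_full.d_lo, crossover)
        windows["upper"] = DensityWindow(crossover, window_full.d_hi)
    rows = []
    for metric in GRID_METRICS:
        ca = [curves[i][metric] for i in cohort.ids_in(ga)]
        cb = [curves[i][metric] for i in cohort.ids_in(gb)]
        for wname, win in windows.items():
            res = gs.auc_permutation_test(
                ca, cb, win, n_perm=config.n_perm,
                seed=_subject_seed(config.seed, "auc", metric, wname))
            rows.append({"metric": metric, "window": wname,
                         "d_lo": win.d_lo, "d_hi": win.d_hi,
                         "observed_diff": res.observed, "p": res.p_value})
    return d_min, curves, window_full, crossover, pd.DataFrame(rows)


def functional_min_density_analysis(
    cohort: Cohort, config: RunConfig
) -> tuple[float, pd.DataFrame]:
    """Group contrasts at the functional minimum connection density.

    Subjects without small-world organization (sigma <= 1) at that density
    are excluded before the t tests.
    """
    conns = [cohort.functional[i] for i in cohort.ids]
    scan_grid = density_grid(config.grid_step, 1.0, config.grid_step)
    d_min = dens.minimum_connection_density(conns, scan_grid)
    panels: dict[str, gm.MetricSet] = {}
    for sid in cohort.ids:
        thr = dens.threshold_at_density(cohort.functional[sid], d_min,
                                        binarize=True)
        panels[sid] = gm.compute_metric_set(
            thr.matrix, weighted=False, n_random=config.n_random,
            seed=_subject_seed(config.seed, "fmin", sid),
            n_restarts=config.n_restarts)
    report = gs.small_world_filter(
        {sid: panels[sid].sigma for sid in cohort.ids},
        dict(zip(cohort.ids, cohort.groups)))
    ga, gb = cohort.group_names
    rows = []
    for metric in ("lambda_norm", "gamma_norm", "sigma", "e_glob", "e_loc", "q"):
        va = [getattr(panels[i], metric) for i in report.included[ga]]
        vb = [getattr(panels[i], metric) for i in report.included[gb]]
        t, p = gs.two_sample_t(np.array(va), np.array(vb))
        rows.append({"metric": metric, "t": t, "p": p,
                     "n_a": len(va), "n_b": len(vb),
                     "excluded": ",".join(sum(report.excluded.values(), []))})
    return d_min, pd.DataFrame(rows)


def weighted_network_analysis(
    cohort: Cohort, config: RunConfig, modality: str = "structural",
    sw_exclude: bool = False,
) -> tuple[pd.DataFrame, dict[str, gm.MetricSet]]:
    """Weighted (unthresholded) metric panel + density-covaried GLM.

    ``sw_exclude`` drops subjects whose weighted network is not small-world
    (sigma <= 1) before the GLM — used for functional networks, where such
    subjects occur; weighted structural networks are analysed in full.
    """
    conns = getattr(cohort, modality)
    panels = {
        sid: gm.compute_metric_set(
            conns[sid].matrix, weighted=True, n_random=config.n_random,
            seed=_subject_seed(config.seed, "wt", modality, sid),
            n_restarts=config.n_restarts)
        for sid in cohort.ids
    }
    if sw_exclude:
        report = gs.small_world_filter(
            {sid: panels[sid].sigma for sid in cohort.ids},
            dict(zip(cohort.ids, cohort.groups)))
        kept = sum(report.included.values(), [])
        excluded = ",".join(sum(report.excluded.values(), []))
    else:
        kept = list(cohort.ids)
        excluded = ""
    groups = np.array([dict(zip(cohort.ids, cohort.groups))[i] for i in kept])
    densities = np.array([conns[i].density for i in kept])
    rows = []
    for metric in ("lambda_norm", "gamma_norm", "sigma", "e_glob", "e_loc", "q",
                   "l_raw", "c_raw"):
        vals = np.array([getattr(panels[i], metric) for i in kept])
        res = gs.glm_group_test(vals, groups, densities)
        rows.append({"modality": modality, "metric": metric,
                     "F": res.f_statistic, "p": res.p_value,
                     "group_coef": res.params[1], "df_resid": res.df_resid,
                     "excluded": excluded})
    return pd.DataFrame(rows), panels


def powerlaw_analysis(
    cohort: Cohort, config: RunConfig, min_densities: dict[str, float]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject power-law tail fits + between-group fit comparison.

    Weighted networks use node strength with the continuous MLE; networks
    thresholded to minimum density use integer degree with the discrete MLE.
    """
    fit_rows, cmp_rows = [], []
    ga, gb = cohort.group_names
    for modality in ("structural", "functional"):
        conns = getattr(cohort, modality)
        for kind in ("weighted", "min_density"):
            fits: dict[str, plmod.PowerLawFit] = {}
            for sid in cohort.ids:
                if kind == "weighted":
                    vals = gm.strengths(conns[sid].matrix)
                    discrete = False
                else:
                    thr = dens.threshold_at_density(
                        conns[sid], min_densities[modality], binarize=True)
                    vals = gm.degrees(thr.matrix)
                    discrete = True
                fits[sid] = plmod.fit_power_law(
                    vals, discrete=discrete, min_tail=10,
                    seed=_subject_seed(config.seed, "pl", modality, kind, sid))
                f = fits[sid]
                fit_rows.append({
                    "modality": modality, "networks": kind, "subject": sid,
                    "alpha": f.alpha, "xmin": f.xmin, "ks": f.ks,
                    "n_tail": f.n_tail})
            obs, p = plmod.compare_fit_between_groups(
                [fits[i] for i in cohort.ids_in(ga)],
                [fits[i] for i in cohort.ids_in(gb)],
                n_perm=config.n_perm,
                seed=_subject_seed(config.seed, "plcmp", modality, kind))
            cmp_rows.append({"modality": modality, "networks": kind,
                             "ks_diff": obs, "p": p})
    return pd.DataFrame(fit_rows), pd.DataFrame(cmp_rows)


def regional_analysis(
    cohort: Cohort, config: RunConfig, min_densities: dict[str, float]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NBS (extent + intensity) and FDR edge tests, weighted and thresholded."""
    ga, gb = cohort.group_names
    nbs_rows, fdr_rows = [], []
    for modality in ("structural", "functional"):
        conns = getattr(cohort, modality)
        for kind in ("weighted", "min_density"):
            def mat(sid):
                if kind == "weighted":
                    return conns[sid].matrix
                return dens.threshold_at_density(
                    conns[sid], min_densities[modality], binarize=False).matrix
            mats_a = [mat(i) for i in cohort.ids_in(ga)]
            mats_b = [mat(i) for i in cohort.ids_in(gb)]
            for mode in ("extent", "intensity"):
                res = nbsmod.nbs_test(
                    mats_a, mats_b, primary_threshold=config.nbs_threshold,
                    mode=mode, n_perm=config.n_perm,
                    seed=_subject_seed(config.seed, "nbs", modality, kind, mode))
                nbs_rows.append({
                    "modality": modality, "networks": kind, "mode": mode,
                    "n_components": len(res.components),
                    "min_fwe_p": res.min_p})
            t = nbsmod.edgewise_contrast(mats_a, mats_b)
            df = len(mats_a) + len(mats_b) - 2
            sig = nbsmod.fdr_edges(t, df, q=0.05)
            fdr_rows.append({"modality": modality, "networks": kind,
                             "n_significant_edges": len(sig)})
    return pd.DataFrame(nbs_rows), pd.DataFrame(fdr_rows)


def coupling_analysis(
    cohort: Cohort, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Structure-function coupling per subject + group comparison."""
    ga, gb = cohort.group_names
    rows, test_rows = [], []
    for subset in config.measure_subsets:
        rs = {}
        for sid in cohort.ids:
            res = sf.predict_fc(cohort.structural[sid].matrix,
                                cohort.functional[sid].matrix,
                                subset=subset, subject_id=sid)
            rs[sid] = res
            rows.append({"subset": subset, "subject": sid,
                         "group": dict(zip(cohort.ids, cohort.groups))[sid],
                         "r": res.r, "p": res.p_value, "n_pairs": res.n_pairs})
        t, p = sf.compare_coupling(
            np.array([rs[i].r for i in cohort.ids_in(ga)]),
            np.array([rs[i].r for i in cohort.ids_in(gb)]))
        test_rows.append({"subset": subset, "t": t, "p": p})
    return pd.DataFrame(rows), pd.DataFrame(test_rows)


def run_full_pipeline(cohort: Cohort, config: RunConfig) -> PipelineResult:
    logger.info("pipeline start: seed=%d, n_perm=%d, n_random=%d",
                config.seed, config.n_perm, config.n_random)
    d_min_s, curves, window_full, crossover, auc_tests = \
        structural_density_analysis(cohort, config)
    d_min_f, min_density_tests = functional_min_density_analysis(cohort, config)
    min_densities = {"structural": d_min_s, "functional": d_min_f}
    glm_s, _ = weighted_network_analysis(cohort, config, "structural",
                                         sw_exclude=False)
    glm_f, _ = weighted_network_analysis(cohort, config, "functional",
                                         sw_exclude=True)
    weighted_glm = pd.concat([glm_s, glm_f], ignore_index=True)
    pl_fits, pl_cmp = powerlaw_analysis(cohort, config, min_densities)
    nbs_df, fdr_df = regional_analysis(cohort, config, min_densities)
    coupling, coupling_tests = coupling_analysis(cohort, config)
    windows = {"full": window_full}
    result = PipelineResult(
        min_density=min_densities, windows=windows, crossover=crossover,
        curves={"structural": curves}, auc_tests=auc_tests,
        min_density_tests=min_density_tests, weighted_glm=weighted_glm,
        powerlaw_fits=pl_fits, powerlaw_comparison=pl_cmp,
        nbs_results=nbs_df, fdr_results=fdr_df,
        coupling=coupling, coupling_tests=coupling_tests,
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in result.tables().items():
            table.to_csv(out / f"{name}.csv", index=False)
        pd.DataFrame([{"modality": k, "min_density": v}
                      for k, v in min_densities.items()]
                     ).to_csv(out / "min_density.csv", index=False)
        logger.info("tables written to %s", out)
    return result
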