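"""End-to-end orchestration: config, staged analysis, report bundle."""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .community import identify_hubs, louvain
from .degree_dist import fit_all_models, select_model
from .graphs import ThresholdGrid, largest_component, threshold_by_cost, threshold_by_r
from .metrics import (
    characteristic_path_length,
    clustering_coefficient,
    betweenness,
    global_efficiency,
    local_efficiency,
    network_cost,
    small_world_summary,
)
from .nulls import lattice_graph, make_ensemble
from .preprocess import (
    ConnectivityMatrix,
    build_censor_mask,
    clean_timeseries,
    correlation_matrix,
    framewise_displacement,
    group_average,
)
from .resilience import isolated_removal_sweep, random_failure, targeted_attack
from .stats import compare_metric_to_null, swi_interval
from .synthetic import SyntheticCohortSpec, generate_cohort

log = logging.getLogger("restnet")


@dataclass
class PipelineConfig:
    """All pipeline knobs with the study's fixed constants as defaults."""

    mode: str = "synthetic"  # synthetic | timeseries | matrices
    input_dir: str | None = None
    output_dir: str = "restnet_out"
    seed: int = 0
    # preprocessing
    fd_thresh_mm: float = 0.3
    outlier_thresh: float = 0.10
    band_hz: tuple[float, float] = (0.01, 0.1)
    tr_seconds: float = 2.0
    head_radius_mm: float = 50.0
    # grids and ensembles
    grid: ThresholdGrid = field(default_factory=ThresholdGrid)
    n_rewired_nulls: int = 100
    n_cost_nulls: int = 20
    swaps_per_edge: int = 10
    # hub / community / attack
    hub_sd_multiplier: float = 1.0
    hub_r_threshold_cost: float = 0.10
    louvain_restarts: int = 100
    attack_random_runs: int = 20
    alpha: float = 0.01
    # synthetic cohort overrides
    cohort: SyntheticCohortSpec = field(default_factory=SyntheticCohortSpec)

    def __post_init__(self) -> None:
        low, high = self.band_hz
        nyquist = 0.5 / self.tr_seconds
        if not (0 < low < high <= nyquist):
            raise ValueError(f"band {self.band_hz} must satisfy 0 < low < high <= Nyquist")
        for name in ("fd_thresh_mm", "outlier_thresh", "tr_seconds", "head_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _fmt(x: float) -> float:
    return float(f"{x:.6g}")


def _sha1(path: Path) -> str:
    import hashlib

    return hashlib.sha1(Path(path).read_bytes()).hexdigest()[:12]


def subject_matrices(config: PipelineConfig) -> tuple[list[ConnectivityMatrix], dict]:
    """Produce per-subject connectivity matrices for the configured input mode."""
    meta: dict = {"mode": config.mode}
    if config.mode == "synthetic":
        spec = dataclasses.replace(config.cohort, seed=config.seed)
        cohort = generate_cohort(spec)
        mats = []
        retained = []
        for sub in cohort.subjects:
            fd = framewise_displacement(sub.motion, config.head_radius_mm)
            mask = build_censor_mask(
                fd, sub.motion.outlier_fraction, config.fd_thresh_mm, config.outlier_thresh
            )
            clean = clean_timeseries(
                sub.timeseries, None, mask, band=config.band_hz, tr=config.tr_seconds
            )
            retained.append(mask.n_retained)
            mats.append(correlation_matrix(clean, cohort.roi_labels))
        meta["retained_frames_mean"] = float(np.mean(retained))
        meta["planted_modules"] = cohort.module_labels.tolist()
        meta["planted_hubs"] = cohort.hub_nodes.tolist()
        return mats, meta
    if config.mode == "matrices":
        if config.input_dir is None:
            raise ValueError("matrices mode requires input_dir")
        paths = sorted(Path(config.input_dir).glob("*.csv"))
        if not paths:
            raise FileNotFoundError(f"no .csv matrices under {config.input_dir}")
        for p in paths:
            log.info("input=%s sha1=%s", p, _sha1(p))
        return [io.read_matrix(p) for p in paths], meta
    if config.mode == "timeseries":
        if config.input_dir is None:
            raise ValueError("timeseries mode requires input_dir")
        ts_paths = sorted(Path(config.input_dir).glob("*_timeseries.csv"))
        if not ts_paths:
            raise FileNotFoundError(f"no *_timeseries.csv under {config.input_dir}")
        mats = []
        for p in ts_paths:
            log.info("input=%s sha1=%s", p, _sha1(p))
            ts, labels = io.read_timeseries(p)
            motion_path = Path(str(p).replace("_timeseries.csv", "_motion.csv"))
            mask = None
            if motion_path.exists():
                motion = io.read_motion(motion_path)
                fd = framewise_displacement(motion, config.head_radius_mm)
                mask = build_censor_mask(
                    fd, motion.outlier_fraction, config.fd_thresh_mm, config.outlier_thresh
                )
            clean = clean_timeseries(ts, None, mask, band=config.band_hz, tr=config.tr_seconds)
            mats.append(correlation_matrix(clean, labels))
        return mats, meta
    raise ValueError(f"unknown mode {config.mode!r}")


def sweep_r_thresholds(
    matrices: list[ConnectivityMatrix],
    grid: ThresholdGrid,
    n_nulls: int,
    swaps_per_edge: int,
    seed: int,
    alpha: float = 0.01,
) -> dict:
    """Per-subject, per-R-threshold small-world metrics with rewired nulls."""
    rows = []
    n_tests = len(grid.r_values)
    for ti, r in enumerate(grid.r_values):
        subj_c, subj_l, subj_sigma, null_c, null_l = [], [], [], [], []
        lcc_fracs = []
        for si, mat in enumerate(matrices):
            g = threshold_by_r(mat, float(r))
            if g.n_edges < 2:
                continue
            _, mean_c = clustering_coefficient(g)
            l = characteristic_path_length(g)
            _, frac = largest_component(g)
            ens = make_ensemble(
                g, "rewired_random", n_nulls,
                seed=int(np.random.default_rng(np.random.SeedSequence([seed, ti, si])).integers(2**31)),
                swaps_per_edge=swaps_per_edge,
            )
            nc = float(np.mean([clustering_coefficient(m)[1] for m in ens.members]))
            nl = float(np.nanmean([characteristic_path_length(m) for m in ens.members]))
            subj_c.append(mean_c)
            subj_l.append(l)
            null_c.append(nc)
            null_l.append(nl)
            lcc_fracs.append(frac)
            if nc > 0 and nl > 0 and np.isfinite(l):
                s = small_world_summary(mean_c, l, nc, nl, global_efficiency(g), network_cost(g))
                subj_sigma.append(s.sigma)
        if len(subj_c) < 3:
            rows.append({"r": float(r), "n_subjects": len(subj_c), "skipped": True})
            continue
        inference = compare_metric_to_null(subj_c, null_c, alpha=alpha, n_tests=n_tests)
        swi = swi_interval(subj_sigma) if len(subj_sigma) >= 3 else None
        rows.append(
            {
                "r": float(r),
                "n_subjects": len(subj_c),
                "mean_c": _fmt(float(np.mean(subj_c))),
                "mean_null_c": _fmt(float(np.mean(null_c))),
                "mean_l": _fmt(float(np.mean(subj_l))),
                "mean_null_l": _fmt(float(np.mean(null_l))),
                "mean_sigma": _fmt(float(np.mean(subj_sigma))) if subj_sigma else None,
                "mean_lcc_fraction": _fmt(float(np.mean(lcc_fracs))),
                "c_vs_null_t": _fmt(inference.t_statistic),
                "c_vs_null_p": inference.p_value,
                "c_significant_corrected": inference.significant_corrected,
                "swi_ci_lower": _fmt(swi.lower) if swi else None,
                "swi_ci_upper": _fmt(swi.upper) if swi else None,
                "swi_exceeds_one": swi.exceeds_one if swi else None,
            }
        )
    return {"rows": rows}


def sweep_cost_thresholds(
    matrices: list[ConnectivityMatrix],
    grid: ThresholdGrid,
    n_nulls: int,
    swaps_per_edge: int,
    seed: int,
) -> dict:
    """Efficiency/economy sweep with lattice and rewired-random benchmarks."""
    rows = []
    for ti, cost in enumerate(grid.cost_values):
        eglob, eloc, ce = [], [], []
        eglob_r, eglob_l, eloc_r, eloc_l = [], [], [], []
        for si, mat in enumerate(matrices):
            g = threshold_by_cost(mat, float(cost))
            e_g = global_efficiency(g)
            e_l = local_efficiency(g)
            actual_cost = network_cost(g)
            eglob.append(e_g)
            eloc.append(e_l)
            ce.append(e_g - actual_cost)
            lat = lattice_graph(g.n_nodes, g.n_edges)
            eglob_l.append(global_efficiency(lat))
            eloc_l.append(local_efficiency(lat))
            ens = make_ensemble(
                g, "rewired_random", n_nulls,
                seed=int(np.random.default_rng(np.random.SeedSequence([seed, 77, ti, si])).integers(2**31)),
                swaps_per_edge=swaps_per_edge,
            )
            eglob_r.append(float(np.mean([global_efficiency(m) for m in ens.members])))
            eloc_r.append(float(np.mean([local_efficiency(m) for m in ens.members])))
        rows.append(
            {
                "cost": float(cost),
                "eglob": _fmt(float(np.mean(eglob))),
                "eloc": _fmt(float(np.mean(eloc))),
                "cost_efficiency": _fmt(float(np.mean(ce))),
                "eglob_random": _fmt(float(np.mean(eglob_r))),
                "eglob_lattice": _fmt(float(np.mean(eglob_l))),
                "eloc_random": _fmt(float(np.mean(eloc_r))),
                "eloc_lattice": _fmt(float(np.mean(eloc_l))),
            }
        )
    return {"rows": rows}


def analyze_group_graph(group: ConnectivityMatrix, config: PipelineConfig) -> dict:
    """Degree-distribution fits, hubs, modules and attacks on the group graph."""
    g = threshold_by_cost(group, config.hub_r_threshold_cost)
    deg = g.degrees
    fits = fit_all_models(deg)
    best = select_model(fits)
    deg_hubs = identify_hubs(deg.astype(float), config.hub_sd_multiplier, kind="degree",
                             labels=g.labels)
    bet = betweenness(g)
    bet_hubs = identify_hubs(bet, config.hub_sd_multiplier, kind="betweenness", labels=g.labels)
    part = louvain(g, n_restarts=config.louvain_restarts, seed=config.seed)
    table = isolated_removal_sweep(g)
    curves = {
        s: targeted_attack(g, s) for s in ("degree", "betweenness")
    }
    curves["random"] = random_failure(g, n_runs=config.attack_random_runs, seed=config.seed)
    return {
        "graph": g,
        "degree_fits": fits,
        "best_model": best,
        "degree_hubs": deg_hubs,
        "betweenness_hubs": bet_hubs,
        "partition": part,
        "isolated_removal": table,
        "attack_curves": curves,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    matrices, meta = subject_matrices(config)
    log.info("stage=matrices n=%d elapsed=%.1fs", len(matrices), time.time() - t0)

    group = group_average(matrices)
    io.write_matrix(out / "group_matrix.csv", group)

    r_sweep = sweep_r_thresholds(
        matrices, config.grid, config.n_rewired_nulls, config.swaps_per_edge,
        config.seed, alpha=config.alpha,
    )
    io.write_json(out / "r_sweep.json", r_sweep)
    log.info("stage=r_sweep elapsed=%.1fs", time.time() - t0)

    cost_sweep = sweep_cost_thresholds(
        matrices, config.grid, config.n_cost_nulls, config.swaps_per_edge, config.seed
    )
    io.write_json(out / "cost_sweep.json", cost_sweep)
    log.info("stage=cost_sweep elapsed=%.1fs", time.time() - t0)

    group_results = analyze_group_graph(group, config)
    io.write_edge_list(out / "group_graph.edges", group_results["graph"])
    io.write_json(
        out / "group_analysis.json",
        {
            "best_model": group_results["best_model"].model,
            "fits": [
                {"model": f.model, "aic": _fmt(f.aic), "rss": _fmt(f.rss), "params": f.parameters}
                for f in group_results["degree_fits"]
            ],
            "degree_hubs": group_results["degree_hubs"].hubs.tolist(),
            "betweenness_hubs": group_results["betweenness_hubs"].hubs.tolist(),
            "modularity_q": _fmt(group_results["partition"].q),
            "n_modules": group_results["partition"].n_modules,
            "module_labels": group_results["partition"].labels.tolist(),
            "isolated_removal": {
                "nodes": group_results["isolated_removal"].nodes.tolist(),
                "delta_eglob_percent": [
                    _fmt(v) for v in group_results["isolated_removal"].delta_eglob_percent
                ],
            },
        },
    )
    for name, curve in group_results["attack_curves"].items():
        io.write_json(
            out / f"attack_{name}.json",
            {
                "strategy": curve.strategy,
                "removed": curve.removed.tolist(),
                "lcc_fraction": [_fmt(v) for v in curve.lcc_fraction],
                "eglob_percent": [_fmt(v) for v in curve.eglob_percent],
            },
        )
    report = {
        "meta": meta,
        "n_subjects": len(matrices),
        "n_r_thresholds": len(config.grid.r_values),
        "n_cost_thresholds": len(config.grid.cost_values),
        "seed": config.seed,
        "elapsed_seconds": _fmt(time.time() - t0),
    }
    io.write_json(out / "report.json", report)
    lines = ["# Pipeline report", ""]
    for k, v in report.items():
        lines.append(f"- **{k}**: {v}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
    log.info("stage=done elapsed=%.1fs", time.time() - t0)
    return {"report": report, "r_sweep": r_sweep, "cost_sweep": cost_sweep, "group": group_results}
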