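"""End-to-end orchestration of the bistability / noise-switching analysis."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .equilibria import bistability_regime, critical_Ks, find_equilibria
from .geometry import Cycle, Separatrix, find_limit_cycle, stable_manifold
from .params import validate_params
from .sde import NoiseSpec, simulate, transition_stats
from .ssf import (ConfidenceSpec, confidence_band, confidence_ellipse,
                  cycle_ssf, equilibrium_ssf, tangency_threshold)

log = logging.getLogger("stoichswitch")

REPORT_SCHEMA = "stoichswitch-report/1"


def run_pipeline(cfg: RunConfig) -> dict:
    """Run validate -> thresholds -> equilibria -> geometry -> SSF ->
    confidence regions -> simulation -> transition statistics.

    Returns a report bundle: a JSON-ready dict under ``"report"`` plus
    DataFrames of the separatrix, cycle/band and trajectory under
    ``"tables"``.  Deterministic for a fixed config (seed included).
    """
    t_start = time.time()
    params = cfg.params
    bundle: dict = {"tables": {}}
    report: dict = {
        "schema": REPORT_SCHEMA,
        "version": __version__,
        "config": cfg.as_dict(),
        "stages": {},
    }
    bundle["report"] = report

    def stage(name):
        log.info("stage %s", name)
        report["stages"][name] = {"t_wall": None}
        return time.time()

    try:
        t0 = stage("validate")
        violations = validate_params(params)
        if violations:
            raise ValueError("; ".join(violations))
        report["stages"]["validate"]["t_wall"] = time.time() - t0

        t0 = stage("thresholds")
        ks = critical_Ks(params)
        report["critical_Ks"] = ks.as_dict()
        report["stages"]["thresholds"]["t_wall"] = time.time() - t0

        t0 = stage("equilibria")
        eqs = find_equilibria(params)
        report["equilibria"] = [eq.as_dict() for eq in eqs]
        regime = bistability_regime(params)
        report["regime"] = regime["regime"]
        report["regime_detail"] = {k: v for k, v in regime.items()
                                   if k != "critical_Ks"}
        report["stages"]["equilibria"]["t_wall"] = time.time() - t0

        interior = [eq for eq in eqs if eq.branch in ("l1", "l2")]
        saddle = next((eq for eq in interior if eq.stability == "saddle"), None)
        stable = [eq for eq in interior if eq.stability == "stable"]

        sep: Separatrix | None = None
        cyc: Cycle | None = None
        t0 = stage("geometry")
        if saddle is not None:
            sep = stable_manifold(saddle, params)
            bundle["tables"]["separatrix"] = pd.DataFrame({
                "index": np.arange(len(sep.points)),
                "t_or_s": np.concatenate(
                    [[0.0], np.cumsum(np.linalg.norm(np.diff(sep.points, axis=0), axis=1))]),
                "x": sep.points[:, 0], "y": sep.points[:, 1],
            })
        if report["regime"] == "cycle_eq":
            focus = next(eq for eq in interior
                         if eq.branch == "l1" and eq.stability == "unstable")
            cyc = find_limit_cycle(params, focus)
            report["cycle"] = {"period": cyc.period,
                               "crosses_branch_line": cyc.crosses_branch_line}
        report["stages"]["geometry"]["t_wall"] = time.time() - t0

        t0 = stage("ssf")
        report["ssf"] = {}
        attractors = {}
        for label, eq in zip(("basin_A", "basin_B"), sorted(stable, key=lambda e: e.x)):
            attractors[label] = eq.location
        for eq in stable:
            ssf = equilibrium_ssf(eq, params)
            entry = {"equilibrium": [eq.x, eq.y],
                     "W": ssf.W.tolist(),
                     "lyapunov_residual": ssf.residual,
                     "ellipses": []}
            for P in cfg.P_fid:
                eps = cfg.eps1 if eq.x + eq.y <= params.p else cfg.eps2
                ell = confidence_ellipse(eq, ssf, ConfidenceSpec(P, eps))
                entry["ellipses"].append({"P_fid": P, "eps": eps,
                                          "Q": ell.Q.tolist(),
                                          "level": ell.level})
                if sep is not None:
                    entry[f"eps_star_P{P}"] = tangency_threshold(eq, ssf, P, sep)
            report["ssf"][f"{eq.branch}_{eq.x:.4f}"] = entry
        if cyc is not None:
            cssf = cycle_ssf(cyc, params)
            band = confidence_band(cyc, cssf,
                                   ConfidenceSpec(cfg.P_fid[0], cfg.eps1))
            report["cycle_ssf"] = {
                "lyapunov_exponent": cssf.lyapunov_exponent,
                "periodicity_residual": cssf.periodicity_residual,
                "mu_min": float(cssf.mu.min()), "mu_max": float(cssf.mu.max()),
                "k": band.k,
            }
            bundle["tables"]["cycle"] = pd.DataFrame({
                "t": cyc.times,
                "x": cyc.samples[:, 0], "y": cyc.samples[:, 1],
                "p1": cssf.p[:, 0], "p2": cssf.p[:, 1], "mu": cssf.mu,
                "band_x1": band.gamma1[:, 0], "band_y1": band.gamma1[:, 1],
                "band_x2": band.gamma2[:, 0], "band_y2": band.gamma2[:, 1],
            })
        report["stages"]["ssf"]["t_wall"] = time.time() - t0

        t0 = stage("simulation")
        init = stable[0].location if stable else np.array([params.K / 2, params.p / 4])
        traj = simulate(params, NoiseSpec(cfg.eps1, cfg.eps2), init,
                        cfg.t_end, h=cfg.h, seed=cfg.seed)
        bundle["tables"]["trajectory"] = traj.to_frame()
        report["simulation"] = {
            "init": init.tolist(), "t_end": cfg.t_end, "h": cfg.h,
            "seed": cfg.seed, "n_clamped": int(traj.clamped.sum()),
        }
        report["stages"]["simulation"]["t_wall"] = time.time() - t0

        t0 = stage("transitions")
        if sep is not None and len(attractors) >= 2:
            stats = transition_stats(traj, sep, attractors, debounce_time=5.0)
            report["transitions"] = {
                "hop_count": stats.hop_count,
                "occupancy": stats.occupancy,
                "debounce_time": stats.debounce_time,
                "warning": stats.warning,
            }
        report["stages"]["transitions"]["t_wall"] = time.time() - t0
    except Exception as exc:
        failed = next((k for k, v in report["stages"].items()
                       if v["t_wall"] is None), "unknown")
        raise RuntimeError(f"pipeline stage '{failed}' failed: {exc}") from exc

    report["t_wall_total"] = time.time() - t_start
    return bundle


def write_report(bundle: dict, out_dir: str | Path) -> list[Path]:
    """Write report.json, the CSV tables and a run manifest; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    rp = out / "report.json"
    rp.write_text(json.dumps(bundle["report"], indent=2, default=float))
    paths.append(rp)

    for name, df in bundle["tables"].items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.17g")
        paths.append(p)

    manifest = {
        "schema": REPORT_SCHEMA,
        "version": __version__,
        "config": bundle["report"]["config"],
        "files": [p.name for p in paths],
    }
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, default=float))
    paths.append(mp)
    return paths
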