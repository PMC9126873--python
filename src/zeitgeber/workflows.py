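"""End-to-end experiment bundles.

Each tag runs one named pipeline — free-oscillator phase diagram,
period-vs-dilution sweep, parameter sensitivity, forced entrainment,
period doubling, and the 1-D/2-D bifurcation scans — and writes tabular
results (CSV/JSON), a manifest sufficient to re-run it identically, and a
convenience figure.  All downstream checks read the tables, never the
rendered images.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, bifurcation, metrics
from .errors import ParameterError
from .model import predicted_period, refresh_for_lambda
from .presets import get_preset
from .reactor import run_reactor

__all__ = ["ExperimentConfig", "EXPERIMENT_TAGS", "run_experiment"]

EXPERIMENT_TAGS = ("free_phase_diagram", "period_vs_delta", "sensitivity",
                   "forced_entrainment", "period_doubling",
                   "bifurcation_1d", "bifurcation_2d")


@dataclass
class ExperimentConfig:
    """Serializable description of one experiment bundle."""

    preset: str = "free"
    lambda_grid: tuple = (0.7, 0.9, 1.05, 1.2, 1.35, 1.48, 1.7)
    n_grid: tuple = (3.0, 4.0, 6.0, 8.0)
    R_grid: tuple = (0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4)
    alpha_grid: tuple = (0.3, 1.0, 3.0)
    equilibration_cycles: int = 500
    analysis_cycles: int = 512
    n_cycles_free: int = 192
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_manifest(out: Path, tag: str, cfg: ExperimentConfig, extra=None):
    manifest = {"tag": tag, "version": __version__, "config": cfg.to_dict()}
    if extra:
        manifest.update(extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _savefig(fig, out: Path, name: str):
    fig.savefig(out / name, dpi=120)
    import matplotlib.pyplot as plt

    plt.close(fig)


def run_experiment(tag: str, out_dir, config: ExperimentConfig | None = None):
    """Execute one named pipeline and write its result bundle to ``out_dir``.

    Returns the main result table as a DataFrame.
    """
    if tag not in EXPERIMENT_TAGS:
        raise ParameterError(f"unknown tag {tag!r}; available: {EXPERIMENT_TAGS}")
    cfg = config or ExperimentConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = _RUNNERS[tag](cfg, out)
    _write_manifest(out, tag, cfg)
    return df


def _free_trace(cfg, alpha, R):
    params, proto = get_preset("free")
    params = replace(params, alpha_a=alpha, alpha_h=alpha)
    proto = replace(proto, R=R, n_cycles=cfg.n_cycles_free)
    return params, proto, run_reactor(params, proto)


def _run_free_phase_diagram(cfg: ExperimentConfig, out: Path) -> pd.DataFrame:
    import matplotlib.pyplot as plt

    rows = []
    for alpha in cfg.alpha_grid:
        for R in cfg.R_grid:
            _, proto, trace = _free_trace(cfg, alpha, R)
            pm = metrics.phase_metrics(trace, "a")
            rows.append({"alpha_pM_s": alpha, "R": R, "delta_per_s": proto.delta,
                         "regime": pm.regime, "A_inf": pm.A_inf,
                         "gamma": pm.gamma, "tau_eq_h": pm.tau_eq_h,
                         "n_maxima": pm.n_maxima})
    df = pd.DataFrame(rows)
    df.to_csv(out / "phase_diagram.csv", index=False)

    fig, ax = plt.subplots()
    colors = {"sustained": "tab:green", "damped": "tab:orange",
              "overdamped": "tab:red"}
    for regime, sub in df.groupby("regime"):
        ax.scatter(sub["delta_per_s"], sub["alpha_pM_s"],
                   c=colors.get(regime, "gray"), label=regime)
    ax.set(xlabel="dilution rate δ (1/s)", ylabel="α (pM/s)",
           title="free-oscillator phase diagram")
    ax.legend()
    _savefig(fig, out, "phase_diagram.png")
    return df


def _run_period_vs_delta(cfg: ExperimentConfig, out: Path) -> pd.DataFrame:
    import matplotlib.pyplot as plt

    rows, deltas, estimates = [], [], []
    for R in cfg.R_grid:
        _, proto, trace = _free_trace(cfg, 3.0, R)
        est = metrics.acf_period(trace, "a")
        deltas.append(proto.delta)
        estimates.append(est)
        rows.append({"R": R, "delta_per_s": proto.delta,
                     "T_acf_h": est.period_h if est else np.nan,
                     "T_pred_h": predicted_period(proto.delta),
                     "uncertainty_h": est.uncertainty_h if est else np.nan})
    df = pd.DataFrame(rows)
    C = metrics.fit_period_scaling(deltas, estimates)
    df.attrs["C"] = C
    ok = df["T_acf_h"].notna()
    x = np.pi / df.loc[ok, "delta_per_s"].to_numpy() / 3600.0
    y = df.loc[ok, "T_acf_h"].to_numpy()
    df.to_csv(out / "period_vs_delta.csv", index=False)
    (out / "fit.json").write_text(json.dumps({"C": C}))

    fig, ax = plt.subplots()
    ax.plot(x, y, "o", label="ACF period")
    ax.plot(x, C * x, "-", label=f"T = Cπ/δ, C = {C:.3f}")
    ax.set(xlabel="π/δ (h)", ylabel="period (h)")
    ax.legend()
    _savefig(fig, out, "period_vs_delta.png")
    return df


def _run_sensitivity(cfg: ExperimentConfig, out: Path) -> pd.DataFrame:
    params, proto = get_preset("free")
    proto = replace(proto, n_cycles=cfg.n_cycles_free)
    results = bifurcation.sensitivity_analysis(params, proto)
    df = pd.DataFrame([{"parameter": r.parameter,
                        "T_baseline_h": r.T_baseline_h,
                        "T_perturbed_h": r.T_perturbed_h,
                        "delta_T_h": r.delta_T_h,
                        "rel_delta_T": r.rel_delta_T} for r in results])
    df.to_csv(out / "sensitivity.csv", index=False)

    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.barh(df["parameter"], df["delta_T_h"])
    ax.set(xlabel="ΔT (h)", title="period sensitivity to +30% perturbations")
    _savefig(fig, out, "sensitivity.png")
    return df


def _forced_run(cfg, lam, n_cycles=None):
    params, proto = get_preset("forced")
    n_cycles = n_cycles or (cfg.equilibration_cycles + cfg.analysis_cycles)
    proto = replace(proto, R=refresh_for_lambda(lam, proto.k), n_cycles=n_cycles)
    return params, proto, run_reactor(params, proto)


def _run_forced_entrainment(cfg: ExperimentConfig, out: Path) -> pd.DataFrame:
    import matplotlib.pyplot as plt

    rows = []
    fig, axes = plt.subplots(2, 1, sharex=True)
    for ax, lam in zip(axes, (1.48, 1.2)):
        params, proto, trace = _forced_run(cfg, lam)
        post = trace.after_cycle(2 * proto.k)  # adaptation takes 1-2 input cycles
        est = metrics.acf_period(post, "h")
        rows.append({"lambda": lam, "R": proto.R, "T_in_h": proto.T_in_h,
                     "T_acf_h": est.period_h if est else np.nan})
        ax.plot(trace.time_h, trace.channel("h"), label=f"λ={lam}")
        ax.legend()
    axes[-1].set(xlabel="time (h)", ylabel="endogenous repressor (nM)")
    _savefig(fig, out, "entrainment.png")
    df = pd.DataFrame(rows)
    df.to_csv(out / "entrainment.csv", index=False)
    return df


def _run_period_doubling(cfg: ExperimentConfig, out: Path) -> pd.DataFrame:
    import matplotlib.pyplot as plt

    params, proto, trace = _forced_run(cfg, 1.20)
    trace.to_csv(out / "trace.csv")
    mx = bifurcation.detect_cycle_maxima(trace, "h", cfg.equilibration_cycles,
                                         spacing_cycles=proto.k)
    rot = bifurcation.rotation_number(mx)
    rmap = metrics.return_map(mx.heights)
    df = pd.DataFrame(rmap, columns=["y_i", "y_i_plus_1"])
    df.to_csv(out / "return_map.csv", index=False)
    (out / "classification.json").write_text(json.dumps(
        {"lambda": 1.20, "m": rot.m, "chaotic": rot.chaotic,
         "n_maxima": rot.n_maxima, "n_interpolated": rot.n_interpolated}))

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(trace.time_h, trace.channel("h"))
    ax1.set(xlabel="time (h)", ylabel="endogenous repressor (nM)")
    ax2.plot(df["y_i"], df["y_i_plus_1"], "o")
    ax2.set(xlabel="maximum i (nM)", ylabel="maximum i+1 (nM)",
            title=f"return map ({rot.label})")
    _savefig(fig, out, "period_doubling.png")
    return df


def _run_bifurcation_1d(cfg: ExperimentConfig, out: Path) -> pd.DataFrame:
    import matplotlib.pyplot as plt

    params, proto = get_preset("forced")
    scan = bifurcation.bifurcation_1d(
        params, proto, cfg.lambda_grid,
        equilibration_cycles=cfg.equilibration_cycles,
        analysis_cycles=cfg.analysis_cycles)
    rows = []
    for entry in scan.results:
        if "error" in entry:
            rows.append({"lambda": entry["lambda"], "channel": "error",
                         "maximum_height": np.nan, "m": np.nan})
            continue
        rot = entry["rotation"]
        m_val = np.inf if rot.chaotic else rot.m
        for ch in ("a", "h"):
            for height in entry[ch].heights:
                rows.append({"lambda": entry["lambda"], "channel": ch,
                             "maximum_height": height, "m": m_val})
    df = pd.DataFrame(rows)
    df.to_csv(out / "bifurcation_1d.csv", index=False)

    fig, ax = plt.subplots()
    for ch, color in (("a", "tab:olive"), ("h", "tab:blue")):
        sub = df[df["channel"] == ch]
        ax.plot(sub["lambda"], sub["maximum_height"], ".", ms=3, color=color,
                label=ch)
    ax.set(xlabel="λ = T_in/T", ylabel="maxima (nM)")
    ax.legend()
    _savefig(fig, out, "bifurcation_1d.png")
    return df


def _run_bifurcation_2d(cfg: ExperimentConfig, out: Path) -> pd.DataFrame:
    import matplotlib.pyplot as plt

    params, proto = get_preset("forced")
    scan = bifurcation.bifurcation_2d(
        params, cfg.n_grid, cfg.lambda_grid, proto,
        equilibration_cycles=cfg.equilibration_cycles,
        analysis_cycles=max(cfg.analysis_cycles, 600))
    mat = scan.m_matrix()
    rows = []
    for i, n in enumerate(scan.n_values):
        for j, lam in enumerate(scan.lambdas):
            rows.append({"n": n, "lambda": lam, "m": mat[i, j]})
    df = pd.DataFrame(rows)
    df.to_csv(out / "bifurcation_2d.csv", index=False)

    fig, ax = plt.subplots()
    shown = np.where(np.isinf(mat), np.nanmax(mat[np.isfinite(mat)]) + 1, mat)
    im = ax.pcolormesh(scan.lambdas, scan.n_values, shown, shading="nearest")
    fig.colorbar(im, ax=ax, label="rotation number m (top bin = chaotic)")
    ax.set(xlabel="λ", ylabel="Hill coefficient n")
    _savefig(fig, out, "bifurcation_2d.png")
    return df


_RUNNERS = {
    "free_phase_diagram": _run_free_phase_diagram,
    "period_vs_delta": _run_period_vs_delta,
    "sensitivity": _run_sensitivity,
    "forced_entrainment": _run_forced_entrainment,
    "period_doubling": _run_period_doubling,
    "bifurcation_1d": _run_bifurcation_1d,
    "bifurcation_2d": _run_bifurcation_2d,
}
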