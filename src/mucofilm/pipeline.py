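"""End-to-end orchestration: bulk SAXS -> film QCM-D -> NR co-refinement.

A single YAML (or dict) config drives all three stages; each stage can
read measured files or generate its synthetic counterpart from the
global seed.  The run writes a machine-readable JSON summary (byte
identical across reruns with the same seed) and optional figures, and
records which parameters were fitted versus fixed to assumed defaults.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import yaml

from .core import FitResult, ScatteringCurve, Solvent, read_curve
from .nr import ContrastSeries, ResolutionSpec, abeles_reflectivity, build_paper_stacks, corefine, sld_profile, smear
from .qcmd import read_qcmd_csv, rigidity_check, segment_trace, step_sauerbrey
from .saxs import GaussianCoilModel, fit_gaussian_coil, guinier_fit, power_law_fit
from .synthetic import NoiseSpec, make_nr_dataset, make_qcmd_trace, make_saxs_dataset

__all__ = ["PipelineConfig", "run_pipeline", "compare_states", "load_config"]


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "mucofilm_out"
    figures: bool = True
    saxs: dict | None = None
    qcmd: dict | None = None
    nr: dict | None = None

    def validate(self) -> None:
        for stage in (self.saxs, self.qcmd, self.nr):
            if not stage:
                continue
            for key in ("curve", "csv"):
                path = stage.get(key)
                if path and not Path(path).exists():
                    raise PipelineError(f"input file not found: {path}")
            for name, path in (stage.get("contrasts") or {}).items():
                if isinstance(path, str) and not Path(path).exists():
                    raise PipelineError(f"input file not found ({name}): {path}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _jsonable(obj):
    if isinstance(obj, FitResult):
        return dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def _run_saxs(cfg: dict, seed: int, outdir: Path, figures: bool) -> dict:
    out: dict = {}
    if cfg.get("synthetic") or "curve" not in cfg:
        ds = make_saxs_dataset(noise=NoiseSpec(level=cfg.get("noise", 0.02), seed=seed))
        curve = ds.components["coil"]
        mixture = ds.interacting_mixture
        out["synthetic"] = True
    else:
        curve = read_curve(cfg["curve"], unit_hint=cfg.get("unit", "A_inv"))
        mixture = None
        out["synthetic"] = False

    init = GaussianCoilModel(**(cfg.get("init") or {"rg": 2.0}))
    fit = fit_gaussian_coil(curve, init)
    out["coil_fit"] = fit
    out["guinier"] = dataclasses.asdict(guinier_fit(curve))
    if mixture is not None:
        window = tuple(cfg.get("power_law_window", (7e-4, 2e-3)))
        out["low_q_power_law"] = dataclasses.asdict(power_law_fit(mixture, window))
    if figures:
        _plot_curve_fit(curve, fit, outdir / "saxs_coil_fit.png")
    return out


def _run_qcmd(cfg: dict, seed: int, outdir: Path, figures: bool) -> dict:
    if cfg.get("synthetic") or "csv" not in cfg:
        trace, events = make_qcmd_trace(seed=seed)
        synthetic = True
    else:
        trace = read_qcmd_csv(cfg["csv"], normalized=cfg.get("normalized", False))
        events = [(float(t), str(lbl)) for t, lbl in cfg["events"]]
        synthetic = False
    rho = float(cfg.get("density", 1.05))
    steps = segment_trace(trace, events)
    summary = []
    for step in steps:
        sb = step_sauerbrey(step, rho=rho)
        summary.append(
            {
                "label": step.label,
                "window_s": step.window,
                "delta_f_per_overtone_Hz": step.delta_f_per_overtone,
                "delta_d_per_overtone_1e6": step.delta_d_per_overtone,
                "harmonic_spread_Hz": step.harmonic_spread,
                "sauerbrey_mass_ng_cm2": sb.mass_areal,
                "sauerbrey_thickness_A": sb.thickness,
                "rigid_film_ok": sb.rigid_film_ok,
            }
        )
    if figures:
        _plot_qcmd(trace, events, outdir / "qcmd_trace.png")
    return {"synthetic": synthetic, "density_g_cm3": rho, "steps": summary}


def _run_nr(cfg: dict, seed: int, outdir: Path, figures: bool) -> dict:
    scenario = cfg.get("scenario", "bare_mucin")
    free = list(cfg.get("free", ["mucin_thickness", "mucin_phi"]))
    res = ResolutionSpec(dq_over_q=float(cfg.get("dq_over_q", 0.10 / 2.355)))
    if cfg.get("synthetic") or "contrasts" not in cfg:
        series = make_nr_dataset(
            scenario,
            noise=NoiseSpec(level=cfg.get("noise", 1.0), seed=seed),
            res=res,
            rinsed=bool(cfg.get("rinsed", False)),
        )
        synthetic = True
    else:
        stack = build_paper_stacks(scenario, Solvent(0.0), rinsed=bool(cfg.get("rinsed", False)))
        contrasts = {}
        for name, path in cfg["contrasts"].items():
            solvent = Solvent(1.0 if "d2o" in name.lower() else 0.0)
            contrasts[name] = (solvent, read_curve(path, kind="reflectivity"))
        series = ContrastSeries(stack=stack, contrasts=contrasts, resolution=res)
        synthetic = False
    fit = corefine(series, free=free, seed=seed,
                   n_restarts=int(cfg.get("n_restarts", 5)))
    fixed = {
        f"{s.label}_{attr}": getattr(s, attr)
        for s in series.stack.slabs
        for attr in ("thickness", "phi", "roughness")
        if s.label and f"{s.label}_{attr}" not in fit.params
    }
    if figures:
        _plot_nr(series, fit, outdir / f"nr_{scenario}.png")
    return {
        "synthetic": synthetic,
        "scenario": scenario,
        "fit": fit,
        "fixed_to_assumed_defaults": fixed,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in order; a stage failure is recorded and
    later stages still run (they do not depend on each other's outputs).
    Returns the report bundle and writes ``summary.json`` to the output
    directory."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    ok = True
    for name, runner, cfg in (
        ("saxs", _run_saxs, config.saxs),
        ("qcmd", _run_qcmd, config.qcmd),
        ("nr", _run_nr, config.nr),
    ):
        if not cfg:
            continue
        try:
            report[name] = runner(cfg, config.seed, outdir, config.figures)
        except Exception as exc:  # recorded, not raised: the report says what failed
            report[name] = {"error": f"{type(exc).__name__}: {exc}"}
            ok = False
    report["ok"] = ok
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def compare_states(fit_before: FitResult, fit_after: FitResult) -> dict[str, dict]:
    """Per-parameter change table between two fits of the same model
    (e.g. before/after polymer exposure or rinsing); uncertainties add in
    quadrature.  Deltas are after - before."""
    shared = sorted(set(fit_before.params) & set(fit_after.params))
    if not shared:
        raise ValueError("fits share no parameters")
    table: dict[str, dict] = {}
    for name in shared:
        b, a = fit_before.params[name], fit_after.params[name]
        sb = fit_before.stderr.get(name)
        sa = fit_after.stderr.get(name)
        err = math.hypot(sb, sa) if (sb is not None and sa is not None) else None
        table[name] = {"before": b, "after": a, "delta": a - b, "delta_err": err}
    return table


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def _plot_curve_fit(curve: ScatteringCurve, fit: FitResult, path: Path) -> None:
    from .saxs import debye_form_factor

    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(curve.q, curve.intensity, ".", ms=3, label="data")
    model = fit.params["scale"] * debye_form_factor(curve.q, fit.params["rg"]) + fit.params["background"]
    ax.loglog(curve.q, model, "-", label=f"coil fit, Rg={fit.params['rg']:.2f} nm")
    ax.set_xlabel("q (1/A)")
    ax.set_ylabel("I(q)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_qcmd(trace, events, path: Path) -> None:
    plt = _mpl()
    fig, (a1, a2) = plt.subplots(2, 1, figsize=(6, 5), sharex=True)
    for n in trace.overtones:
        a1.plot(trace.time, trace.normalized_f(n), lw=0.7, label=f"n={n}")
        a2.plot(trace.time, trace.delta_d[n], lw=0.7)
    for t, lbl in events:
        a1.axvline(t, color="0.8", lw=0.6)
        a2.axvline(t, color="0.8", lw=0.6)
    a1.set_ylabel("delta f / n (Hz)")
    a2.set_ylabel("delta D (1e-6)")
    a2.set_xlabel("time (s)")
    a1.legend(fontsize=7, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_nr(series: ContrastSeries, fit: FitResult, path: Path) -> None:
    from .nr import _apply_params  # best-fit stack for the model curves
    import lmfit

    plt = _mpl()
    fig, (a1, a2) = plt.subplots(1, 2, figsize=(9, 4))
    p = lmfit.Parameters()
    for k, v in fit.params.items():
        p.add(k, value=v, vary=False)
    stack = _apply_params(series.stack, p)
    for name, (solvent, curve) in series.contrasts.items():
        line = a1.errorbar(curve.q, curve.intensity, yerr=curve.sigma, fmt=".", ms=3, label=name)
        model = smear(abeles_reflectivity(stack, curve.q, solvent), curve.q, series.resolution)
        scale = fit.params.get(f"scale_{name}", 1.0)
        bg = fit.params.get(f"background_{name}", 0.0)
        a1.plot(curve.q, scale * model + bg, "-", color=line[0].get_color())
        z, prof = sld_profile(stack, solvent)
        a2.plot(z, prof * 1e6, label=name)
    a1.set_yscale("log")
    a1.set_xlabel("q (1/A)")
    a1.set_ylabel("R")
    a1.legend()
    a2.set_xlabel("z (A)")
    a2.set_ylabel("SLD (1e-6 / A^2)")
    a2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
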