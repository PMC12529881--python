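"""Config-driven orchestration: simulate -> quantify -> fit -> pharmacology.

The pipeline reproduces the study workflow end to end on synthetic data:
event lists are generated per titration design and replicate, reduced to
oligomer-fraction tables, fitted with the Hill-logistic conventions of
the study, and the inhibitor fits are converted into a potency summary
(IC50, Ki per compound).  Optionally a Schild grid is simulated and
analyzed (linear Schild plus OMAM global fit).  All stages are
deterministic under a fixed seed and write plain CSV/JSON outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import reference
from .fitting import TitrationSeries, fit_assembly_affinities, fit_hill
from .histogram import fractions_table
from .pharm import PharmacologyConfig, calibrate_lambda, ic50_to_ki, omam_global_fit, schild_analysis
from .synthetic import NoiseModel, read_events, simulate_titration, write_conditions_table

log = logging.getLogger("oligomp")

DEFAULT_DESIGNS = (
    "protein_dilution",
    "protein_dilution_substrate",
    "substrate_titration",
    "inhibitor_titration",
)


@dataclass
class RunConfig:
    """Pipeline settings; defaults mirror the study design."""

    designs: tuple = DEFAULT_DESIGNS
    inhibitors: tuple = ("C5", "C13", "C15")
    n_events: int = 8000
    replicates: int = 3
    seed: int = 0
    run_schild: bool = False
    noise: NoiseModel = field(default_factory=NoiseModel)
    pharm_mode: str = "empirical_lambda"
    pharm_lambda: Optional[float] = None  # default: calibrated from the reference table

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        noise = NoiseModel(**raw.pop("noise", {}))
        known = {f.name for f in cls.__dataclass_fields__.values()}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("designs", "inhibitors"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(noise=noise, **raw)


def _design_seed(base_seed: int, design: str, inhibitor: str | None, replicate: int) -> int:
    """Stable per-(design, inhibitor, replicate) seed below 2**31."""
    key = f"{design}|{inhibitor or ''}|{replicate}"
    h = 2166136261
    for ch in key:  # FNV-1a over the key, mixed with the base seed
        h = ((h ^ ord(ch)) * 16777619) & 0xFFFFFFFF
    return int((h ^ (base_seed * 2654435761)) % (2**31 - 1))


def _simulate_design(cfg: RunConfig, design: str, inhibitor: Optional[str], outdir: Path) -> None:
    params = reference.default_equilibrium_params()
    inh = reference.default_inhibitors()[inhibitor] if inhibitor else None
    overrides = {"inhibitor_id": inhibitor} if inhibitor else None
    for rep in range(cfg.replicates):
        seed = _design_seed(cfg.seed, design, inhibitor, rep)
        events = simulate_titration(
            design, params, inh=inh, noise=cfg.noise,
            n_events=cfg.n_events, seed=seed, overrides=overrides,
        )
        write_conditions_table(events, outdir / f"rep{rep}")


def stage_simulate(cfg: RunConfig, workdir: Path) -> None:
    """Generate event CSVs for every configured design and replicate."""
    for design in cfg.designs:
        if design == "inhibitor_titration":
            for name in cfg.inhibitors:
                _simulate_design(cfg, design, name, workdir / "events" / f"{design}_{name}")
        else:
            _simulate_design(cfg, design, None, workdir / "events" / design)
    if cfg.run_schild:
        _simulate_design(cfg, "schild_grid", "C15", workdir / "events" / "schild_grid_C15")


def _quantify_dir(design_dir: Path) -> pd.DataFrame:
    frames = []
    for rep_dir in sorted(design_dir.glob("rep*")):
        conds = pd.read_csv(rep_dir / "conditions.csv")
        events = [read_events(rep_dir / f) for f in conds["file"]]
        df = fractions_table(events)
        df.insert(0, "replicate", rep_dir.name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def stage_quantify(workdir: Path) -> None:
    """Reduce every simulated acquisition to an oligomer-fractions table."""
    outdir = workdir / "fractions"
    outdir.mkdir(parents=True, exist_ok=True)
    for design_dir in sorted((workdir / "events").iterdir()):
        if design_dir.is_dir():
            df = _quantify_dir(design_dir)
            df.to_csv(outdir / f"{design_dir.name}.csv", index=False)


def _mean_series(table: pd.DataFrame, xcol: str, ycol: str) -> TitrationSeries:
    grouped = table.groupby(xcol)[ycol]
    mean = grouped.mean()
    std = grouped.std().fillna(0.0)
    y_err = np.maximum(std.to_numpy(), 0.2) if (std > 0).any() else None
    return TitrationSeries(x=mean.index.to_numpy(), y=mean.to_numpy(), y_err=y_err)


def _hill_fit_record(fit) -> dict:
    return {
        "bottom": fit.bottom, "top": fit.top, "k_molar": fit.k, "n": fit.n,
        "stderr": {k: (None if v is None else float(v)) for k, v in fit.stderr.items()},
        "r_squared": fit.r_squared, "constraints": fit.constraints,
        "flagged": fit.flagged, "flag_reason": fit.flag_reason,
    }


def stage_fit(workdir: Path) -> dict:
    """Hill fits per design: interface K_Ds, substrate K_S, inhibitor IC50s."""
    fits: dict = {}
    fracdir = workdir / "fractions"
    for path in sorted(fracdir.glob("*.csv")):
        table = pd.read_csv(path)
        name = path.stem
        if name.startswith("protein_dilution"):
            res = fit_assembly_affinities(table)
            fits[name] = {k: _hill_fit_record(v) for k, v in res.items()}
        elif name == "substrate_titration":
            # the Hill exponent is *determined* here (and only fixed in the
            # downstream inhibition fits), so n stays free
            series = _mean_series(table, "s_molar", "conc_f_t")
            fit = fit_hill(series, bottom=float(series.y[0]), top=float(series.y[-1]))
            fits[name] = {"k_s": _hill_fit_record(fit)}
        elif name.startswith("inhibitor_titration"):
            series = _mean_series(table, "b_molar", "conc_f_t")
            fit = fit_hill(series, fix_n=reference.HILL_N,
                           bottom=float(series.y[0]), top=float(series.y[-1]))
            fits[name] = {"ic50_tetramer": _hill_fit_record(fit)}
    (workdir / "fits.json").write_text(json.dumps(fits, indent=1, sort_keys=True) + "\n")
    return fits


def stage_pharm(cfg: RunConfig, workdir: Path, fits: Optional[dict] = None) -> dict:
    """Ki conversion, ranking summary and (optionally) Schild + OMAM."""
    if fits is None:
        fits = json.loads((workdir / "fits.json").read_text())
    lam = cfg.pharm_lambda
    if cfg.pharm_mode == "empirical_lambda" and lam is None:
        pairs = [(row["ic50"], row["ki"]) for row in reference.INHIBITOR_TABLE.values()]
        lam = calibrate_lambda(pairs).lam
    pcfg = PharmacologyConfig(
        mode=cfg.pharm_mode, s=reference.ASSAY_SUBSTRATE, k_s=reference.K_S,
        n=reference.HILL_N, lam=lam,
    )
    report: dict = {"cheng_prusoff_mode": cfg.pharm_mode, "lambda": lam, "inhibitors": {}}
    rows = []
    for name in cfg.inhibitors:
        key = f"inhibitor_titration_{name}"
        if key not in fits:
            continue
        rec = fits[key]["ic50_tetramer"]
        ic50 = rec["k_molar"]
        conv = ic50_to_ki(ic50, pcfg)
        report["inhibitors"][name] = {
            "ic50_molar": ic50, "ki_molar": conv["ki"],
            "conversion_factor": conv["factor"], "flagged": rec["flagged"],
        }
        rows.append({"inhibitor": name, "ic50_um": ic50 * 1e6, "ki_nm": conv["ki"] * 1e9})

    if cfg.run_schild:
        report["schild"] = _schild_stage(workdir)

    (workdir / "pharmacology.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    if rows:
        pd.DataFrame(rows).sort_values("ic50_um").to_csv(workdir / "summary.csv", index=False)
    return report


def _schild_stage(workdir: Path) -> dict:
    table = pd.read_csv(workdir / "fractions" / "schild_grid_C15.csv")
    ec50_by_b: dict[float, float] = {}
    curves = []
    for b, sub in table.groupby("b_molar"):
        series = _mean_series(sub, "s_molar", "conc_f_t")
        fit = fit_hill(series, bottom=float(series.y[0]), top=float(series.y[-1]))
        if not fit.flagged:
            ec50_by_b[float(b)] = fit.k
        curves.append((float(b), series.x, series.y))
    out: dict = {}
    control = ec50_by_b.get(0.0)
    if control is None:
        return {"error": "control substrate curve could not be fitted"}
    try:
        sr = schild_analysis({b: k for b, k in ec50_by_b.items() if b > 0}, control)
        out["linear"] = {
            "slope": sr.slope, "k_b_app_molar": sr.k_b_app, "r_squared": sr.r_squared,
            "linear_region_molar": list(sr.linear_region), "n_used": sr.n_used,
        }
    except ValueError as exc:
        out["linear"] = {"error": str(exc)}
    ctrl_curve = next(c for c in curves if c[0] == 0.0)
    ctrl_fit = fit_hill(
        TitrationSeries(x=ctrl_curve[1], y=ctrl_curve[2]),
        bottom=float(ctrl_curve[2][0]), top=float(ctrl_curve[2][-1]),
    )
    om = omam_global_fit(curves, e_max=min(ctrl_fit.top, 100.0), k_s=ctrl_fit.k)
    out["omam"] = {
        "e_max_fixed": om.params.e_max, "k_s_fixed_molar": om.params.k_s,
        "k_b_molar": om.params.k_b, "tau_s": om.params.tau_s, "tau_i": om.params.tau_i,
        "alpha": om.params.alpha, "beta": om.params.beta, "n": om.params.n,
        "sse": om.sse, "flagged": om.flagged,
    }
    return out


def run_pipeline(cfg: RunConfig, workdir: str | Path) -> dict:
    """Execute all stages; on failure an error manifest is written and the
    exception propagates (partial outputs are retained)."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    stages = (
        ("simulate", lambda: stage_simulate(cfg, workdir)),
        ("quantify", lambda: stage_quantify(workdir)),
        ("fit", lambda: stage_fit(workdir)),
        ("pharm", lambda: stage_pharm(cfg, workdir)),
    )
    result = None
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            (workdir / "error_manifest.json").write_text(
                json.dumps({"stage": name, "error": str(exc)}, indent=1) + "\n"
            )
            raise
        log.info("stage %s finished in %.1f s", name, time.perf_counter() - t0)
    return result
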