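"""Seeded synthetic mass-photometry event generator.

Mass photometry records one mass per landing particle, so a measurement
of an oligomerizing protein is a list of kDa values clustered at 1x/2x/4x
the monomer mass.  The generator draws species multinomially with
probabilities proportional to the *particle* concentrations from the
equilibrium solver (landing counts follow particle number, not mass),
adds Gaussian peak noise, a uniform background over the detection range,
and a hard detection floor.  It reproduces the titration designs used to
characterize the GNE system: protein serial dilutions, substrate and
inhibitor titrations at fixed protein, and a substrate-by-inhibitor
Schild grid, plus a glycinin calibration standard.

The measured distribution reflects the equilibrium at the stated
incubation concentration (assembly is kinetically trapped on the
measurement timescale after dilution), so events are always drawn at the
condition's ``c_tot``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .equilibrium import (
    Condition,
    EquilibriumParams,
    InhibitorModel,
    effective_constants,
    solve_equilibrium,
)

__all__ = [
    "NoiseModel",
    "EventList",
    "simulate_events",
    "simulate_titration",
    "simulate_calibration_standard",
    "design_conditions",
    "write_events",
    "read_events",
    "write_conditions_table",
    "DESIGNS",
]

GLYCININ_MASSES_KDA = (160.0, 320.0, 480.0, 640.0)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description.

    ``peak_cv`` is the Gaussian peak width as a fraction of species mass;
    ``background_rate`` the fraction of events drawn uniformly over
    ``background_range``; ``min_mass`` the detection floor in kDa.
    """

    peak_cv: float = 0.08
    background_rate: float = 0.02
    min_mass: float = 40.0
    background_range: tuple[float, float] = (40.0, 300.0)

    def __post_init__(self) -> None:
        if not 0 <= self.peak_cv <= 0.3:
            raise ValueError("peak_cv must lie in [0, 0.3]")
        if not 0 <= self.background_rate <= 0.2:
            raise ValueError("background_rate must lie in [0, 0.2]")


@dataclass
class EventList:
    """Single-particle masses (kDa) from one acquisition."""

    masses: np.ndarray
    condition: Condition
    seed: int
    monomer_mass: float = 46.4

    @property
    def n_events(self) -> int:
        return len(self.masses)


def _draw_species(
    rng: np.random.Generator,
    mean: float,
    sigma: float,
    count: int,
    min_mass: float,
) -> np.ndarray:
    """Draw `count` masses from a Gaussian peak, redrawing below the floor."""
    if mean < min_mass and sigma == 0:
        raise ValueError(f"species mass {mean} kDa is below the detection floor")
    out = rng.normal(mean, sigma, size=count) if sigma > 0 else np.full(count, mean)
    for _ in range(1000):
        bad = out < min_mass
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sigma, size=int(bad.sum()))
    else:
        raise ValueError(f"species peak at {mean} kDa lies almost entirely below the floor")
    return out


def simulate_events(
    params: EquilibriumParams,
    inh: Optional[InhibitorModel],
    cond: Condition,
    monomer_mass: float = 46.4,
    n_events: int = 8000,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> EventList:
    """Simulate one acquisition under an equilibrium condition.

    Species are drawn multinomially with probabilities proportional to
    the particle concentrations (M, D, T); event masses are Gaussian
    around 1x/2x/4x the monomer mass with sigma = peak_cv * mass.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    k1, k2 = effective_constants(params, inh, cond)
    sp = solve_equilibrium(k1, k2, cond.c_tot)
    probs = np.array([sp.m, sp.d, sp.t])
    probs = probs / probs.sum()

    n_bg = rng.binomial(n_events, noise.background_rate) if noise.background_rate > 0 else 0
    counts = rng.multinomial(n_events - n_bg, probs)
    chunks = []
    for k, count in zip((1, 2, 4), counts):
        if count == 0:
            continue
        mean = k * monomer_mass
        chunks.append(_draw_species(rng, mean, noise.peak_cv * mean, count, noise.min_mass))
    if n_bg:
        lo, hi = noise.background_range
        chunks.append(rng.uniform(lo, hi, size=n_bg))
    masses = np.concatenate(chunks)
    rng.shuffle(masses)
    return EventList(masses=masses, condition=cond, seed=seed, monomer_mass=monomer_mass)


def _twofold_down(top: float, n: int) -> np.ndarray:
    """n two-fold dilution steps starting at `top`, ascending order."""
    return top / 2.0 ** np.arange(n)[::-1]


def design_conditions(design: str, overrides: Optional[dict] = None) -> list[Condition]:
    """Concentration grid of a named titration design.

    Designs mirror the study layout: ``protein_dilution`` covers
    50 nM - 50 uM in 11 geometric steps (no substrate unless overridden);
    ``protein_dilution_substrate`` titrates protein 0.2 - 10 uM at 100 uM
    substrate; ``substrate_titration`` covers 7.81 - 500 uM substrate at
    800 nM protein; ``inhibitor_titration`` runs a two-fold inhibitor
    series 7.81 - 500 uM (plus a no-inhibitor control) at 800 nM protein
    and 100 uM substrate; ``schild_grid`` crosses a 97.7 nM - 800 uM
    substrate series with inhibitor levels from 2 nM to 200 uM.
    Recognized overrides: ``s``, ``b``, ``c_tot``, ``inhibitor_id`` and,
    for the grids, ``s_grid``/``b_grid``/``c_grid`` arrays.
    """
    ov = dict(overrides or {})
    inh_id = ov.get("inhibitor_id")
    if design == "protein_dilution":
        c_grid = np.asarray(ov.get("c_grid", np.geomspace(50e-9, 50e-6, 11)))
        s = float(ov.get("s", 0.0))
        return [Condition(c_tot=float(c), s=s, b=0.0) for c in c_grid]
    if design == "protein_dilution_substrate":
        c_grid = np.asarray(ov.get("c_grid", np.geomspace(0.2e-6, 10e-6, 9)))
        s = float(ov.get("s", 100e-6))
        return [Condition(c_tot=float(c), s=s, b=0.0) for c in c_grid]
    if design == "substrate_titration":
        s_grid = np.asarray(ov.get("s_grid", _twofold_down(500e-6, 7)))
        c_tot = float(ov.get("c_tot", 800e-9))
        return [Condition(c_tot=c_tot, s=float(s), b=0.0) for s in s_grid]
    if design == "inhibitor_titration":
        b_grid = np.asarray(ov.get("b_grid", np.concatenate([[0.0], _twofold_down(500e-6, 7)])))
        c_tot = float(ov.get("c_tot", 800e-9))
        s = float(ov.get("s", 100e-6))
        return [
            Condition(c_tot=c_tot, s=s, b=float(b), inhibitor_id=inh_id if b > 0 else None)
            for b in b_grid
        ]
    if design == "schild_grid":
        s_grid = np.asarray(ov.get("s_grid", _twofold_down(800e-6, 14)))
        b_grid = np.asarray(
            ov.get(
                "b_grid",
                [0.0, 2e-9, 20e-9, 0.2e-6, 0.8e-6, 2e-6, 5e-6, 10e-6, 50e-6, 200e-6],
            )
        )
        c_tot = float(ov.get("c_tot", 800e-9))
        return [
            Condition(c_tot=c_tot, s=float(s), b=float(b), inhibitor_id=inh_id if b > 0 else None)
            for b in b_grid
            for s in s_grid
        ]
    raise ValueError(
        f"unknown design {design!r}; valid designs: protein_dilution, "
        "protein_dilution_substrate, substrate_titration, inhibitor_titration, schild_grid"
    )


DESIGNS = (
    "protein_dilution",
    "protein_dilution_substrate",
    "substrate_titration",
    "inhibitor_titration",
    "schild_grid",
)


def simulate_titration(
    design: str,
    params: EquilibriumParams,
    inh: Optional[InhibitorModel] = None,
    noise: NoiseModel = NoiseModel(),
    n_events: int = 8000,
    seed: int = 0,
    overrides: Optional[dict] = None,
) -> list[EventList]:
    """Simulate every condition of a titration design.

    Per-condition seeds are spawned deterministically from ``seed`` so the
    full design is reproducible while acquisitions stay independent.
    """
    conditions = design_conditions(design, overrides)
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=len(conditions))
    return [
        simulate_events(params, inh, cond, n_events=n_events, noise=noise, seed=int(s))
        for cond, s in zip(conditions, child_seeds)
    ]


def simulate_calibration_standard(
    n_events: int = 8000,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    weights: Optional[Sequence[float]] = None,
    masses: Sequence[float] = GLYCININ_MASSES_KDA,
) -> EventList:
    """Simulate a glycinin-like multi-species calibration standard.

    Glycinin forms trimers/hexamers/nonamers/dodecamers at 160/320/480/640
    kDa; weights default to equal.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    w = np.full(len(masses), 1.0 / len(masses)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    counts = rng.multinomial(n_events, w)
    chunks = [
        _draw_species(rng, m, noise.peak_cv * m, c, noise.min_mass)
        for m, c in zip(masses, counts)
        if c > 0
    ]
    masses_out = np.concatenate(chunks)
    rng.shuffle(masses_out)
    return EventList(
        masses=masses_out,
        condition=Condition(c_tot=1.0e-8),
        seed=seed,
        monomer_mass=float(masses[0]),
    )


# ---------------------------------------------------------------------------
# disk interface: event CSVs + JSON sidecars + conditions table


def write_events(events: EventList, path: str | Path) -> Path:
    """Write one event list as CSV (column ``mass_kda``) + JSON sidecar."""
    path = Path(path)
    pd.DataFrame({"mass_kda": events.masses}).to_csv(path, index=False, float_format="%.6f")
    sidecar = {
        "c_tot_molar": events.condition.c_tot,
        "s_molar": events.condition.s,
        "b_molar": events.condition.b,
        "inhibitor_id": events.condition.inhibitor_id,
        "seed": events.seed,
        "monomer_mass_kda": events.monomer_mass,
        "n_events": events.n_events,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
    return path


def read_events(path: str | Path) -> EventList:
    """Read an event CSV written by :func:`write_events`."""
    path = Path(path)
    masses = pd.read_csv(path)["mass_kda"].to_numpy()
    meta_path = path.with_suffix(".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        cond = Condition(
            c_tot=meta["c_tot_molar"],
            s=meta["s_molar"],
            b=meta["b_molar"],
            inhibitor_id=meta.get("inhibitor_id"),
        )
        return EventList(
            masses=masses,
            condition=cond,
            seed=meta.get("seed", -1),
            monomer_mass=meta.get("monomer_mass_kda", 46.4),
        )
    return EventList(masses=masses, condition=Condition(c_tot=float("nan")), seed=-1)


def write_conditions_table(
    event_lists: Sequence[EventList], outdir: str | Path, prefix: str = "events"
) -> Path:
    """Write each event list plus a conditions-table CSV describing them."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, ev in enumerate(event_lists):
        fname = f"{prefix}_{i:03d}.csv"
        write_events(ev, outdir / fname)
        rows.append(
            {
                "file": fname,
                "c_tot_molar": ev.condition.c_tot,
                "s_molar": ev.condition.s,
                "b_molar": ev.condition.b,
                "inhibitor_id": ev.condition.inhibitor_id or "",
            }
        )
    table = outdir / "conditions.csv"
    pd.DataFrame(rows).to_csv(table, index=False)
    return table
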