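"""Reference parameter set of the GNE assembly system.

Houses the measured constants of the UDP-GlcNAc 2-epimerase (GNE)
monomer-dimer-tetramer system that the synthetic-data generator uses as
ground truth: interface dissociation constants with and without
substrate, substrate affinity and cooperativity, the operational-model
parameters of C15 inhibition, and the IC50/Ki table of the three
characterized inhibitors (C5, C13, C15).

The interface constants measured "with substrate" refer to the standard
assay concentration of 100 uM UDP-GlcNAc (the plateau of tetramer
formation), not to true saturation, so the default
:class:`~oligomp.equilibrium.EquilibriumParams` back-computes the
saturated constants such that the effective constants at 100 uM equal
the measured values.  Inhibitor binding constants in the generator are
calibrated once, deterministically, so that the noise-free model curve
fitted with the study's Hill conventions reproduces each measured IC50.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from .equilibrium import Condition, EquilibriumParams, InhibitorModel, species_fractions
from .fitting import TitrationSeries, fit_hill

__all__ = [
    "MONOMER_MASS_KDA",
    "OBSERVED_MASSES_KDA",
    "KD0_MM", "KD0_DD", "KDS_MM", "KDS_DD",
    "KD0_CALC_MM", "KD0_CALC_DD", "KDS_CALC_MM", "KDS_CALC_DD",
    "K_S", "HILL_N", "E_MAX",
    "TAU_S", "TAU_I", "OMAM_ALPHA", "OMAM_BETA", "OMAM_KB",
    "SCHILD_KB_APP", "SCHILD_SLOPE",
    "ASSAY_PROTEIN", "ASSAY_SUBSTRATE",
    "INHIBITOR_TABLE",
    "default_equilibrium_params",
    "default_inhibitors",
    "model_ic50",
]

MONOMER_MASS_KDA = 46.4
#: apparent peak positions read off the mass histograms (monomer, dimer, tetramer)
OBSERVED_MASSES_KDA = (50.0, 90.0, 180.0)

# interface dissociation constants from Hill-logistic binding plots
KD0_MM = 12.6e-9   # monomer-monomer, no substrate (molar)
KD0_DD = 9.6e-6    # dimer-dimer, no substrate
KDS_MM = 37.2e-9   # monomer-monomer at 100 uM substrate
KDS_DD = 98.1e-9   # dimer-dimer at 100 uM substrate

# law-of-mass-action (calculated) counterparts
KD0_CALC_MM = 25.8e-9
KD0_CALC_DD = 76.9e-6
KDS_CALC_MM = 65.3e-9
KDS_CALC_DD = 221.3e-9

K_S = 34.6e-6      # substrate half-saturation (molar)
HILL_N = 1.3       # tetramer-curve Hill coefficient
E_MAX = 68.3       # maximal tetramer response (% of total protein)

# OMAM global-fit parameters for C15
TAU_S = 17.6
TAU_I = 0.02
OMAM_ALPHA = 0.02
OMAM_BETA = 0.0
OMAM_KB = 25.2e-9

SCHILD_KB_APP = 0.7e-6
SCHILD_SLOPE = 1.1

ASSAY_PROTEIN = 800e-9     # fixed protein concentration of titration assays
ASSAY_SUBSTRATE = 100e-6   # standard substrate concentration

#: measured tetramer-destabilization IC50 (molar) and Ki (molar) per inhibitor,
#: at 800 nM protein + 100 uM substrate
INHIBITOR_TABLE = {
    "C5": {"ic50": 19.7e-6, "ki": 517.2e-9, "gamma_d": 1.0},
    "C13": {"ic50": 19.4e-6, "ki": 508.3e-9, "gamma_d": 50.0},
    "C15": {"ic50": 3.1e-6, "ki": 82.6e-9, "gamma_d": 50.0},
}


@lru_cache(maxsize=1)
def default_equilibrium_params() -> EquilibriumParams:
    """Generator ground truth for the GNE system."""
    return EquilibriumParams.from_reference_substrate(
        k1_0=KD0_MM,
        k1_ref=KDS_MM,
        k2_0=KD0_DD,
        k2_ref=KDS_DD,
        k_s=K_S,
        s_ref=ASSAY_SUBSTRATE,
        n_link=HILL_N,
    )


def model_ic50(
    params: EquilibriumParams,
    inh: InhibitorModel,
    c_tot: float = ASSAY_PROTEIN,
    s: float = ASSAY_SUBSTRATE,
    b_grid=None,
) -> float:
    """Noise-free tetramer-destabilization IC50 of the equilibrium model.

    Computes exact tetramer concentration-fractions over the inhibitor
    grid and fits them with the study convention (Hill n fixed at 1.3,
    plateaus constrained at the endpoint values), returning the fitted
    midpoint.
    """
    if b_grid is None:
        b_grid = np.concatenate([[0.0], 500e-6 / 2.0 ** np.arange(7)[::-1]])
    y = []
    for b in b_grid:
        sp = species_fractions(params, inh, Condition(c_tot=c_tot, s=s, b=float(b)))
        y.append(100.0 * sp.conc_fractions()[2])
    y = np.asarray(y)
    series = TitrationSeries(x=np.asarray(b_grid), y=y, axis_kind="inhibitor")
    fit = fit_hill(series, fix_n=HILL_N, bottom=float(y[0]), top=float(y[-1]))
    return fit.k


def _calibrate_kb(target_ic50: float, gamma_d: float, alpha: float = OMAM_ALPHA) -> float:
    """Solve for the inhibitor K_B whose model IC50 equals the target.

    The fitted IC50 increases monotonically with K_B (a weaker binder
    needs more compound), so bisection in log10 K_B converges cleanly.
    """
    params = default_equilibrium_params()

    def f(log_kb: float) -> float:
        inh = InhibitorModel(k_b=10.0**log_kb, alpha=alpha, gamma_d=gamma_d)
        return math.log10(model_ic50(params, inh)) - math.log10(target_ic50)

    lo, hi = -10.0, -3.0
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise RuntimeError("IC50 target outside the calibratable range")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-6:
            break
    return 10.0 ** (0.5 * (lo + hi))


@lru_cache(maxsize=1)
def default_inhibitors() -> dict:
    """Inhibitor models calibrated to the measured IC50s.

    C5 destabilizes tetramers only (``gamma_d = 1``); C13 and C15
    additionally weaken the monomer-monomer interface.  All three share
    the substrate-binding-site competition described by ``alpha``.
    """
    return {
        name: InhibitorModel(
            k_b=_calibrate_kb(row["ic50"], row["gamma_d"]),
            alpha=OMAM_ALPHA,
            gamma_d=row["gamma_d"],
        )
        for name, row in INHIBITOR_TABLE.items()
    }
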