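"""Mass-action core of the monomer-dimer-tetramer assembly model.

The GNE epimerase assembles stepwise, monomer (M) to dimer (D) to
tetramer (T), with only the tetramer enzymatically active.  The two
interfaces are characterized by dissociation constants

    K1 = [M]^2 / [D]        (monomer-monomer interface)
    K2 = [D]^2 / [T]        (dimer-dimer interface)

Substrate (UDP-GlcNAc) binding tightens the dimer-dimer interface;
orthosteric inhibitors displace substrate from its pocket and thereby
revert K2 toward its apo value, and the more potent compounds
additionally loosen the monomer-monomer interface.  This module solves
the conservation equation for the species concentrations, applies the
ligand linkage to the interface constants, and provides the
operational-model (OMAM) response function used for global fits of
substrate-response curves under allosteric inhibition.

All concentrations are molar.  Mass units (kDa) appear only at the
I/O layer of the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "EquilibriumParams",
    "InhibitorModel",
    "Condition",
    "SpeciesConcentrations",
    "OMAMParams",
    "solve_equilibrium",
    "effective_constants",
    "mass_action_kd",
    "omam_response",
    "species_fractions",
]


@dataclass(frozen=True)
class EquilibriumParams:
    """Interface dissociation constants and substrate-linkage parameters.

    Parameters
    ----------
    k1_0, k1_s
        Monomer-monomer dissociation constant (molar) without substrate
        and at substrate saturation.
    k2_0, k2_s
        Dimer-dimer dissociation constant (molar) without substrate and
        at substrate saturation.
    k_s
        Substrate concentration of half-maximal occupancy (molar).
    n_link
        Hill exponent of the substrate-occupancy linkage; values above 1
        encode positive cooperativity of substrate action on assembly.
    """

    k1_0: float
    k1_s: float
    k2_0: float
    k2_s: float
    k_s: float
    n_link: float = 1.3

    def __post_init__(self) -> None:
        for name in ("k1_0", "k1_s", "k2_0", "k2_s", "k_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.5 <= self.n_link <= 4:
            raise ValueError("n_link must lie in [0.5, 4]")

    @classmethod
    def from_reference_substrate(
        cls,
        k1_0: float,
        k1_ref: float,
        k2_0: float,
        k2_ref: float,
        k_s: float,
        s_ref: float,
        n_link: float = 1.3,
    ) -> "EquilibriumParams":
        """Build parameters from constants observed at a finite substrate level.

        Titration studies report the interface constants at a reference
        substrate concentration ``s_ref`` (e.g. the 100 uM plateau
        concentration) rather than at true saturation.  This constructor
        back-computes the saturated constants so that the effective
        constants at ``s_ref`` equal the observed values exactly.
        """
        x = (s_ref / k_s) ** n_link
        theta = x / (1.0 + x)
        k1_sat = math.exp((math.log(k1_ref) - (1 - theta) * math.log(k1_0)) / theta)
        k2_sat = math.exp((math.log(k2_ref) - (1 - theta) * math.log(k2_0)) / theta)
        return cls(k1_0=k1_0, k1_s=k1_sat, k2_0=k2_0, k2_s=k2_sat, k_s=k_s, n_link=n_link)


@dataclass(frozen=True)
class InhibitorModel:
    """Phenomenological description of an orthosteric assembly inhibitor.

    ``k_b`` is the inhibitor dissociation constant; ``alpha`` the binding
    cooperativity between inhibitor and substrate (``alpha < 1`` means
    negative cooperativity, i.e. mutual displacement); ``gamma_d`` the
    fold-weakening of the monomer-monomer constant at full inhibitor
    occupancy.  ``gamma_d = 1`` describes a tetramer-only destabilizer
    (C5-like); ``gamma_d > 1`` additionally disrupts dimers (C13/C15-like).
    """

    k_b: float
    alpha: float = 0.0
    gamma_d: float = 1.0

    def __post_init__(self) -> None:
        if not self.k_b > 0:
            raise ValueError("k_b must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.gamma_d < 1:
            raise ValueError("gamma_d must be >= 1")


@dataclass(frozen=True)
class Condition:
    """One experimental condition (all concentrations molar).

    ``c_tot`` is total protein in monomer equivalents, ``s`` the
    substrate and ``b`` the inhibitor concentration.
    """

    c_tot: float
    s: float = 0.0
    b: float = 0.0
    inhibitor_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.c_tot < 0 or self.s < 0 or self.b < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class SpeciesConcentrations:
    """Particle concentrations (molar) of monomer, dimer and tetramer."""

    m: float
    d: float
    t: float

    @property
    def c_tot(self) -> float:
        """Total protein in monomer equivalents."""
        return self.m + 2.0 * self.d + 4.0 * self.t

    def count_fractions(self) -> tuple[float, float, float]:
        """Particle-count fractions (what a landing-event counter sees)."""
        tot = self.m + self.d + self.t
        return self.m / tot, self.d / tot, self.t / tot

    def conc_fractions(self) -> tuple[float, float, float]:
        """Monomer-equivalent (mass) fractions of total protein."""
        tot = self.c_tot
        return self.m / tot, 2.0 * self.d / tot, 4.0 * self.t / tot


@dataclass(frozen=True)
class OMAMParams:
    """Parameters of the Hill-modified operational model of allosterically
    modulated agonism (OMAM).

    ``tau_s`` and ``tau_i`` are the operational efficacies of substrate
    and inhibitor, ``alpha`` the binding and ``beta`` the operational
    cooperativity between them, ``k_s``/``k_b`` their affinities, and
    ``e_max`` (percent) the maximal response with Hill slope ``n``.
    """

    e_max: float
    k_s: float
    k_b: float
    tau_s: float
    tau_i: float
    alpha: float
    beta: float
    n: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.e_max <= 100:
            raise ValueError("e_max must lie in (0, 100]")
        if self.k_s <= 0 or self.k_b <= 0:
            raise ValueError("k_s and k_b must be positive")
        if min(self.tau_s, self.tau_i, self.alpha, self.beta) < 0:
            raise ValueError("tau_s, tau_i, alpha, beta must be >= 0")
        if self.n <= 0:
            raise ValueError("n must be positive")


_MAX_BISECT = 200


def solve_equilibrium(k1: float, k2: float, c_tot: float) -> SpeciesConcentrations:
    """Solve the stepwise assembly equilibrium for given effective constants.

    Finds the unique non-negative free-monomer concentration M satisfying
    monomer-equivalent conservation

        M + 2 M^2/K1 + 4 M^4/(K1^2 K2) = C_tot

    with D = M^2/K1 and T = D^2/K2.  The left side is strictly increasing
    in M, so plain bisection on [0, C_tot] converges unconditionally.
    """
    if k1 <= 0 or k2 <= 0 or c_tot <= 0:
        raise ValueError("k1, k2 and c_tot must be positive")

    def excess(m: float) -> float:
        d = m * m / k1
        return m + 2.0 * d + 4.0 * d * d / k2 - c_tot

    lo, hi = 0.0, c_tot
    for _ in range(_MAX_BISECT):
        mid = 0.5 * (lo + hi)
        if mid <= lo or mid >= hi:  # adjacent doubles: converged
            break
        if excess(mid) > 0.0:
            hi = mid
        else:
            lo = mid
    m = hi if excess(hi) == 0.0 else lo
    d = m * m / k1
    t = d * d / k2
    return SpeciesConcentrations(m=m, d=d, t=t)


def effective_constants(
    params: EquilibriumParams,
    inh: Optional[InhibitorModel],
    cond: Condition,
) -> tuple[float, float]:
    """Interface constants under substrate/inhibitor linkage.

    Substrate occupancy follows an allosteric ternary-complex expression
    raised to the linkage Hill exponent,

        theta = x / (1 + x + b + alpha*x*b),   x = (S/K_S)^n,  b = B/K_B,

    and the interface constants interpolate log-linearly between their
    apo and substrate-saturated values.  Fractional inhibitor occupancy
    phi_B = (b + alpha*x*b) / (1 + x + b + alpha*x*b) additionally
    weakens the monomer-monomer interface by ``gamma_d`` at saturation.
    Returns ``(k1_eff, k2_eff)``.
    """
    x = (cond.s / params.k_s) ** params.n_link if cond.s > 0 else 0.0
    if inh is not None and cond.b > 0:
        b = cond.b / inh.k_b
        alpha = inh.alpha
        log_gamma = math.log(inh.gamma_d)
    else:
        b, alpha, log_gamma = 0.0, 0.0, 0.0
    denom = 1.0 + x + b + alpha * x * b
    theta = x / denom
    phi_b = (b + alpha * x * b) / denom
    log_k1 = (1 - theta) * math.log(params.k1_0) + theta * math.log(params.k1_s)
    log_k2 = (1 - theta) * math.log(params.k2_0) + theta * math.log(params.k2_s)
    log_k1 += phi_b * log_gamma
    return math.exp(log_k1), math.exp(log_k2)


def mass_action_kd(conc: SpeciesConcentrations) -> dict:
    """Back-calculate interface constants from species concentrations.

    Returns ``kd_mm_calc = M^2/D`` and ``kd_dd_calc = D^2/T``.  A zero
    denominator yields NaN with the corresponding ``*_defined`` flag set
    to False rather than raising.
    """
    if conc.d > 0:
        kd_mm, mm_ok = conc.m * conc.m / conc.d, True
    else:
        kd_mm, mm_ok = float("nan"), False
    if conc.t > 0:
        kd_dd, dd_ok = conc.d * conc.d / conc.t, True
    else:
        kd_dd, dd_ok = float("nan"), False
    return {
        "kd_mm_calc": kd_mm,
        "kd_dd_calc": kd_dd,
        "kd_mm_defined": mm_ok,
        "kd_dd_defined": dd_ok,
    }


def species_fractions(
    params: EquilibriumParams,
    inh: Optional[InhibitorModel],
    cond: Condition,
) -> SpeciesConcentrations:
    """Equilibrium species under a full condition (linkage + solver)."""
    k1, k2 = effective_constants(params, inh, cond)
    return solve_equilibrium(k1, k2, cond.c_tot)


def omam_response(s, b, p: OMAMParams):
    """Hill-modified OMAM response (percent) at substrate ``s``, inhibitor ``b``.

    E = E_max * A^n / (C^n + A^n) with

        A = tau_S*S*(K_B + alpha*beta*B) + tau_I*B*K_S
        C = S*K_B + K_S*K_B + K_S*B + alpha*S*B

    At ``b = 0`` this reduces to the two-parameter operational Hill curve
    E_max*(tau_S*S)^n / ((S + K_S)^n + (tau_S*S)^n).  Accepts scalars or
    numpy arrays.
    """
    s = np.asarray(s, dtype=float)
    b = np.asarray(b, dtype=float)
    a = p.tau_s * s * (p.k_b + p.alpha * p.beta * b) + p.tau_i * b * p.k_s
    c = s * p.k_b + p.k_s * p.k_b + p.k_s * b + p.alpha * s * b
    with np.errstate(divide="ignore", invalid="ignore"):
        e = p.e_max * a**p.n / (c**p.n + a**p.n)
    e = np.where(a == 0, 0.0, e)
    if e.ndim == 0:
        return float(e)
    return e
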