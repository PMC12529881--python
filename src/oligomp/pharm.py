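"""Inhibition analytics: IC50-to-Ki conversion, Schild analysis and the
OMAM global fit.

Three explicit Cheng-Prusoff conversion modes are exposed because the
appropriate correction for assembly inhibition with cooperative substrate
linkage is not a settled closed form:

* ``classical``          Ki = IC50 / (1 + S/K_S)
* ``hill``               Ki = IC50 / (1 + S/K_S)^n
* ``empirical_lambda``   Ki = IC50 / lambda, with lambda calibrated from
                         reference IC50/Ki pairs (:func:`calibrate_lambda`).

Schild analysis regresses log10(CR - 1) on log10([B]) over the linear
region, where CR = EC50(B)/EC50(0); a purely competitive antagonist gives
slope 1 and x-intercept log10(K_B).  The allosteric ternary-complex model
(ATCM) alternative fits CR = (1 + B/K_B)/(1 + alpha*B/K_B).  The OMAM
global fit shares one parameter set across substrate-response curves at
several inhibitor concentrations (multi-start least squares, seeded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .equilibrium import OMAMParams, omam_response

__all__ = [
    "PharmacologyConfig",
    "SchildResult",
    "ic50_to_ki",
    "calibrate_lambda",
    "schild_analysis",
    "schild_nonlinear",
    "omam_global_fit",
    "OMAMFitResult",
]


@dataclass(frozen=True)
class PharmacologyConfig:
    """Cheng-Prusoff conversion settings.

    ``mode`` must be stated explicitly; ``lam`` is the empirical
    IC50/Ki factor (only used in ``empirical_lambda`` mode); ``s`` the
    assay substrate concentration, ``k_s`` its affinity and ``n`` the
    Hill exponent (used in ``hill`` mode).
    """

    mode: str
    s: float = 100e-6
    k_s: float = 34.6e-6
    n: float = 1.3
    lam: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("classical", "hill", "empirical_lambda"):
            raise ValueError("mode must be classical, hill or empirical_lambda")
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lambda must be positive")


def ic50_to_ki(ic50: float, cfg: PharmacologyConfig) -> dict:
    """Convert an IC50 into a Ki under the configured conversion mode."""
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    if cfg.mode == "classical":
        factor = 1.0 + cfg.s / cfg.k_s
    elif cfg.mode == "hill":
        factor = (1.0 + cfg.s / cfg.k_s) ** cfg.n
    else:
        if cfg.lam is None:
            raise ValueError("empirical_lambda mode requires lambda")
        factor = cfg.lam
    return {"ki": ic50 / factor, "mode": cfg.mode, "factor": factor}


@dataclass(frozen=True)
class LambdaCalibration:
    lam: float
    ratios: tuple
    residuals: tuple  # relative deviation of each pair ratio from lambda
    consistent: bool  # all residuals within 10%


def calibrate_lambda(ic50_ki_pairs: Sequence[tuple[float, float]]) -> LambdaCalibration:
    """Back-derive the empirical IC50/Ki factor from reference pairs.

    lambda is the geometric mean of the per-pair IC50/Ki ratios; pairs
    deviating from it by more than 10% flag the calibration inconsistent.
    """
    if len(ic50_ki_pairs) < 1:
        raise ValueError("need at least one IC50/Ki pair")
    ratios = []
    for ic50, ki in ic50_ki_pairs:
        if ic50 <= 0 or ki <= 0:
            raise ValueError("IC50 and Ki must be positive")
        ratios.append(ic50 / ki)
    lam = float(np.exp(np.mean(np.log(ratios))))
    residuals = tuple(abs(r / lam - 1.0) for r in ratios)
    return LambdaCalibration(
        lam=lam,
        ratios=tuple(ratios),
        residuals=residuals,
        consistent=max(residuals) <= 0.10,
    )


@dataclass
class SchildResult:
    points: list  # (B, CR) pairs actually used
    slope: float
    k_b_app: float
    r_squared: float
    linear_region: tuple[float, float]
    n_used: int


def _concentration_ratios(ec50_by_b: dict, ec50_control: float) -> list[tuple[float, float]]:
    if ec50_control <= 0:
        raise ValueError("control EC50 must be positive")
    return sorted((float(b), ec50 / ec50_control) for b, ec50 in ec50_by_b.items() if b > 0)


def schild_analysis(
    ec50_by_b: dict,
    ec50_control: float,
    linear_region: Optional[tuple[float, float]] = None,
    cr_threshold: float = 0.2,
) -> SchildResult:
    """Linear Schild regression of log10(CR - 1) on log10([B]).

    ``linear_region`` bounds (molar) restrict the antagonist
    concentrations used; by default all points with CR - 1 above
    ``cr_threshold`` are taken (the deterministic stand-in for the
    empirical no-effect / linear split).  The apparent antagonist
    affinity K_B,app is 10^(x-intercept).
    """
    pairs = _concentration_ratios(ec50_by_b, ec50_control)
    usable = [(b, cr) for b, cr in pairs if cr > 1.0]
    if not usable:
        raise ValueError("no-effect region only: no concentration ratios above 1")
    if linear_region is not None:
        lo, hi = linear_region
        sel = [(b, cr) for b, cr in usable if lo <= b <= hi]
    else:
        sel = [(b, cr) for b, cr in usable if cr - 1.0 > cr_threshold]
    if len(sel) < 2:
        raise ValueError("need at least 2 usable points in the linear region")
    b = np.log10([p[0] for p in sel])
    y = np.log10([p[1] - 1.0 for p in sel])
    slope, intercept = np.polyfit(b, y, 1)
    yhat = slope * b + intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    k_b_app = 10.0 ** (-intercept / slope)
    return SchildResult(
        points=sel,
        slope=float(slope),
        k_b_app=float(k_b_app),
        r_squared=r2,
        linear_region=(sel[0][0], sel[-1][0]),
        n_used=len(sel),
    )


def schild_nonlinear(ec50_by_b: dict, ec50_control: float) -> dict:
    """Fit the ATCM concentration-ratio model CR = (1+B/K_B)/(1+alpha*B/K_B).

    Least squares on log CR; returns ``alpha``, ``k_b`` and a ``flagged``
    marker set when the data carry no shift (CR = 1, the alpha = 1 null
    case) or when the optimizer fails.
    """
    pairs = _concentration_ratios(ec50_by_b, ec50_control)
    if len(pairs) < 3:
        raise ValueError("need at least 3 antagonist concentrations")
    b = np.array([p[0] for p in pairs])
    log_cr = np.log([p[1] for p in pairs])
    if np.max(np.abs(log_cr)) < 0.02:
        return {"alpha": float("nan"), "k_b": float("nan"), "flagged": True,
                "flag_reason": "concentration ratios indistinguishable from 1"}

    def resid(theta):
        log_kb, logit_a = theta
        kb = 10.0**log_kb
        alpha = expit(logit_a)  # constrain alpha to (0, 1)
        model = np.log1p(b / kb) - np.log1p(alpha * b / kb)
        return model - log_cr

    best = None
    for log_kb0 in np.linspace(np.log10(b.min()) - 2, np.log10(b.max()) + 1, 7):
        for logit_a0 in (-6.0, -2.0, 0.0):
            sol = least_squares(resid, x0=[log_kb0, logit_a0], method="lm")
            if best is None or sol.cost < best.cost:
                best = sol
    kb = 10.0 ** best.x[0]
    alpha = float(expit(best.x[1]))
    return {
        "alpha": float(alpha),
        "k_b": float(kb),
        "flagged": not best.success,
        "flag_reason": "" if best.success else "optimizer did not converge",
    }


@dataclass
class OMAMFitResult:
    params: OMAMParams
    sse: float
    flagged: bool
    flag_reason: str
    unidentifiable: tuple = ()


def omam_global_fit(
    curves: Sequence[tuple[float, np.ndarray, np.ndarray]],
    e_max: float,
    k_s: float,
    y_err: Optional[Sequence[np.ndarray]] = None,
    n_starts: int = 12,
    seed: int = 12345,
) -> OMAMFitResult:
    """Global OMAM fit across substrate-response curves at several
    inhibitor concentrations.

    ``curves`` is a sequence of ``(B, S_array, response_array)`` with the
    response in percent; ``e_max`` and ``k_s`` are fixed from the
    control-titration analysis.  Free parameters K_B, tau_S, tau_I
    (log scale), alpha, beta (bounded [0, 100]) and Hill n are estimated
    by multi-start trust-region least squares; starts are log-uniform
    with a fixed seed and the best final SSE wins.
    """
    if len(curves) < 1:
        raise ValueError("need at least one curve")
    b_values = [c[0] for c in curves]
    only_control = all(b == 0 for b in b_values)
    if not only_control and 0.0 not in b_values:
        raise ValueError("a control (B = 0) curve is required")

    s_all = np.concatenate([np.asarray(c[1], float) for c in curves])
    b_all = np.concatenate([np.full(len(c[1]), c[0], dtype=float) for c in curves])
    y_all = np.concatenate([np.asarray(c[2], float) for c in curves])
    if y_err is not None:
        w_all = 1.0 / np.maximum(np.concatenate([np.asarray(e, float) for e in y_err]), 1e-6)
    else:
        w_all = None

    # theta = (log10 k_b, log10 tau_s, log10 tau_i, alpha, beta, n)
    lower = np.array([-12.0, -3.0, -4.0, 0.0, 0.0, 0.3])
    upper = np.array([-3.0, 3.0, 3.0, 100.0, 100.0, 4.0])

    def unpack(theta):
        return OMAMParams(
            e_max=e_max, k_s=k_s,
            k_b=10.0 ** theta[0],
            tau_s=10.0 ** theta[1],
            tau_i=10.0 ** theta[2],
            alpha=theta[3], beta=theta[4], n=theta[5],
        )

    def resid(theta):
        r = omam_response(s_all, b_all, unpack(theta)) - y_all
        return r if w_all is None else r * w_all

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        x0 = np.empty(6)
        x0[0] = rng.uniform(-9, -5)           # k_b: 1 nM .. 10 uM scale
        x0[1] = rng.uniform(-1, 2)            # tau_s
        x0[2] = rng.uniform(-3, 1)            # tau_i
        x0[3] = 10.0 ** rng.uniform(-3, 1)    # alpha
        x0[4] = 10.0 ** rng.uniform(-3, 1)    # beta
        x0[5] = rng.uniform(0.7, 2.0)         # n
        try:
            sol = least_squares(resid, x0=x0, bounds=(lower, upper), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all OMAM fit starts failed")

    params = unpack(best.x)
    unident = ("k_b", "tau_i", "alpha", "beta") if only_control else ()
    return OMAMFitResult(
        params=params,
        sse=float(2 * best.cost),
        flagged=only_control or not best.success,
        flag_reason="only control curve supplied: inhibitor parameters unidentifiable"
        if only_control
        else ("" if best.success else "optimizer did not converge"),
        unidentifiable=unident,
    )
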