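"""Hill-logistic fitting of titration series.

Binding curves (oligomer fraction versus free-species, substrate or
inhibitor concentration) are fitted with the four-parameter Hill-logistic
model

    y = bottom + (top - bottom) * x^n / (K^n + x^n)

where K is interpreted as K_D, EC50 or IC50 depending on the titration
axis, and decreasing (inhibition) curves simply have top < bottom.
Plateaus can be constrained to approximate asymptotes (box bounds of
+/- 5 percentage points around a supplied value) and the Hill exponent
can be fixed, matching the conventions used for the tetramer curves of
the GNE study (n fixed at 1.3) versus the remaining curves (n free).

Interface affinities are extracted from stepwise *conversion shares*:
the monomer share M/(M+D) plotted against free monomer and the tetramer
share T/(D+T) against free dimer.  Under pure mass action both are exact
rectangular hyperbolas whose midpoints equal the interface constants K1
and K2, so the fitted midpoint is a consistent estimator of the
underlying dissociation constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "TitrationSeries",
    "HillFit",
    "hill_logistic",
    "free_species_concentrations",
    "fit_hill",
    "fit_assembly_affinities",
]


@dataclass
class TitrationSeries:
    """One titration curve: concentrations (molar) versus fraction (%)."""

    x: np.ndarray
    y: np.ndarray
    y_err: Optional[np.ndarray] = None
    axis_kind: str = "concentration"  # protein|free_monomer|free_dimer|substrate|inhibitor
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y_err is not None:
            self.y_err = np.asarray(self.y_err, dtype=float)
        if np.any(self.x < 0):
            raise ValueError("concentrations must be non-negative")


@dataclass
class HillFit:
    """Result of one Hill-logistic fit (K in molar, y in %)."""

    bottom: float
    top: float
    k: float
    n: float
    stderr: dict
    r_squared: float
    constraints: dict
    flagged: bool = False
    flag_reason: str = ""

    def predict(self, x):
        return hill_logistic(x, self.bottom, self.top, self.k, self.n)


def hill_logistic(x, bottom, top, k, n):
    """Four-parameter Hill-logistic curve; top < bottom gives inhibition."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = x**n / (k**n + x**n)
    frac = np.where(x == 0, 0.0, frac)
    out = bottom + (top - bottom) * frac
    if out.ndim == 0:
        return float(out)
    return out


def free_species_concentrations(fractions, c_tot: float) -> dict:
    """Free monomer and free dimer (particle) concentrations from
    concentration fractions.

    ``fractions`` may be an :class:`~oligomp.histogram.OligomerFractions`
    or a (f_M, f_D, f_T) triple of monomer-equivalent fractions (0-1).
    """
    conc_f = getattr(fractions, "conc_fractions", fractions)
    f_m, f_d = conc_f[0], conc_f[1]
    return {"m_free": f_m * c_tot, "d_free": f_d * c_tot / 2.0}


def fit_hill(
    series: TitrationSeries,
    fix_n: Optional[float] = None,
    bottom: Optional[float] = None,
    top: Optional[float] = None,
    plateau_halfwidth: float = 5.0,
    n_bounds: tuple[float, float] = (0.3, 4.0),
) -> HillFit:
    """Weighted least-squares Hill-logistic fit of one titration series.

    ``bottom``/``top`` supply approximate plateau values which become box
    bounds of +/- ``plateau_halfwidth`` percentage points; ``fix_n`` pins
    the Hill exponent.  Weights are 1/sigma^2 when ``y_err`` is given.
    The fit is flagged (not raised) when it does not converge, when the
    midpoint lands outside the data range by more than a factor 100, or
    when the series shows no transition at all.
    """
    x, y = series.x, series.y
    if len(x) < 4:
        raise ValueError("need at least 4 points to fit a Hill curve")
    pos = x > 0
    if pos.sum() < 3:
        raise ValueError("need at least 3 non-zero concentrations")

    y_span = float(y.max() - y.min())
    constraints = {
        "fix_n": fix_n,
        "bottom": bottom,
        "top": top,
        "plateau_halfwidth": plateau_halfwidth,
    }
    if y_span < 1.0:  # flat series: no transition to fit
        return HillFit(
            bottom=float(y.mean()),
            top=float(y.mean()),
            k=float("nan"),
            n=float("nan"),
            stderr={},
            r_squared=0.0,
            constraints=constraints,
            flagged=True,
            flag_reason="flat series: no transition in the data",
        )

    increasing = y[np.argmax(x)] >= y[np.argmin(x)]
    b0 = bottom if bottom is not None else (y.min() if increasing else y.max())
    t0 = top if top is not None else (y.max() if increasing else y.min())
    mid = 0.5 * (b0 + t0)
    k0 = float(x[pos][np.argmin(np.abs(y[pos] - mid))])

    params = lmfit.Parameters()
    if bottom is not None:
        params.add("bottom", value=bottom, min=bottom - plateau_halfwidth, max=bottom + plateau_halfwidth)
    else:
        params.add("bottom", value=b0)
    if top is not None:
        params.add("top", value=top, min=top - plateau_halfwidth, max=top + plateau_halfwidth)
    else:
        params.add("top", value=t0)
    params.add("log_k", value=np.log10(k0), min=np.log10(x[pos].min()) - 4, max=np.log10(x.max()) + 4)
    if fix_n is not None:
        params.add("n", value=fix_n, vary=False)
    else:
        params.add("n", value=1.0, min=n_bounds[0], max=n_bounds[1])

    weights = None if series.y_err is None else 1.0 / np.maximum(series.y_err, 1e-6)

    def residual(p):
        r = hill_logistic(x, p["bottom"], p["top"], 10.0 ** p["log_k"], p["n"]) - y
        return r if weights is None else r * weights

    result = lmfit.minimize(residual, params, method="leastsq")
    p = result.params
    k_fit = 10.0 ** p["log_k"].value
    yhat = hill_logistic(x, p["bottom"].value, p["top"].value, k_fit, p["n"].value)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    stderr = {}
    for name in ("bottom", "top", "n"):
        stderr[name] = p[name].stderr
    if p["log_k"].stderr is not None:
        stderr["k"] = k_fit * np.log(10) * p["log_k"].stderr
    else:
        stderr["k"] = None

    flagged, reason = False, ""
    if not result.success:
        flagged, reason = True, "optimizer did not converge"
    elif not (x[pos].min() / 100.0 <= k_fit <= x.max() * 100.0):
        flagged, reason = True, "midpoint far outside the sampled concentration range"

    return HillFit(
        bottom=float(p["bottom"].value),
        top=float(p["top"].value),
        k=float(k_fit),
        n=float(p["n"].value),
        stderr=stderr,
        r_squared=r2,
        constraints=constraints,
        flagged=flagged,
        flag_reason=reason,
    )


def fit_assembly_affinities(table: pd.DataFrame, fix_n: Optional[float] = None) -> dict:
    """Extract the interface dissociation constants from a protein-dilution
    fractions table.

    Expects the per-condition schema produced by
    :func:`oligomp.histogram.fractions_table` (``c_tot_molar``,
    ``count_f_*`` and ``conc_f_*`` columns, percent; replicate rows for
    the same condition are averaged, their scatter becoming the fit
    weights).  Returns ``{"kd_mm": HillFit, "kd_dd": HillFit}`` where the
    monomer conversion share M/(M+D) versus free monomer yields the
    monomer-monomer constant and the tetramer conversion share T/(D+T)
    versus free dimer yields the dimer-dimer constant.  Plateaus are
    pinned at the theoretical 0/100% asymptotes of a conversion share.
    """
    grouped = table.groupby(["c_tot_molar", "s_molar", "b_molar"], as_index=False)
    mean = grouped.mean(numeric_only=True)
    std = grouped.std(numeric_only=True) if grouped.size()["size"].max() > 1 else None

    m_free = mean["conc_f_m"] / 100.0 * mean["c_tot_molar"]
    d_free = mean["conc_f_d"] / 100.0 * mean["c_tot_molar"] / 2.0

    def conversion_share(df, num, den):
        return 100.0 * df[num] / (df[num] + df[den])

    y_mm = conversion_share(mean, "count_f_m", "count_f_d")
    y_dd = conversion_share(mean, "count_f_t", "count_f_d")

    def share_err(num, den):
        if std is None:
            return None
        # first-order propagation of replicate scatter into the share
        n, d = mean[num], mean[den]
        sn, sd = std[num].fillna(0), std[den].fillna(0)
        tot = n + d
        return 100.0 * np.sqrt((d * sn) ** 2 + (n * sd) ** 2) / tot**2

    series_mm = TitrationSeries(
        x=m_free.to_numpy(), y=y_mm.to_numpy(),
        y_err=None if std is None else np.maximum(share_err("count_f_m", "count_f_d"), 0.2),
        axis_kind="free_monomer",
    )
    series_dd = TitrationSeries(
        x=d_free.to_numpy(), y=y_dd.to_numpy(),
        y_err=None if std is None else np.maximum(share_err("count_f_t", "count_f_d"), 0.2),
        axis_kind="free_dimer",
    )
    fit_mm = fit_hill(series_mm, fix_n=fix_n, bottom=100.0, top=0.0, plateau_halfwidth=5.0)
    fit_dd = fit_hill(series_dd, fix_n=fix_n, bottom=0.0, top=100.0, plateau_halfwidth=5.0)
    return {"kd_mm": fit_mm, "kd_dd": fit_dd}
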