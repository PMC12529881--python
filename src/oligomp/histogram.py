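"""Mass histograms, Gaussian peak fitting and oligomer-fraction quantification.

Event lists are reduced to per-species counts by fitting a three-component
Gaussian mixture (monomer/dimer/tetramer, initialized at 1x/2x/4x the
monomer mass) plus an optional uniform background component, species
counts being the posterior responsibility sums.  Degenerate inputs
(zero-width peaks, non-convergence) fall back to deterministic
fixed-window counting.  Fractions are reported in two conventions:

* count fractions — share of detected landing events per species (the
  "frequency distribution" view of a mass-photometry histogram);
* concentration fractions — monomer-equivalent protein fractions,
  weighting dimers x2 and tetramers x4 (the "fraction of total protein"
  view used for binding curves).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic import EventList

__all__ = [
    "MassHistogram",
    "PeakFit",
    "OligomerFractions",
    "build_histogram",
    "fit_peaks",
    "fractions_from_counts",
    "mass_accuracy",
    "calibrate",
    "CalibrationResult",
    "fractions_table",
]


@dataclass(frozen=True)
class MassHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PeakFit:
    """Per-species Gaussian peak parameters and event counts."""

    means: np.ndarray  # kDa, one per species, increasing
    sigmas: np.ndarray
    counts: np.ndarray  # posterior-assigned event counts per species
    background_count: int
    converged: bool
    method: str  # "em" or "window"

    @property
    def n_assigned(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class OligomerFractions:
    """Monomer/dimer/tetramer fractions in both reporting conventions."""

    count_fractions: tuple[float, float, float]
    conc_fractions: tuple[float, float, float]
    n_assigned: int


def build_histogram(events: EventList, bin_width: float = 4.0) -> MassHistogram:
    """Bin an event list into a mass histogram with fixed-width bins."""
    if events.n_events == 0:
        raise ValueError("cannot histogram an empty event list")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(events.masses.min() / bin_width) * bin_width
    hi = np.ceil(events.masses.max() / bin_width) * bin_width
    if hi == lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(events.masses, bins=edges)
    return MassHistogram(bin_edges=edges, counts=counts)


def _window_counts(
    masses: np.ndarray, init_masses: np.ndarray, init_sigmas: np.ndarray, window_sigmas: float
) -> tuple[np.ndarray, int]:
    """Fixed-window species counting (fallback path).

    Windows are mean +/- window_sigmas * sigma_init; an event inside
    several windows goes to the lower-mass species (deterministic
    tie-break), events outside every window count as background.
    """
    lo = init_masses - window_sigmas * init_sigmas
    hi = init_masses + window_sigmas * init_sigmas
    counts = np.zeros(len(init_masses), dtype=int)
    assigned = np.zeros(len(masses), dtype=bool)
    for k in range(len(init_masses)):
        in_win = (~assigned) & (masses >= lo[k]) & (masses <= hi[k])
        counts[k] = int(in_win.sum())
        assigned |= in_win
    return counts, int((~assigned).sum())


def fit_peaks(
    events: EventList,
    init_masses: Optional[Sequence[float]] = None,
    window_sigmas: float = 2.5,
    init_cv: float = 0.08,
    background: bool = True,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> PeakFit:
    """Fit monomer/dimer/tetramer Gaussian peaks to an event list.

    Maximum-likelihood Gaussian mixture (EM), one component per species
    initialized at ``init_masses`` (default 1x/2x/4x monomer mass) with
    width ``init_cv`` x mass, plus a uniform background component over
    the observed mass range when ``background`` is True.  Species counts
    are posterior-weighted (responsibility sums), so overlapping
    background events contribute fractionally rather than being claimed
    outright by the widest peak.  If the fit degenerates or fails to
    converge the result is flagged and fixed-window counting is used
    instead.
    """
    if events.n_events < 100:
        raise ValueError("need at least 100 events for peak fitting")
    x = np.asarray(events.masses, dtype=float)
    if init_masses is None:
        init_masses = events.monomer_mass * np.array([1.0, 2.0, 4.0])
    init_masses = np.asarray(init_masses, dtype=float)
    init_sigmas = init_cv * init_masses
    k = len(init_masses)

    means = init_masses.copy()
    sigmas = init_sigmas.copy()
    weights = np.full(k, (1.0 - 0.02 * background) / k)
    bg_weight = 0.02 if background else 0.0
    span = max(x.max() - x.min(), 1e-9)
    bg_density = 1.0 / span

    ok = True
    ll_old = -np.inf
    for _ in range(max_iter):
        # E step: responsibilities for k Gaussians (+ background)
        z = (x[:, None] - means[None, :]) / sigmas[None, :]
        log_pdf = -0.5 * z**2 - np.log(sigmas[None, :] * np.sqrt(2 * np.pi))
        dens = weights[None, :] * np.exp(log_pdf)
        if background:
            dens = np.concatenate([dens, np.full((len(x), 1), bg_weight * bg_density)], axis=1)
        total = dens.sum(axis=1)
        if not np.all(np.isfinite(total)) or np.any(total <= 0):
            ok = False
            break
        resp = dens / total[:, None]
        ll = float(np.log(total).sum())
        # M step
        nk = resp[:, :k].sum(axis=0)
        if np.any(nk < 1e-8):
            nk = np.maximum(nk, 1e-8)
        means_new = (resp[:, :k] * x[:, None]).sum(axis=0) / nk
        var = (resp[:, :k] * (x[:, None] - means_new[None, :]) ** 2).sum(axis=0) / nk
        sigmas_new = np.sqrt(var)
        if np.any(sigmas_new < 1e-3) or not np.all(np.isfinite(sigmas_new)):
            ok = False
            break
        means, sigmas = means_new, sigmas_new
        weights = nk / len(x)
        if background:
            bg_weight = resp[:, k].sum() / len(x)
        if np.any(np.diff(means) <= 0):  # species order lost: peaks collapsed
            ok = False
            break
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            break
        ll_old = ll
    else:
        ok = False

    if not ok:
        counts, bg_count = _window_counts(x, init_masses, init_sigmas, window_sigmas)
        return PeakFit(
            means=init_masses.copy(),
            sigmas=init_sigmas.copy(),
            counts=counts,
            background_count=bg_count,
            converged=False,
            method="window",
        )

    counts = resp[:, :k].sum(axis=0)
    bg_count = int(round(resp[:, k].sum())) if background else 0
    return PeakFit(
        means=means,
        sigmas=sigmas,
        counts=counts,
        background_count=bg_count,
        converged=True,
        method="em",
    )


def fractions_from_counts(counts: Sequence[float]) -> OligomerFractions:
    """Convert per-species event counts to both fraction conventions.

    Count fractions are c_k / sum(c); concentration (monomer-equivalent)
    fractions weight dimers x2 and tetramers x4.
    """
    c = np.asarray(counts, dtype=float)
    if len(c) != 3 or np.any(c < 0):
        raise ValueError("counts must be three non-negative values (M, D, T)")
    if c.sum() == 0:
        raise ValueError("all species counts are zero")
    count_f = c / c.sum()
    w = c * np.array([1.0, 2.0, 4.0])
    conc_f = w / w.sum()
    return OligomerFractions(
        count_fractions=tuple(count_f),
        conc_fractions=tuple(conc_f),
        n_assigned=int(round(c.sum())),
    )


def mass_accuracy(observed_mass: float, expected_mass: float) -> float:
    """Percent agreement between observed and expected mass (min/max ratio)."""
    if observed_mass <= 0 or expected_mass <= 0:
        raise ValueError("masses must be positive")
    lo, hi = sorted((observed_mass, expected_mass))
    return 100.0 * lo / hi


@dataclass(frozen=True)
class CalibrationResult:
    """Linear raw-signal -> kDa calibration map."""

    slope: float
    intercept: float

    def apply(self, raw):
        return self.slope * np.asarray(raw, dtype=float) + self.intercept


def calibrate(standard_events: EventList, known_masses: Sequence[float]) -> CalibrationResult:
    """Least-squares linear calibration against a multi-species standard.

    Peak positions are located by 1D k-means on the raw values (centers
    initialized at evenly spaced quantiles, deterministic) and regressed
    against the known masses.  Requires at least two resolvable peaks.
    """
    known = np.sort(np.asarray(known_masses, dtype=float))
    if len(known) < 2:
        raise ValueError("need at least 2 known masses")
    x = np.sort(np.asarray(standard_events.masses, dtype=float))
    k = len(known)
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    for _ in range(100):
        labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array([x[labels == j].mean() if np.any(labels == j) else centers[j] for j in range(k)])
        if np.allclose(new, centers, rtol=0, atol=1e-12):
            break
        centers = new
    order = np.argsort(centers)
    centers = centers[order]
    within = np.array(
        [x[labels == j].std() if np.sum(labels == j) > 1 else 0.0 for j in order]
    )
    # adjacent clusters count as one peak unless separated well beyond
    # their own widths
    gaps = np.diff(centers)
    sep = gaps > 2.0 * (within[:-1] + within[1:]) + 1e-12
    if np.sum(sep) + 1 < 2:
        raise ValueError("fewer than 2 resolvable peaks in the calibration standard")
    slope, intercept = np.polyfit(centers, known, 1)
    return CalibrationResult(slope=float(slope), intercept=float(intercept))


def fractions_table(
    event_lists: Sequence[EventList],
    monomer_mass: Optional[float] = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Quantify a list of acquisitions into a per-condition fractions table.

    One row per event list with the condition columns, both fraction
    conventions (percent) and the number of species-assigned events.
    """
    rows = []
    for ev in event_lists:
        mm = monomer_mass if monomer_mass is not None else ev.monomer_mass
        pf = fit_peaks(ev, init_masses=mm * np.array([1.0, 2.0, 4.0]), **fit_kwargs)
        fr = fractions_from_counts(pf.counts)
        rows.append(
            {
                "c_tot_molar": ev.condition.c_tot,
                "s_molar": ev.condition.s,
                "b_molar": ev.condition.b,
                "inhibitor_id": ev.condition.inhibitor_id or "",
                "count_f_m": fr.count_fractions[0] * 100,
                "count_f_d": fr.count_fractions[1] * 100,
                "count_f_t": fr.count_fractions[2] * 100,
                "conc_f_m": fr.conc_fractions[0] * 100,
                "conc_f_d": fr.conc_fractions[1] * 100,
                "conc_f_t": fr.conc_fractions[2] * 100,
                "n_assigned": fr.n_assigned,
                "peak_fit_converged": pf.converged,
            }
        )
    return pd.DataFrame(rows)
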