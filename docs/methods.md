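# Methods

## The system and the model

GNE (UDP-GlcNAc 2-epimerase) self-associates stepwise: two monomers (M)
form a dimer (D), two dimers a tetramer (T), and only the tetramer is
catalytically active.  `oligomp` models this with two mass-action
dissociation constants,

    K1 = [M]^2 / [D],        K2 = [D]^2 / [T],

and a monomer-equivalent conservation equation

    M + 2 M^2/K1 + 4 M^4/(K1^2 K2) = C_tot.

The left side is strictly increasing in M, so the free-monomer root is
unique and is found by plain bisection on [0, C_tot], iterated to
adjacent floating-point values (at most 200 iterations; conservation
residual is at machine precision, well below the 1e-9 relative tolerance
asserted in the tests).  No starting value or seed is involved.

### Ligand linkage

Substrate (UDP-GlcNAc) binding stabilizes the tetramer; orthosteric
inhibitors displace substrate and revert that stabilization, the more
potent compounds additionally loosening the monomer-monomer interface.
Because no mechanistic linkage scheme is established for this system,
the package uses the simplest monotone construction that reproduces the
measured endpoint constants:

* substrate occupancy from an allosteric ternary-complex expression with
  a Hill exponent,

      theta = x / (1 + x + b + alpha*x*b),   x = (S/K_S)^n_link,  b = B/K_B,

* log-linear interpolation of both interface constants between their apo
  (superscript 0) and substrate-saturated (superscript S) values,
  weighted by theta;

* inhibitor occupancy phi_B = (b + alpha*x*b)/(1 + x + b + alpha*x*b)
  scales log K1 by log(gamma_d), so that a compound with gamma_d > 1
  weakens dimers once it occupies the substrate pocket.  gamma_d = 1
  describes a pure tetramer destabilizer (C5-like); C13/C15 profiles use
  gamma_d = 50, i.e. a 50-fold loss of monomer-monomer affinity at full
  occupancy — a deliberately strong setting chosen once to reproduce the
  qualitative sequential tetramer-then-dimer disruption.

An important unit convention: the constants measured "with substrate"
(K_D^S) refer to the standard assay concentration of 100 uM UDP-GlcNAc,
which is the plateau of the tetramer response but only ~80% occupancy
under the Hill linkage (K_S = 34.6 uM, n_link = 1.3).
`EquilibriumParams.from_reference_substrate` therefore back-computes the
saturated constants such that the *effective* constants at 100 uM equal
the measured 37.2 nM (M:M) and 98.1 nM (D:D) exactly.

### Reference parameter set

`oligomp.reference` holds the measured constants used as generator
ground truth: K_D^0(M:M) = 12.6 nM, K_D^0(D:D) = 9.6 uM, K_D^S(M:M) =
37.2 nM, K_D^S(D:D) = 98.1 nM, K_S = 34.6 uM, Hill n = 1.3, monomer mass
46.4 kDa, and the inhibitor potency table (IC50, Ki) for C5/C13/C15.
Inhibitor binding constants K_B are calibrated once, deterministically
(bisection on log K_B), so that the noise-free model curve — fitted with
the same convention as the data analysis (n fixed at 1.3, endpoint
plateau constraints) — reproduces each measured IC50.  This makes the
printed IC50s the operational ground truth of the inhibitor designs.

## Synthetic mass-photometry data

Mass photometry counts individual landing particles, so species are
drawn multinomially with probabilities proportional to the *particle*
concentrations (M, D, T) — not mass-weighted.  Event masses are Gaussian
around 1x/2x/4x the monomer mass with sigma = peak_cv * mass
(default peak_cv = 0.08, giving a ~3.7 kDa monomer peak width,
consistent with the few-kDa between-measurement scatter of the
instrument class); a background_rate fraction (default 2%) of events is
uniform over 40-300 kDa; events below the 40 kDa detection floor are
redrawn.  The distribution reflects the equilibrium at the incubation
concentration: assembly is kinetically trapped on the measurement
timescale after the final dilution, so no re-equilibration is applied.
Mass-dependent detection efficiency is not modeled.

Titration designs mirror the study layout: protein serial dilution
50 nM-50 uM (11 steps); protein dilution 0.2-10 uM at 100 uM substrate;
substrate titration 7.81-500 uM at 800 nM protein; inhibitor two-fold
series 7.81-500 uM (plus control) at 800 nM protein + 100 uM substrate;
and a Schild grid crossing 14 substrate levels (97.7 nM-800 uM) with
inhibitor levels 2 nM-200 uM.  8000 events per acquisition and three
replicates per condition are the default problem size throughout (the
study scale); the per-condition RNG streams are spawned deterministically
from one seed.

What the generator does *not* emulate: interferometric contrast physics,
focus drift, mass-calibration error, binding cooperativity beyond the
Hill-shaped linkage, and non-specific aggregation.  Passing recovery
tests therefore demonstrates that the analysis chain is consistent and
unbiased under the stated statistical model, not that it is robust to
every artifact of real recordings.

## Histogram analysis

Events are reduced to species counts by a three-component Gaussian
mixture (EM, initialized at 1x/2x/4x monomer mass, per-species free
sigma) plus a uniform background component.  Species counts are
posterior responsibility sums; hard assignment would systematically
credit background events near the broad tetramer peak to the tetramer,
which measurably biases downstream affinity fits.  Degenerate inputs
(zero-width peaks, non-convergence, collapsed component order) fall back
to deterministic fixed-window counting (mean +/- 2.5 sigma_init, ties to
the lower-mass species).

Fractions are always reported in both conventions: count fractions
(share of landing events, the histogram "frequency distribution" view)
and concentration fractions (monomer-equivalent protein fractions with
1/2/4 weighting, the "fraction of total protein" view used for binding
curves).

Calibration against a glycinin-like standard (160/320/480/640 kDa)
locates peaks by deterministic 1D k-means (quantile initialization) and
maps raw positions to known masses by linear least squares.

## Curve fitting conventions

All titration curves use the four-parameter Hill-logistic model
y = bottom + (top-bottom) x^n / (K^n + x^n), fitted by weighted least
squares (lmfit, K parameterized on a log scale; weights 1/sigma^2 when
replicate scatter is available, with a 0.2 percentage-point floor so a
lucky zero-variance triplet cannot dominate).  Plateau constraints are
box bounds of +/- 5 percentage points around a supplied asymptote.
Fits are flagged — never silently dropped — when the optimizer fails,
when the midpoint lands more than a factor 100 outside the sampled
range, or when the series shows no transition (< 1 percentage point of
span).

Interface affinities are extracted from stepwise *conversion shares*:
monomer share M/(M+D) versus free monomer, and tetramer share T/(D+T)
versus free dimer.  Under pure mass action both are exact rectangular
hyperbolas whose midpoints equal K1 and K2, so the fitted midpoint is a
consistent estimator of the generating constant; plotting fractions of
total protein instead makes the midpoint depend on the plateau
convention (e.g. the total-fraction monomer curve with free plateaus has
its midpoint at K1/2).  The Hill exponent is left free in these fits,
as in the binding-plot convention of the study.

The substrate-titration K_S fit also leaves n free: the Hill exponent is
*determined* by that curve and only fixed (at 1.3) for the subsequent
inhibition and Schild fits.  This matters numerically because the
equilibrium model's tetramer response is somewhat steeper (effective
n ~ 1.7) than the occupancy linkage that drives it; forcing n = 1.3
shifts the fitted midpoint ~+17% while the free-n midpoint sits within
~5% of K_S.

## Pharmacology

IC50-to-Ki conversion exposes three explicit Cheng-Prusoff modes —
classical (1 + S/K_S), Hill ((1 + S/K_S)^n) and empirical-lambda
(IC50/lambda) — because the appropriate correction for assembly
inhibition with cooperative substrate linkage is not a settled closed
form.  `calibrate_lambda` back-derives lambda as the geometric mean of
reference IC50/Ki ratios and flags inconsistency above 10%; on the
reference inhibitor table the three ratios agree within 2% and give
lambda ~ 37.9, which is the pipeline default.  For comparison, the
classical factor at the assay condition is 3.89 and the Hill factor
5.85 — neither reproduces the reference Ki values, which is why the
empirical mode exists and is explicit.

Schild analysis regresses log10(CR-1) on log10([B]); the linear region
is either supplied or auto-selected as all points with CR-1 > 0.2 (a
deterministic stand-in for the empirical no-effect/linear split).  The
ATCM alternative fits CR = (1+B/K_B)/(1+alpha B/K_B) on log CR with
alpha constrained to (0,1) via a logistic transform (an antagonist's
concentration ratio requires alpha < 1); flat CR data (the alpha = 1
null case) are flagged unidentifiable.

The OMAM global fit shares one parameter set (K_B, tau_S, tau_I, alpha,
beta, n; E_max and K_S fixed from the control analysis) across all
substrate-response curves.  It uses bounded trust-region least squares
with 12 log-uniform multi-starts from a fixed seed (default 12345) and
best-SSE selection; K_B, tau_S and tau_I are fitted on a log scale,
alpha and beta on [0, 100], n on [0.3, 4].  With only a control curve
the inhibitor parameters are reported but flagged unidentifiable.

Note an internal tension in the reference parameter set itself: the
printed OMAM parameters imply an operational EC50 of roughly
K_S/(tau_S - 1) ~ 2 uM at B = 0, whereas the substrate titration
plateaus near 100 uM; and the OMAM K_B (25.2 nM) and the Schild
K_B,app (0.7 uM) differ ~28-fold.  The package treats Schild and OMAM
as independent analyses and does not force consistency.

## Problem sizes and numerical choices

Default analyses use 8000 events per acquisition, three replicates per
condition and the concentration grids above; the full default pipeline
(four designs, three inhibitors, optional Schild grid) runs in a few
minutes on one core.  Tests and the acceptance checks use the same
scale for recovery claims and smaller event counts (200-500) for smoke
and interface tests.  Random draws all flow from
`numpy.random.default_rng` seeded per (design, inhibitor, replicate) via
a hash of the run seed, so every output is bit-reproducible and
independent acquisitions stay statistically independent.

## Known limitations

* The linkage scheme (Hill-shaped occupancy, log-linear interpolation,
  gamma_d) is phenomenological; it reproduces endpoint constants and the
  qualitative inhibition sequence, not any specific structural mechanism.
* Recovery tolerances (15-20%) reflect the study-scale design, where the
  monomer-monomer midpoint lies at the edge of the dilution grid; they
  are statements about this design, not fundamental limits.
* The Gaussian mixture assumes unimodal, well-separated peaks; heavily
  overlapping species or non-Gaussian tails would require a different
  peak model.
* Concentrations are treated as exact; pipetting error is not modeled.
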