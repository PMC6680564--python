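# Methods

## System and model

The sensor is a three-fluorophore energy cascade: a cationic polyfluorene
conjugated polymer (CP) electrostatically complexed with a guanine-rich
15-mer aptamer labeled with 6-FAM (5′) and TAMRA (3′).  Without K⁺ only
one-step FRET (CP→6-FAM, CP→TAMRA) competes with photo-induced charge
transfer (PCT) quenching; K⁺-driven G-quadruplex folding shortens the
6-FAM–TAMRA separation and opens the two-step CP→6-FAM→TAMRA channel.  The
package treats each fluorophore as a kinetic state with intrinsic decay
rate 1/τ_int = k_rad + k_nonrad, an extra non-radiative loss 1/τ*_nr
(quenching/PCT), and distance-dependent transfer rates: Förster
k_FRET = τ_D⁻¹(R₀/R)⁶ and PCT k = k₀e^{−βR}.  Intrinsic photophysics are
assumed unchanged by complexation (only rates are added, never modified),
transfer runs only downhill in energy, and the dipole orientation factor
is the dynamic-isotropic-average value κ² = 2/3.

## Spectral calculus

The overlap integral J = ∫f_D(λ)ε_A(λ)λ⁴dλ uses an *area-normalized*
donor emission density f_D (the display convention of peak-normalized
spectra is also provided, but only area normalization makes R₀
dimensionally meaningful).  J is carried in M⁻¹·cm⁻¹·nm⁴ with the matching
Förster prefactor R₀ = 0.2108·[κ²n⁻⁴Q_D J]^{1/6} Å — the Å/nm⁴ form of
R₀⁶ = 9000 ln10 κ² Q_D J / (128 π⁵ N_A n⁴).  Spectra are resampled by
linear interpolation onto the union grid restricted to the common
wavelength range, zero outside their support; the integral is trapezoid.
Defaults: n = 1.33 (aqueous buffer), κ² = 2/3, both configurable.

Published overlap magnitudes for this system are quoted in a unit whose
absolute scale cannot be reconciled with the accompanying Förster
distances under any standard convention, so the package validates only the
dimension-free *ratio* of the two CP-donor overlaps through the
sixth-root law R₀(J₁)/R₀(J₂) = (J₁/J₂)^{1/6}; absolute recomputation of
the 6-FAM/TAMRA R₀ is additionally blocked by the unpublished 6-FAM
quantum yield and is not attempted.

## TCSPC forward model and fitting

Photon histograms are modeled as the multi-exponential impulse response
convolved with the instrument response function (IRF) and wrapped modulo
the 12.5 ns repetition window (80 MHz).  The implementation is exact for a
piecewise-constant IRF: within each bin the convolution obeys a
first-order recursion (evaluated with `scipy.signal.lfilter`), previous
excitation cycles are summed analytically as a geometric series, and bin
contents are exact time-integrals of the modeled intensity — so the only
approximation anywhere is the piecewise-constant representation of the
IRF itself, which vanishes as O(Δt²).  Against the continuous
exponentially-modified-Gaussian closed form the model agrees to 1e-6
relative on a fine grid.

Defaults follow typical TCSPC hardware: 4096 bins over 12.5 ns (≈3 ps/bin),
Gaussian IRF of FWHM 0.19 ns centered at 0.8 ns (a measured IRF histogram
is equally accepted).  Fitting maximizes the Poisson likelihood via least
squares on deviance residuals written in the cancellation-free form
2c[x − ln(1+x)], x=(m−c)/c (Neyman-weighted least squares, variance
max(c,1), is available; the two agree on lifetimes within 2% once per-bin
counts support the Gaussian approximation, and Neyman weighting is known
to bias low-count bins).  Reconvolution over the full window is the
default; tail fitting past the pulse is provided.  The fit window starts
at the first bin reaching 1% of the smoothed peak; the baseline starts
from pre-pulse bins and stays free; an IRF time-shift nuisance parameter
is bounded to ±0.05 ns.  Lifetime pairs are multi-started from five
deterministic log-spaced values; amplitudes are reported as
pre-exponential fractions normalized to Σaᵢ = 1 (the intensity scale is a
separate parameter), components sorted fast-first.

Model order (1 vs 2 components) follows a conjunctive rule: two components
are accepted only when the single-exponential fit is rejected *both* by a
reduced-χ² improvement > 0.05 *and* by a Wald–Wolfowitz runs test on its
residual signs at α = 0.05, with ties toward fewer components.  The runs
test alone is anti-conservative in low-count tails (sign frequencies are
asymmetric when bin means fall below ~1 count), which is one reason the
rule is conjunctive.  A second component whose pre-exponential weight,
intensity fraction, or lifetime collapses (lifetime pinned at the lower
bound) is flagged degenerate, as is any fit that parks the bulk of the
counts in the flat baseline.

## Population kinetics and rate curves

The cascade is a linear ODE system, so it is propagated *exactly* on a
uniform grid by the matrix exponential of an augmented matrix whose extra
rows accumulate radiated, non-radiatively lost, and per-edge transferred
quanta; a Gaussian excitation pulse enters as piecewise-constant
generation, integrated exactly within each step.  Quantum bookkeeping
(radiated + lost + still-excited = generated) therefore closes to machine
precision and is asserted at 1e-6.  The default pulse is a delta at t=0:
the 70 fs excitation is orders of magnitude shorter than a bin.

The time-dependent decay rate k(t) = [g − dN/dt]/N is extracted with a
Savitzky–Golay quadratic smoother (default 21-bin window) because raw
finite differences are unusable under Poisson noise; evaluation is
restricted to bins where the smoothed population exceeds 1% of its peak,
since the formula divides by N.  Scenario changes are reported as
Δk(t) = k_initial(t) − k_final(t) with the free state as "initial".

## Efficiency statistics

Three read-outs, all dimensionless fractions internally (percent only at
reporting): φ = 1 − τ_DA/τ_D from fitted lifetimes; the pointwise
E(t) = [I_D − I_DA]/I_D from donor traces, where negative values are
first-class results (they signal population gain of the intermediate dye
by upstream compensation) and are never clipped; and the acceptor gain
η(t) = [I_with − I_w/o]/I_w/o.  η is written as a ratio of integrals, but
the sensor's worked read-out plugs in instantaneous intensities at 2 ns,
so pointwise mode is the default and cumulative mode (trapezoid from 0 to
t) is provided alongside.  Both are invariant under common rescaling of
the two curves, and cumulative η at t→∞ reduces to the ratio of total
radiated acceptor quanta minus one, which the kinetics bookkeeping
reproduces to 1e-3.

## Synthetic data: what it emulates, and what not

No measured spectra or photon records are available, so the generator
produces statistically faithful stand-ins.

*Spectra* are Gaussian vibronic progressions pinned to the published peak
wavelengths and extinction maxima (CP absorption 397.8 nm at 0.52×10⁴
M⁻¹cm⁻¹, emission 426.6/451.0 nm, Q = 0.58; 6-FAM 490.4 nm at 1.25×10⁴,
emission 514.4 nm; TAMRA 567.6 nm at 1.96×10⁴, emission 590.2 nm).  Band
widths and progression amplitudes are not published; they were fixed once
so that the two resolved CP emission peaks survive (σ = 9 nm for the 0-0
and 0-1 bands, broader low-energy shoulders at 483/520 nm) and the
overlap ratio J(CP/6-FAM)/J(CP/TAMRA) ≈ 3.14 falls within 20% of the
published 3.09 — a calibration, recorded in the fixture manifest, not a
prediction.  Dye quantum yields that are unpublished use typical values
(0.90 fluorescein, 0.55 rhodamine) and affect no validated number.

*Scenarios* map assay states to distances: with K⁺, R(CP–6-FAM)=37.3 Å,
R(CP–TAMRA)=37.1 Å, R(6-FAM–TAMRA)=30.7 Å; without K⁺ the unfolded
aptamer keeps the dyes further out (60.2/57.3/32.3 Å); free fluorophores
have no transfer.  These distances were solved once, through the preset
spectra's Förster distances (36.9/30.5/46.7 Å), so the resulting total
decay rates reproduce the published fitted fast lifetimes (CP: 0.19 ns
with K⁺, 0.35 ns without; 6-FAM: 0.25/0.36 ns) — again calibration, not
prediction.  PCT defaults k₀ = 2000 ns⁻¹, β = 0.3 Å⁻¹ keep the channel a
minor loss at these separations; an explicit 6-FAM quench rate (0.40 ns⁻¹
with K⁺, 0.05 without) carries the concomitant quenching of the
intermediate dye.

*Histograms* draw independent Poisson counts per bin around the wrapped
reconvolution curve, plus a flat dark-count background of 1e-4 of the
signal peak per bin; a fixed seed makes traces bit-identical.  Cascade
states are converted to exact exponential mixtures by eigendecomposition
of the (triangular) rate matrix, so acceptor rise terms carry negative
amplitudes exactly.

The demonstration TAMRA curves for the gain read-out are *calibrated*:
a single-exponential 0.87 ns decay without K⁺, and with K⁺ a 0.90 ns
decay plus a 0.4 ns feeding transient, scaled so the pointwise
intensities at 2 ns are 100 and 330 (hence η(2 ns) = 230% exactly) and
the initial enhancement is 4-fold (hence η(0) = 300%).  They demonstrate
the efficiency calculus on curves with the published geometry; they do
not predict those numbers from the kinetics.

What the generator deliberately omits — and what passing tests therefore
do not establish about real data: photon-by-photon records with detector
dead time and pile-up, wavelength-dependent detection efficiency, IRF
afterpulsing and color shift, scattering/photobleaching drift, exciton
diffusion along the CP backbone, and static donor–acceptor distance
distributions (a single effective distance per pair is used).

## Problem sizes and determinism

Simulation-and-refit checks run at 1e6 total counts in 4096 bins, the
regime where all published Table parameter sets are recovered within a
few percent (tolerances: 10% per lifetime, 15% for components at or below
the IRF width).  Closed-form convolution oracles use a 2¹⁹-bin grid so
the only remaining discrepancy, the O(Δt²) piecewise-constant-IRF term,
sits below 1e-6.  Model-order studies use 8 seeded replicates per case.
Every stochastic step takes an explicit integer seed; multi-start fitting
is fully deterministic.

## Known limitations

* Two exponential components at most; no stretched-exponential or
  lifetime-distribution models, and no global multi-trace analysis.
* The grid-refinement invariance of J is held to 1e-4 in the canonical
  dye-width regime (σ ≳ 15 nm on a 0.5 nm grid); very narrow or
  tail-dominated band overlaps degrade toward 1e-3.
* Published initial decay rates of the CP (3.58/2.58/2.29 ns⁻¹) are not
  exactly recoverable from the published fitted amplitude/lifetime pairs
  under any amplitude convention; the package asserts only their ordering
  (with K⁺ > complexation > free).
* The per-pathway decomposition of the total efficiency into FRET vs PCT
  contributions is not identifiable from intensity data alone; the
  kinetics module's forward bookkeeping is the only place it exists.
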