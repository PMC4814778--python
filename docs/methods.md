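# Methods

This note documents the models behind `fusiontrap`, the choices made where
the design was genuinely open, and what the synthetic-data tests do and do
not demonstrate about real instrument data.

## Physical model of the assay

A silica bead of radius R = 0.485 µm, coated with a fluid lipid bilayer,
sits in a weak 3-D harmonic optical trap above a bilayer-coated coverslip.
Its position is recorded at 100 kHz with nanometre precision; the dominant
localisation error is the nanopositioning stage (SD 1 nm axial, 1.5 nm
lateral).  Membrane tension — set in the experiment by the thermal area
mismatch between bilayer and substrate, about 5% per 10 °C
(`area_mismatch`) — controls how readily the bilayers fuse; in the
simulator, tension appears only through the schedule (which intermediates
occur and when).

Each axis of the bead follows an overdamped Langevin equation

    dx = −(k_total/γ_total)(x − x_c) dt + sqrt(2 k_B T dt / γ_total) ξ

with state-dependent totals:

| state | stiffness | drag | wall |
| --- | --- | --- | --- |
| free | trap only | bulk Stokes 6πηR | far away |
| surface | trap | ×3 near-wall factor | reflection at z = 0 |
| transient/hemifusion | trap + stiff axial tether | near-wall + membrane drag γ_m | tether rest height 30 nm |
| fused | very stiff on all axes | near-wall + ~10⁻⁶ N s/m | — |

Hydrodynamic memory, inertia, a non-harmonic optical force field and
lipid-scale detail are out of scope.  The near-wall hindrance is the
lumped factor 3 ("diffusion at the surface is about a third of bulk"), not
a gap-dependent correction: the analysis itself only ever uses the lumped
factor, so the generator matches the analysis assumption.

### Numerical integration

Euler–Maruyama with substeps: the recorded 10 µs interval is divided into
n substeps such that k·dt/γ ≤ 0.1 for every segment and axis (i.e. dt at
most a tenth of the fastest relaxation time).  The stiff fused state
(relaxation time ~20 µs) would be unstable at the raw sampling step;
`SimulationConfig.stabilized(schedule)` computes the minimum substep
count, and `simulate_bead_trajectory` rejects unstable configurations
outright rather than silently subdividing.  Traces are bit-reproducible
for a fixed seed.

### Wall model

The coverslip is a specular reflector at z = 0, applied to the axial
coordinate throughout any schedule that contains a wall segment (the wall
physically exists during the whole experiment; free segments simply sit
~5σ above it).  Reflecting the trap-centred axial fluctuation at the wall
folds the Gaussian and yields a surface width of `162·sqrt(1 − 2/π) ≈ 98
nm` — the observed free → surface width reduction falls out of the
geometry with no extra parameter.  Tethered states fluctuate about a 30 nm
rest height so their tight axial distribution is not artificially folded;
z is a recorded coordinate, not a bead–wall gap, and no contact mechanics
beyond reflection is modelled.

### State presets

The trap stiffnesses are not independently known for the instrument;
presets derive them from the canonical width progression at the working
temperature: k = k_B T/σ² with σ half the target width (axial 162 nm free,
12 nm hemifused, 4 nm fused; lateral 82/80 nm free, 4 nm fused, stage
noise subtracted in quadrature).  The hemifused membrane drag default is
γ_m = 9.25×10⁻⁸ N s/m, which puts the hemifused lateral diffusion constant
at ≈ 0.034 µm²/s on top of the near-wall drag — the scale of the observed
hemifusion diffusion drop.  The fused state is a very stiff tether plus a
10⁻⁶ N s/m drag; its residual recorded width is dominated by stage noise,
as observed for beads adsorbed to glass.  Default constants are T = 295 K
(22 °C working temperature) and η = 0.89×10⁻³ Pa s (water at ~25 °C; the
detection-latency estimates use T = 298 K with the same η, the convention
under which the printed 3.8 ms / 0.4 ms latencies are reproduced exactly).

## Width estimation and state classification

Width ≡ 2 × sample SD (ddof = 1) in sliding windows (default 0.5 s,
advancing by a quarter window).  For a correlated Ornstein–Uhlenbeck trace
the width of a finite window is noisy and biased low: with axial
relaxation time τ ≈ 13 ms a 0.5 s window gives a width SE of ~11% (the
naive i.i.d. formula would suggest <1%).  Two consequences shaped the
classifier:

1. **Axial-first, lateral-on-runs.**  Windows are first categorised by the
   axial width alone (collapse < 25% of the free reference, partial 25–75%,
   free ≥ 75%, fused ≤ 8 nm on all axes, tie-break to fused).  The lateral
   "unchanged" criterion (± 25% of reference) is then evaluated on *runs*
   of windows using the pooled width — within-window variance plus the
   variance of window means (law of total variance).  This matters because
   membrane drag stretches the lateral relaxation time to ~50 ms: a single
   window then systematically under-measures the lateral amplitude, while
   the pooled run statistic stays unbiased.
2. **Certification span.**  A segment is certified only if it outlasts
   both the first-passage latency `t = (3w)²/2D` *and* one estimator
   window plus one advance — overlapping windows share most of their data,
   so a shorter run is indistinguishable from a single width-estimator
   excursion.  Shorter runs are merged into their longer neighbour.

Free reference widths, when not supplied, are the per-axis medians over
the windows whose axial width is within 20% of the trace's 90th
axial-width percentile — in effect the first free segment, robust to the
few windows that straddle a transition (where a drifting mean masquerades
as width).  Hemifusion-like segments shorter than 3 s that release to a
less-confined state are relabelled transient fusion.

With the defaults the classifier recovers the programmed four-state
schedule exactly in ≥ 95 of 100 seeded runs; resolving the 0.5 s
transient-fusion blip of the `transient_only` preset needs a shorter
window (0.125 s), because a blip must span more than one window to be
certified.

## Diffusion estimation

Time-averaged MSD over all overlapping pairs, fitted over lags up to 10
sampling intervals (0.1 ms at 100 kHz) — far below both the ~20 ms MSD
linearity bound and the trap relaxation time, so confinement does not bias
the slope.  Localisation noise enters as a 2σ² intercept, fixed from the
stage-noise metadata when available and fitted otherwise; weights are the
pair counts and D is floored at zero.  The drag decomposition is exact
arithmetic (γ_hf = γ₀ + γ_m by construction); its precision is limited
only by the D estimates feeding it.  Covariance-based and
maximum-likelihood estimators are deliberately out of scope — the pipeline
is defined in terms of the MSD.

## Evans–Sackmann inversion

Parameters default to the DOPC-on-glass values h_m = 4.5 nm, µ_m = 0.11
Pa s (η_m = h_m µ_m = 4.95×10⁻¹⁰ Pa s m), h_g = 0.4 nm, µ_w = 10⁻³ Pa s.
The Bessel ratio K₁/K₀ uses exponentially scaled functions (`kve`), stable
for ε from 10⁻⁶ to beyond 10⁵; the large-ε limit γ → π µ_w r²/h_g is
matched within 5% at ε = 100.  The inversion solves D(r) = D_m by Brent's
method on log r over r ∈ [0.1 nm, 10 µm] (strict monotonicity guarantees
uniqueness; forward ∘ inverse agrees to 10⁻⁶ relative across the range).

**Prefactor caveat.**  With the standard translational-drag prefactor 4π
and the parameters above, a measured D_m of 0.044 µm²/s inverts to ≈ 82 nm
and 0.24 µm²/s to ≈ 23 nm.  Reading the moving inclusion as threading two
membrane monolayers doubles the prefactor (8π) and gives ≈ 51 nm and ≈ 11
nm.  Published analyses of this assay report radii (47 nm, 13 nm) between
these conventions, closer to the 8π reading, and the exact constants they
used are not recoverable; both variants are therefore exposed
(`prefactor_variant`), reported side by side, and no attempt is made to
tune the model onto any particular printed radius.  The geometric chord
estimate `r = sqrt(2Rh − h²)` (≈ 66 nm for a bead submerged by one bilayer
thickness) brackets the hemifusion-diaphragm scale from above.

## Boltzmann inversion

E(bin) = −ln p(bin) in k_B T units, minimum shifted to zero; empty bins
are masked, never imputed, and the landscape is invariant under count
rescaling.  The default bin width is the largest for which the modal bin
holds ≤ 5% of the samples; if the shallowest defined bin then holds fewer
than 5 counts a warning is logged but resolution is kept (coverage of the
deep tail improves with n, resolution does not).  The reported depth
(max − min over defined bins) is a *lower* bound on the true barrier —
unvisited regions are higher — and converges to the well depth from below
as the sample grows; 10⁶ samples from a 10 k_BT truncated quadratic well
recover the depth within 1 k_BT.  Which coordinate to invert is
configurable (axial by default, the axis along which the arrested states
are confined).

## Problem sizes

Simulation-backed tests run at 10 kHz (the statistics of interest — widths
at ≥ 0.1 s windows, diffusion at ≥ 0.1 ms lags — are fully resolved
there), with 100 kHz used where the short-lag MSD itself is under test.
The width-recovery computation in `scripts/acceptance.py` uses a 100 s
trace with 10 s windows: at τ ≈ 13 ms that trace holds ~7600 independent
axial fluctuations, putting the width estimate's own sampling error near
2 nm and the 10 s window's finite-window bias near 0.3%.  The 100-seed
schedule-recovery check uses the full 23.6 s preset at 10 kHz.

## What the synthetic tests do not show

The generator reproduces the *statistical structure* the analysis assumes
(state-dependent OU statistics, additive drags, reflective wall, white
stage noise).  Real traces additionally contain low-frequency drift,
calibration nonlinearity, gap-dependent hydrodynamics, and genuinely
stochastic state lifetimes, none of which are emulated; passing tests
certify the estimators and the inference chain, not instrument-specific
robustness.  The published D_m and contact-radius *histograms* pool ~180
experimental fusion events; with no event ensemble to draw from, the
corresponding checks are invariant-based (monotonicity, round-trip
identity, asymptotics, recovery of known generator parameters) rather than
numeric reproductions.
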