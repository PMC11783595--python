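# Methods

This note documents the models, defaults and numerical choices behind
`barrelfret`, and what the synthetic-data generators do and do not emulate.

## The physical picture

A donor dye (DPH, emitting 430–480 nm, fluorescence lifetime ~16 ns when
channel-bound) and an acceptor (Nile red, emitting near 593 nm, ~4–5 ns) can
occupy the same α-helical-barrel channel. Their separation r sets the
Förster transfer rate k_T = (1/τ_D)(R0/r)⁶. Two conformational
subpopulations coexist: a dominant π-stacked pair a few Å apart that
transfers in ~10 ps (resolvable only by transient absorption, IRF ~280 fs),
and a minority pair several nm apart transferring in ~1 ns (resolvable by
TCSPC as a small sensitized-emission rise). Free-energy profiles over the
inter-dye distance rationalize the two populations as distinct basins. A
separate readout co-confines two anthracenes: if π-stacked, 365 nm
irradiation drives a [4+4] cycloaddition that quenches anthracene emission
exponentially to completion; otherwise only a slow linear photobleach is
seen.

## Synthetic data generators (`barrelfret.synth`)

All generators are pure functions of their inputs and an integer seed
(`NoiseSpec`). They emulate:

- **TCSPC** (`simulate_tcspc`): expected counts = model ⊗ Gaussian IRF,
  scaled to a target peak, plus a constant background; channelwise Poisson
  draws. Defaults: IRF FWHM 0.170 ns, 4096 channels over 0–100 ns, 2×10⁴
  peak counts, background 1% of peak, pulse at t = 2 ns. The channel count,
  window and background are our declarations (chosen so a ~16 ns lifetime is
  well conditioned); instrument papers rarely print them. Windows shorter
  than 5× the longest lifetime are flagged rather than rejected.
- **Transient absorption** (`simulate_ta`): ΔmOD(delay, λ) = Σ populations ×
  species spectra + Gaussian noise relative to the signal maximum. Delay
  grid: linear −1…+1 ps then logarithmic to 7 ns (standard pump–probe
  practice); IRF FWHM 0.28 ps. Stimulated-emission spectra are negative by
  convention; the donor feature is placed far to the blue of the acceptor
  band so that the 575–605 nm integration band is acceptor-dominated, as in
  the real spectra.
- **Binding titrations** (`simulate_titration`): single-site binding with
  ligand depletion (quadratic mass-balance root), F/Fmax = f0 + (1−f0)·bound
  fraction. The hyperbolic approximation is *not* used because ligand
  (0.5 μM) and Kd (low μM) are comparable.
- **Free-energy profiles** (`simulate_fes`): sums of negative Gaussian wells
  on a 1.5–40 Å grid plus a *smooth* random error curve (Gaussian knots
  every 2 Å joined by a cubic spline). Point-wise i.i.d. noise at the
  multi-kJ/mol amplitudes seen in converged metadynamics error bands would
  create spurious prominence-scale minima that real profiles do not show;
  the smooth model emulates the slowly varying bias-estimate error instead.
  The heptamer fixture uses wells at 3.5 Å (93 kJ/mol) and 10.0 Å
  (92 kJ/mol) with a shallow 20–30 Å shelf; the octamer fixture a broad
  94.6 kJ/mol well at 4.1 Å. Well widths are our declarations.
- **Photolysis** (`simulate_photolysis`): promoted = plateau +
  (1−plateau)e^{−kt} (plateau 0.02); inhibited = 1 − s·t clipped at zero;
  16 points over 30 min, 2% Gaussian noise.
- **Screen fixture** (`default_screen_panels`): 15 panels whose mixed
  spectra are (1−E)·donor + E·acceptor with declared transfer fractions —
  ten between 0.20 and 0.85, five at ≤0.02 — and 1% multiplicative noise.

Not emulated: photon-by-photon arrival statistics (pile-up, afterpulsing),
detector wavelength response, TA chirp/coherent artifacts, 2D
excitation–emission maps, and cooperativity in binding. Passing tests
therefore demonstrate estimator correctness under the stated noise models,
not robustness to these instrument artifacts.

## TCSPC reconvolution (`barrelfret.tcspc`)

Each component is convolved analytically:
h(t) = (α/2)·exp(σ²/2τ² − t/τ)·erfc((σ/τ − t/σ)/√2). Where the erfc
argument is nonnegative the product is evaluated through erfcx with the
identity exp-factor → exp(−t²/2σ²), which is overflow-safe for σ ≪ τ; the
plain form is used elsewhere, where its exponent is provably negative.

Fitting minimizes Poisson deviance residuals (correct for counting data; a
Neyman-weighted χ² option is retained for cross-checks) with
`scipy.optimize.least_squares` under bounds. Initialization: lifetimes
log-spaced over [channel width, t_max/2] (five starts, plus a tail-slope
estimate); amplitudes by nonnegative least squares at fixed lifetimes; IRF
position/width from thresholded moments of the IRF histogram (channels below
1% of the IRF peak are zeroed first). The time-zero shift is co-fitted.
Standard errors come from the information matrix (JᵀJ)⁻¹ of the deviance
residuals. Components below 0.1% of the total amplitude are pruned
post-fit; lifetimes pinned at bounds are flagged.

Model selection fits n = 1…N and takes the *smallest* n whose BIC
(deviance + p·ln(channels)) is within 10 of the minimum — a parsimony rule.
The average lifetime is intensity-weighted (Σατ²/Σατ) over
positive-amplitude components.

The acceptor-channel rise fit fixes the decay lifetime (from a
direct-excitation control) and floats the rise constant and the rise:decay
amplitude ratio ρ. The outcome is "no resolvable rise" when ρ < 0.005 or
ρ < 2 standard errors — the no-transfer (hexamer-like) case.

## Transient-absorption target model (`barrelfret.ta`)

State populations of the two-population scheme are closed-form: each
exponential term convolved with the Gaussian instrument function reuses the
exp⊗Gauss kernel, and the acceptor is a sum of two sequential-kinetics
terms fed at the fast and slow branch rates. The removable singularity at
feeding rate = acceptor decay rate is evaluated through the exact analytic
limit (the k-derivative of the convolved exponential), not a perturbation.
Rates are stored in ps⁻¹ (fast) and ns⁻¹ (all others); populations are
validated against a stiff-ODE oracle in the tests.

Band kinetics integrate the ΔmOD map over 575–605 nm (trapezoid), following
the band-integration route rather than single-wavelength slices. The target
fit floats the fast time constant, an overall amplitude, and time zero by
default (multi-start over fast-rate decades); the slow pathway is kept in
the model but fixed, because at the TA noise level its amplitude sits at the
noise floor. fits whose fast time falls below the IRF width are flagged as
unresolved. The fixture default f_fast = 0.95 encodes "dominant fast
population"; the exact fraction is a declaration.

## Steady-state screen (`barrelfret.steady_state`)

E_app is operationalized ratiometrically: unmix the mixed spectrum against
the single-dye references (nonnegative least squares), form the sensitized
acceptor signal (acceptor coefficient minus the direct-excitation fraction,
times the acceptor-only band area) and the residual donor signal, and take
sensitized/(sensitized+donor), clamped to [0,1]. Band areas integrate
±40 nm around 450 nm (donor) and 593 nm (acceptor). This definition is
invariant to uniform rescaling of all three spectra and reduces to the
mixing fraction for unit-area reference shapes. The positive-screen
threshold is 0.1, chosen with margin against the fixture's 0.02-level
negatives. The displacement test compares saturating-region means (top
quartile of the concentration grid) with a 50% drop threshold.

## Free-energy basins (`barrelfret.fes`)

Minima are detected on the inverted profile with a prominence filter
(default 2 kJ/mol) — raw sign changes would be noise-dominated — and basin
boundaries are the separating maxima (watershed), with profile ends as outer
boundaries. Boltzmann weights use R = 8.314 J mol⁻¹ K⁻¹, T = 298 K by
default, with the profile shifted to zero at its global minimum before
exponentiation (overflow guard). Stacking labels: ≤5 Å stacked, ≤12 Å
slipped, else distal — thresholds bracketing the 3.5/10.0 Å basin anchors.

## Photodimerization (`barrelfret.photodimer`)

The promoted model is pseudo-first-order because encapsulation pre-pairs the
two anthracenes (1:2 barrel:guest stoichiometry), making the photoreaction
effectively unimolecular; explicit second-order dimerization kinetics are
deliberately not fitted. Model choice is by AICc (non-nested comparison),
requiring a margin of 2 to accept the exponential; completion additionally
requires the fitted end value below 0.1 of the initial fluorescence.
Classification: promoted = exponential with initial rate >3× the fastest
control; inhibited = linear within 2× the control band (mean + 2 SD of
control slopes); anything else is ambiguous — deliberately so for
octamer-like linear losses modestly above the controls.

## Förster conversions (`barrelfret.forster`)

The wavelength-domain overlap convention (λ⁴, nm) fixes the prefactor at
8.79×10⁻⁵ Å⁶ per M⁻¹cm⁻¹nm⁴ (cross-checked in the tests against the
first-principles CGS constant). κ² defaults to 2/3 (isotropic dynamic
averaging), refractive index to 1.4 (protein interior). Because κ² and R0
are genuinely uncertain in experiments, interval inputs propagate to
distance intervals. In the distance analysis (driver 06) R0 enters as
configuration (5.5 nm): the absolute overlap depends on the real dyes'
environment-sensitive spectra, which the synthetic stand-ins only sketch, so
the fixture-derived R0 is reported separately and not used for the
consistency check.

## Reproduction targets and problem sizes

`barrelfret.report` runs 20 replicate simulate-and-refit experiments per
target (the same count the acceptance criteria specify), with per-target
sub-seeds derived from one base seed via `numpy.random.SeedSequence`. The
full run takes on the order of ten seconds on one CPU; the oracle
equivalence suites use 100 random schemes/profiles.

## Known limitations

- The IRF is modeled as a fitted Gaussian width, not an empirical histogram
  convolution; structured IRFs (afterpulses, reflections) are out of scope.
- Global (linked-parameter) analysis across multiple traces and SVD-based
  wavelength-resolved TA analysis are not implemented; fits are per-trace.
- The rise-amplitude detectability limit means transfer times below ~2× the
  TCSPC IRF width are not recoverable by the rise route — which is exactly
  why the fast pathway is fitted from TA data instead.
- Binding fits assume one effective site per barrel assembly and no
  cooperativity between the two guests.
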