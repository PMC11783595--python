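# barrelfret

Photophysics analyses for small-molecule co-encapsulation in *de novo*
α-helical peptide barrels (αHBs). αHBs are self-assembling coiled-coil
oligomers (5+ helices) whose solvent-accessible central channel can bind
hydrophobic guests. When a FRET donor (1,6-diphenyl-1,3,5-hexatriene, DPH)
and an acceptor (Nile red) occupy the *same* channel, energy transfer
reports on their separation; when two anthracenes are co-confined and
π-stacked, UV irradiation drives a [4+4] photodimerization. This package
implements the quantitative analyses behind those readouts, with a seeded
synthetic-data generator standing in for the instruments:

- **steady-state screening** — spectral unmixing and an apparent FRET
  efficiency `E_app = S_sens / (S_sens + S_don)` from sensitized-acceptor vs
  residual-donor band signals; saturation binding fits with the single-site
  ligand-depletion (quadratic) isotherm; competitive-displacement detection;
- **Förster theory** — overlap integral `J = ∫ F̄_D(λ) ε_A(λ) λ⁴ dλ`,
  Förster radius `R0⁶ = 8.79×10⁻⁵ κ² n⁻⁴ Q_D J` (Å⁶, J in M⁻¹cm⁻¹nm⁴),
  `E = 1/(1+(r/R0)⁶)`, and `r = R0 (τ_T/τ_D)^{1/6}` from measured transfer
  times, with κ² interval sweeps returning distance ranges;
- **TCSPC reconvolution** — multi-exponential fits of photon-counting
  histograms using the analytic exponential⊗Gaussian model
  `(α/2) e^{σ²/2τ² − t/τ} erfc((σ/τ − t/σ)/√2)` and Poisson maximum
  likelihood, BIC model selection, and acceptor-channel rise extraction
  (negative-amplitude component = FRET feeding time);
- **transient-absorption target analysis** — closed-form populations of a
  two-population kinetic scheme (a dominant close-contact subpopulation
  transferring in ~10 ps, a minority slipped population at ~1 ns) convolved
  with a 280 fs Gaussian instrument function, fitted to band-integrated
  stimulated-emission kinetics;
- **free-energy-profile basins** — prominence-filtered minima with watershed
  boundaries, Boltzmann populations at 298 K, and stacked / slipped / distal
  classification of inter-dye distances;
- **photodimerization kinetics** — exponential-to-completion vs linear-drift
  model selection (AICc) and promoted / inhibited / ambiguous classification
  against controls.

## Worked example

The numbered drivers under `analysis/` run each study end to end and write
tables under `results/`. For example, the transient-absorption target
analysis (`python analysis/05_ta_target.py`) prints:

```
t6 fast transfer time, heptamer: 10.41 ps (truth 10.4) ok
t7 fast transfer time, octamer: 7.90 ps (truth 7.9) ok
delayed rise (donor vs direct acceptor pumping): 7.1 ps
```

Twenty ΔmOD maps per barrel are simulated from the two-population scheme
with the fast transfer time as ground truth, the 575–605 nm Nile red
stimulated-emission band is integrated, and the target model is refitted
freeing the fast rate, amplitude and time zero: the mean recovered time
constants land on the ground truths, and the model-free delayed-rise metric
(~7 ps, of order 1/k_fast) distinguishes donor pumping from direct acceptor
excitation. Likewise `python analysis/03_tcspc_lifetimes.py` recovers the
four control lifetimes (15.9, 4.10, 4.9, 19.8 ns) from reconvolution fits of
Poisson decay histograms, and `python analysis/01_screen_panels.py` ranks
the 15-barrel screen, finding exactly the 10 constructed FRET-positive
barrels.

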