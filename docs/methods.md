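# Methods

## Physical model and assumptions

The molecule is a two-surface Born–Oppenheimer vibronic system.  Each
electronic surface (ground `g`, one excited `e`) carries the same set of
harmonic normal modes with its own frequencies; the excited-surface minimum is
displaced along each mode by a dimensionless shift d_k (ground-frequency
convention, Q_k = √ω_g x_k with ħ = m = 1, so the Huang–Rhys factor is
S_k = d_k²/2).  Modes are parallel: no Duschinsky rotation is computed
internally.  Anharmonicity, additional excited surfaces and nonadiabatic
couplings are out of scope; the method therefore applies to molecules whose
vertical excitation region is far from avoided crossings.

The truncated vibronic basis holds, per surface, the zero-quanta state plus
the one-quantum fundamental of every mode (a knob raises the truncation for
convergence studies such as the FC sum rule).  Energies are re-referenced so
the global ground vibronic state sits at 0, which fixes all phase conventions.

**Transition dipoles.**  Between surfaces,
μ(Q) = μ₀ + Σ_k (∂μ/∂Q_k) Q_k (Herzberg–Teller expansion around the ground
equilibrium geometry, derivatives along ground-state normal modes).  Matrix
elements combine per-mode Franck–Condon overlaps and ⟨v_e|Q_k|v_g⟩ elements,
both from an exact two-frequency displaced-oscillator recursion (validated to
10⁻¹⁰ against quadrature).  Same-surface (IR) dipoles are neglected.  For
Duschinsky-mixed data from external vibronic codes, explicit state-pair FC/HT
tables can be imported through the model file and override the analytic
factors.

## From the trajectory to the cross-section

1. **Propagation.**  i ċ = [H₀ − μ̂·ε(t)] c on the truncated basis, integrated
   with the two-step explicit stencil c(t+dt) = c(t−dt) − 2i dt H(t) c(t)
   (one RK4 startup step).  Coefficients keep absolute phases e^{−iE_J t}; no
   rotating-wave approximation is made in the dynamics.  In the weak-field
   study regime the excited-surface amplitudes equal the first-order
   perturbative wave function (verified: doubling ε doubles them to <1%).
2. **Scattered-field coefficients.**  For each final ground-surface state N
   and scattered polarization λ,
   B_N^λ(ω_S, t) = ∫₀^t dt′ [Σ_J μ_λ^{NJ} c_J(t′)] e^{i E_N t′} e^{i ω_S t′},
   evaluated by zero-padded FFT of the Heaviside-windowed integrand (default
   padding ×8; the window is re-applied per observation time).  Only
   excited-surface intermediates contribute because same-surface dipoles
   vanish.  Before the pulse ends the cumulative lines have width ∝ 1/t; a
   constant-amplitude intermediate gives the exact finite-window sinc
   (FWHM = 7.582/t), which the tests assert.
3. **Orientational average.**  The nine B^{λη} components (three propagations
   with incident polarization along x, y, z; three scattered projections)
   form a tensor that transforms like the transition polarizability.  With
   Σ₀ = |Tr B|², Σ₁ = Σ|B_{λη}|², Σ₂ = Σ B_{λη}B*_{ηλ}, the exact fourth-rank
   isotropic rotation average of the detected intensity for the default
   geometry (incident linear polarization perpendicular to the detection
   direction, both scattered polarizations detected) is
   P̄ = (Σ₀ + 6Σ₁ + Σ₂)/30.
   Parallel- and perpendicular-polarized detection use (2,2,2)/30 and
   (−1,4,−1)/30; a traceless symmetric tensor then gives the classic
   depolarization ratio 3/4.  The weights are validated against a 10⁵-sample
   Monte-Carlo rotation average.
4. **Cross-section.**  σ(ω_S; t) = ω_I ω_S³ Σ_N P̄_N(ω_S, t) / (π c⁴ F) with
   F = ∫ε(t)²dt.  The prefactor is not a fit: it is derived by requiring the
   quasi-CW limit to reproduce the KHD spontaneous-Raman differential
   cross-section (ω_I ω_S³/c⁴)·⟨|α|²⟩ with α_N = Σ_J μ^{NJ}μ^{J0}/(E_J − ω_I − iγ)
   (resonant term only, matching the propagation, which likewise keeps no
   antiresonant bookkeeping).  `fluence()` therefore returns ∫ε²dt and the
   radiometric constants cancel by construction; the CW↔KHD agreement is an
   end-to-end test (observed ≈0.4% on the demo model), not a calibration.

## Vibrational relaxation (open system)

Each vibrationally excited basis state decays to the lowest vibronic level of
its own electronic surface with rate Γ (default: one shared phenomenological
rate, 1/1.8 ps; configurable per channel, and restrictable to the excited
surface).  Trajectories follow the Markovian quantum-jump unravelling: per
step, jump probability p_q = Γ_q|c_src|²dt; on a jump the wave function
collapses onto the channel target and is renormalized; otherwise the no-jump
step applies the unitary stencil followed by the diagonal damping
exp(−Γ dt/2) and renormalization.  Two numerical points:

* The damping cannot be folded into the two-step stencil directly — the
  stencil's characteristic roots have product −1, so damping one root grows
  the other.  Applying the same diagonal damping to both stored levels after
  the unitary step damps both roots equally and is stable; the dissipative
  part is first-order in dt.
* Correctness is pinned by oracles: ensemble survival matches exp(−Γt) within
  binomial errors, jump times pass a KS test against Exp(Γ), and driven
  ensembles match the dense Lindblad master equation (DOP853, trace drift
  guarded at 10⁻⁶) within the empirical standard errors.

Random streams: one master seed; per-trajectory (and per-incident-direction)
child streams via `numpy.random.SeedSequence.spawn`, so ensembles are
reproducible and order-independent.

## Numerical choices

* **Time step.**  Default dt = 0.024 fs.  The stencil's dispersion shifts a
  state of energy E by E³dt²/6 (≈24 cm⁻¹ at 2.28 eV and the default step);
  at 0.24 eV detuning this biases nonresonant intensities by ≈2%.  Runs meant
  for quantitative CW comparisons use dt = 0.012 fs (<1% predicted bias).
  The propagator refuses runs whose final norm drifts beyond 10⁻³ (signals
  |E_max·dt| near the stability limit).
* **Storage stride.**  Default 8 (stored step ≈0.19 fs → Nyquist ≈5 eV for
  the scattered-frequency grid, ample for optical emission).
* **FFT.**  Zero padding ×8 (×16 in line-shape tests); scattered-frequency
  windows passed explicitly to bound memory.
* **Short-pulse line pull.**  A finite-bandwidth pulse chirps the transient
  response through the adiabatic-following correction f′/(fΔ); cumulative
  lines are pulled toward the carrier by ≈1/(σ_t²Δ) (≈40 cm⁻¹ at σ = 24 fs,
  <1 cm⁻¹ at σ = 128 fs on the demo model).  This is physics of the windowed
  transform, not an artifact; position assertions are therefore tight only in
  the quasi-CW regime.
* **Degenerate inputs.**  Zero-amplitude pulses propagate trivially but are
  rejected by the cross-section (zero fluence); KHD exactly on a pole demands
  γ > 0; observation times outside the stored run, empty integration bands
  and mismatched grids raise instead of silently truncating.

## Synthetic models and study conditions

`demo_model()` is the fixed study system: modes 738/1400 cm⁻¹ (excited-state
softening to 732/1386 cm⁻¹), Huang–Rhys 0.18/0.10, 0-0 gap 2.280 eV, in-plane
μ₀ = (1.2, 0.8, 0) a.u. with weak HT derivatives — a reduced-scale stand-in
for a porphyrin-like chromophore.  Study pulses are Gaussian, 5.14×10⁵ V/m
(10⁻⁶ a.u., safely perturbative), σ = 64 fs with t₀ = 4σ and runs to 10σ
(and the doubled-width pair σ = 128 fs); nonresonant carrier 0.24 eV below
the 0-0 line, resonant carrier on it; ensembles use 50 trajectories at a
1.8 ps lifetime.  `synthesize_model(spec, seed)` draws random models from
stated ranges for property tests.

What the synthetic generator does *not* emulate: the ~100-mode density of a
real chromophore (tests use 1–3 modes; the basis builder itself is checked at
108 modes), Duschinsky mixing (import path only), anharmonicity, solvent
broadening, and anti-Stokes signals from thermal initial populations (the
initial state is always the vibronic ground state).  Passing tests therefore
validate the method's internal consistency and its CW/Lindblad/closed-form
limits, not quantitative agreement with any specific molecule.

## Known limitations

* The antiresonant two-photon pathway is omitted: quantitative accuracy is
  limited to resonant/preresonant excitation; far-infrared carriers would
  need it.
* One excited surface only; no radiative (electronic) decay channel and no
  pure dephasing in the jump operators.
* Raman and fluorescence are reported as one total scattering cross-section
  in resonance — the two contributions are not decomposed.
* The leapfrog dispersion bias grows as E³dt²; heavy molecules with bright
  states far above 3 eV need a smaller step than the default.
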