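# tdraman

Time-resolved spontaneous Raman and fluorescence of molecules from real-time
vibronic wavepacket propagation.

## What it computes, and for whom

Spontaneous Raman scattering is a two-photon process: an incident field drives
the molecule into a transient superposition of excited vibronic states (the
"virtual state"), from which a photon is emitted at a frequency shifted from
the carrier by a vibrational quantum.  Standard tools compute the *total*
Raman cross-section of a CW field from the Kramers–Heisenberg–Dirac (KHD)
polarizability.  `tdraman` instead asks *when* the signal is emitted: it
propagates the vibronic wave function in real time under a laser pulse of
arbitrary shape (analytic Gaussian envelope or tabulated by points) and
accumulates the **cumulative time-dependent cross-section** σ(ω_S; t) — the
scattered energy per unit scattered frequency and solid angle collected up to
the observation time t, divided by the incident fluence.  Because Raman
scattering and fluorescence both live in the second-order response, the same
run yields the early-time sharp Raman lines and the late-time fluorescence
growth, on one footing.  It is aimed at molecular/chemical physicists studying
pulsed (femtosecond-to-picosecond) Raman experiments and the Raman–fluorescence
interplay in resonant conditions.

## Model

* **Vibronic basis.**  Two Born–Oppenheimer electronic surfaces, each dressed
  with harmonic normal modes (displaced, optionally frequency-changed between
  surfaces; parallel-mode approximation).  Default truncation: the zero-quanta
  state plus every one-quantum fundamental per surface.
* **Transition dipoles.**  μ(Q) = μ₀ + Σₖ (∂μ/∂Qₖ) Qₖ between surfaces
  (Franck–Condon plus Herzberg–Teller); analytic overlap recursions, or
  imported FC/HT tables for Duschinsky-mixed data.  Same-surface dipoles are
  zero.
* **Propagation.**  i ċ = [H₀ − μ̂·ε(t)] c with a two-step explicit
  ("second-order Euler") stencil; coefficients keep absolute phases.
* **Scattered field.**  Second-order coefficients by windowed FFT:
  B_N(ω_S, t) = ∫₀ᵗ dt′ ⟨N|μ_λ|Ψ(t′)⟩ e^{i(E_N+ω_S)t′}.  The nine (λ, η)
  polarization components form a tensor whose rotational invariants give the
  isotropic orientational average for a chosen illumination–detection
  geometry (default: incident polarization ⊥ detection, unpolarized).
* **Cross-section.**  σ(ω_S; t) = ω_I ω_S³ Σ_N P̄_N(ω_S, t) / (π c⁴ ∫ε² dt),
  whose quasi-CW limit is the KHD differential cross-section — the built-in
  sum-over-states oracle `khd_cross_section` verifies this.
* **Relaxation.**  Vibrational decay via the stochastic Schrödinger equation
  with quantum jumps; trajectory averages converge to the built-in Lindblad
  master-equation oracle.

## Worked example

The built-in demo model is a reduced-scale porphyrin-like chromophore: modes
at 738 and 1400 cm⁻¹, 0-0 transition at 2.280 eV, in-plane transition dipole
with weak Herzberg–Teller activity.  Driving it below resonance (2.04 eV,
5.14×10⁵ V/m, σ = 32 fs Gaussian pulse centred at 128 fs):

```bash
$ tdraman demo --out demo_spectrum.tsv --sigma-fs 32
wrote demo_spectrum.tsv
cumulative 738 cm^-1 band integral (a.u.) at t=128 fs, t=224 fs, t=320 fs:
  2.1980e-11  2.8488e-11  2.8485e-11
```

Read: at the envelope peak (128 fs) about three quarters of the final Raman
signal in the 738 cm⁻¹ Stokes band has already been emitted; once the pulse is
over the integral is flat to 0.01% — nonresonant Raman stops with the field.
The plateau value is the per-line CW cross-section: the sum-over-states oracle
for the same model and carrier gives

```bash
$ tdraman khd --model model.txt --omega-ev 2.0401    # model.txt from `tdraman synthesize` or write_model
state  shift_cm1  dsigma/dOmega_au
    0       0.00  1.098500e-09
    1     738.00  3.176900e-11
    2    1400.00  3.096700e-11
```

i.e. the time-domain plateau (3.13×10⁻¹¹ a.u. with a quasi-CW σ = 128 fs
pulse) reproduces the KHD line within 0.5%.  Driving the same model *on*
resonance instead makes the band integral keep growing long after the pulse
peak — that is the fluorescence contribution accumulating — and a twice-longer
pulse then yields a *larger* late-time signal, the opposite of the nonresonant
behaviour.

The library surface mirrors the pipeline: `demo_model` / `synthesize_model` →
`GaussianPulse`/`TabulatedPulse` → `propagate_first_order` or
`run_sse_ensemble` → `time_resolved_spectrum` / `sse_averaged_spectrum` →
`peak_integral`, with `khd_cross_section` and `propagate_lindblad` as
independent oracles.  See `docs/methods.md` for the science and the numerical
choices.

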