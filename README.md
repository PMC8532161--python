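# gelnmr

NMR relaxometry toolkit for starch–sugar confectionery gels (Turkish
delight / lokum), aimed at food-physics and NMR groups that use
fast-field-cycling (FFC) and benchtop time-domain NMR to authenticate
and characterize gel formulations: original sucrose gels versus
corn-syrup ("adulterated") substitutes.

## What it computes

**Dispersion (NMRD) modelling.** The spin–lattice relaxation rate of the
mobile protons (water plus dissolved sugar) is modelled as

```
R1(ω) = R1_rot(ω) + R1_trans^MM(ω) + R1_trans^LM(ω)
```

* `R1_rot` — BPP-type rotational term `C_intra [J(ω) + 4J(2ω)]` with the
  Lorentzian spectral density `J(ω) = τ/(1+ω²τ²)` averaged over a
  log-Gaussian distribution of correlation times (centre `τ_rot`, width
  `δ = 1.5` decades).
* `R1_trans` — Torrey's jump-diffusion intermolecular term for each of
  two translational pools (MM = more mobile, LM = less mobile):
  `C_inter (N τ_t/d³) [f(δ_j, ωτ_t) + 4 f(δ_j, 2ωτ_t)]`, with
  `C_inter = (9/8)(μ₀γ²ħ/4π)²`, jump time `τ_t = d²/(6D)`, closest
  approach `d = 3.6 Å`, and `δ_j = ⟨a²⟩/(12d²) = 1/12` under `a = d`.
  The Torrey spectral function is evaluated in closed form (contour
  residues of the defining wavenumber integral).

Fitting follows a two-stage shared-parameter protocol: six free
parameters `(C_intra, τ_rot, D_MM, D_LM, N_MM, N_LM)` at 25 °C, then
four free parameters at 4 °C with the spin densities `N_MM, N_LM`
frozen. Derived authenticity quantities: `N = N_MM + N_LM`,
`N_MM/N_LM`, relative changes against the sucrose reference, and a
low-frequency discriminant (mean R1 below 1 MHz).

**Time-domain T2 analysis.** Mono-exponential fits, discrete
two-component decomposition of CPMG decays into `(T2a, RA1)` /
`(T2b, RA2)`, Tikhonov-regularized non-negative inverse-Laplace T2
spectra, and the zero-method conversion `T1 = t(Mz=0)/ln 2`.

**Quality metrics.** CIE76 total color change ΔE against the sucrose
reference, TPA descriptor algebra (gumminess = hardness × cohesiveness,
chewiness = gumminess × springiness), moisture relative change, and a
Pearson-correlation utility.

**Synthetic acquisition.** Because no raw dispersion or decay data are
deposited, a first-class generator module emulates the acquisitions
(pre-polarized/non-polarized FFC curves with 22 log-spaced delays,
≤ 5 % relative error on R1; CPMG with 100 µs echo spacing; saturation
recovery) from the published fitted parameters of the four
formulations, registered under their sample names `SUC`, `SBF10`,
`SCG40`, `SCG60`.

## Worked example

```python
import gelnmr as g

# forward-simulate the sucrose gel's dispersion profiles and refit them
grid = g.make_frequency_grid(1e4, 2e7, 30, [5e8])      # 10 kHz-20 MHz + 500 MHz
p25 = g.simulate_nmrd_profile(g.nmrd_params_for("SUC", 25.0), grid,
                              noise_fraction=0.0, seed=1,
                              sample_id="SUC", temperature_C=25.0)
p4 = g.simulate_nmrd_profile(g.nmrd_params_for("SUC", 4.0), grid,
                             noise_fraction=0.0, seed=2,
                             sample_id="SUC", temperature_C=4.0)
res = g.fit_nmrd_joint(p25, p4, g.FitProtocol(seed=1))
print(res.params_report()["25.0"]["D_mm_1e-12_m2s"])   # 1.7000...
print(g.derive_quantities(res).report())
# {'N_total_1e28_per_m3': 5.72, 'ratio_N_mm_over_N_lm': 3.3, ...}

# discrete T2 decomposition of a noisy synthetic CPMG decay
decay = g.simulate_cpmg_decay(g.SAMPLE_T2_PARAMS["SUC"],
                              g.AcquisitionSpec(sequence="CPMG", n_echoes=256),
                              noise_sd=0.01, seed=1)
print(g.fit_discrete_multiexp(decay, 2).report())
# {'T2a_ms': 2.252..., 'RA1_pct': 53.95..., 'T2b_ms': 12.91..., 'RA2_pct': 46.05...}

print(round(g.delta_e(g.COLOR_TABLE["SBF10"], g.COLOR_TABLE["SUC"]), 2))  # 6.38
```

The noiseless joint fit returns the generating parameters exactly
(`D_MM = 1.70e-12 m²/s`, `N = 5.72e28 m⁻³`, ratio 3.3); with 1–2 %
instrument-level noise single realizations scatter (as in the CPMG
decomposition above) while multi-seed medians stay on the generating
values.

A shell pipeline wraps the same functions:

```bash
gelnmr report --out out/ --seed 3            # simulate -> fit -> t2 -> quality
gelnmr fit-nmrd --out out/ --sample SUC --sample SBF10
```

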