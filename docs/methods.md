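# Methods

## The composite dispersion model

The measurable protons of a starch–sugar gel under field-cycling
conditions are the "mobile" fraction — water and dissolved sugar; the
rigid gelator protons dephase within the receiver dead time and
contribute no signal. The spin–lattice relaxation rate as a function of
Larmor angular frequency ω is modelled as the sum of one rotational and
two translational channels,

```
R1(ω) = R1_rot(ω) + R1_trans^MM(ω) + R1_trans^LM(ω).
```

The split into a more-mobile (MM) and less-mobile (LM) translational
pool reflects the pore-scale heterogeneity of the gel: molecules in
large pools diffuse faster than those confined in small pockets, and
the two time scales are far enough apart that a single effective
diffusion coefficient cannot average them.

### Rotational channel

`R1_rot = C_intra [J(ω) + 4J(2ω)]` with the Lorentzian spectral density
`J(ω) = τ/(1+ω²τ²)`, averaged over a distribution of rotational
correlation times that is Gaussian in log10 τ with centre `τ_rot` and
standard deviation `delta_rot` in decades (default 1.5, held fixed
during fitting). `C_intra` (s⁻², order 4×10⁹ for these gels) is the
intramolecular dipolar relaxation constant, proportional to the inverse
sixth power of the mean intra-molecular proton–proton distance.

The average is a fixed-node trapezoidal quadrature on an even log10 τ
grid spanning ±4·`delta_rot` around the centre with 128 nodes, weights
renormalized to unit mass. Against a 10⁴-node reference the default
rule is accurate to better than 10⁻³ relative at ω = 0 (the
worst-conditioned point) and ~10⁻⁶ over the measured window;
`delta_rot = 0` reduces exactly to the single-τ BPP expression. The
quadrature is deterministic and cheap, which keeps the least-squares
objective smooth.

A consequence worth knowing: with a 1.5-decade width, the sub-MHz part
of `R1_rot` is carried by the ≳3σ long-τ tail of the distribution, so
low-frequency rotational amplitudes are very sensitive to `τ_rot` and
to the tail treatment. This matters for the four-sample low-frequency
ranking (see Limitations).

### Translational channels (Torrey jump diffusion)

Each pool contributes

```
R1_trans = C_inter (N τ_t / d³) [ f(δ_j, ωτ_t) + 4 f(δ_j, 2ωτ_t) ],
C_inter = (9/8) (μ₀ γ² ħ / 4π)² ≈ 6.408e-49 m⁶ s⁻²,
```

where `N` is the proton density of the pool (m⁻³), `d` the distance of
closest approach between interacting molecules (3.6 Å, fixed: between
the water and sugar molecular diameters), `τ_t = d²/(6D)` the mean time
between translational jumps, and `δ_j = ⟨a²⟩/(12d²)` the reduced jump
parameter — exactly 1/12 under the simplifying assumption that the mean
jump length equals `d`. Each pool therefore exposes exactly two free
parameters, `D` and `N`.

`f` is the spectral function of the isotropic jump-diffusion
(random-flight) model: propagator `exp(-t(1-A(k))/τ)` in wavenumber
space with `A(k) = 1/(1 + k²⟨a²⟩/6)`, uniform spin density outside `d`.
Carrying out the dipolar lattice sum gives

```
f(δ, u) = (32/15) ∫₀^∞ j₁(x)² · B(1+B) / (B² + u²(1+B)²) dx,
B = 2δx²,  u = ωτ_t,
```

with `j₁` the spherical Bessel function. The integrand is a rational
function of x² times `j₁²`, so the integral has a closed form by
contour integration; the implementation evaluates the two
upper-half-plane residues (at `B = (-u² ± iu)/(1+u²)`) with a
cancellation-safe series for the entire factor
`[(1+z²) + (z+i)²e^{2iz}]/(2z⁴)` near the origin. At `u = 0` the
integral is elementary: `f(δ,0) = (32/15)(π/6 + π/(30δ))`. The closed
form agrees with direct numerical quadrature of the defining integral
to ~10⁻¹¹ relative over eight decades of `u` (this is a test), runs in
vectorized constant time per frequency, and is finite, positive and
strictly decreasing — which the quadrature-based alternative could not
guarantee cheaply inside an optimizer loop.

The same normalization of `f` is used for simulation and fitting, so
every parameter-recovery statement is convention-independent. The
absolute scale was sanity-checked against the classic
continuous-diffusion limit for water, which it reproduces within the
usual model-level factor ~2 (relative vs. self diffusion of the spin
pair).

### Two-stage joint fitting

Weighted least squares with per-point σ = relative_error × R1 (5 %
assumed where the error column is absent — the instrument's stated
bound). Stage 1 fits the 25 °C profile with six free parameters; stage
2 fits the 4 °C profile with four free parameters, the spin densities
frozen bit-identically at their stage-1 values. This mirrors the
measurement logic: the proton content of the pools is a composition
property and should not change over 21 K, while the dynamics (τ_rot,
D) do.

Optimization is bounded trust-region least squares (`scipy`'s `trf`) in
log10 parameter space, with a deterministic mid-bounds start plus
seeded log-uniform multistarts (8 total). Default bounds bracket the
expected values by ≥ 2 orders of magnitude: τ_rot ∈ [1 ps, 1 µs],
D ∈ [1e-14, 1e-9] m²/s, N ∈ [1e27, 1e29] m⁻³, C_intra ∈ [1e8, 1e10]
s⁻². After each stage the two translational pools are relabelled so
that D_MM > D_LM, preventing label switching across starts; stage-2
relabelling carries the frozen spin densities along with their pools.
Parameter uncertainties come from the Jacobian-based covariance at the
optimum (± one standard error). A fitted 4 °C dynamics faster than at
25 °C triggers a warning (not an error): it usually indicates a poor
profile rather than physics.

An optional frequency window can be down-weighted (σ × 10) to tolerate
unmodelled structure — e.g. a relaxation enhancement confined to
0.15–2 MHz — as structured residual without biasing the rest of the
fit.

## Synthetic acquisition layer

The generators emulate the structure of the two instruments, not their
absolute signal scale (raw amplitudes and exact delay lists are not
published):

* **NMRD profiles**: 30 log-spaced frequencies from 10 kHz to 20 MHz
  plus a conventional high-field point at 500 MHz; relative Gaussian
  noise on R1, default 2 %, capped at the instrument's 5 % bound. The
  R1 noise is applied directly to the forward-model rate because each
  published R1 already condenses one mono-exponential magnetization
  curve.
* **Magnetization curves**: mono-exponential evolution over 22
  log-spaced delays spanning [T1/50, 5 T1]; pre-polarized (decay-type)
  below 10 MHz, non-polarized (recovery) at and above; polarization at
  the 20 MHz-equivalent field for 5 T1; saturation recovery with a
  300 ms relaxation period; absolute Gaussian amplitude noise.
* **CPMG decays**: echo maxima at t_k = k × 100 µs, no t = 0 sample;
  128 echoes matches the emulated benchtop acquisition, while
  validation decays default to 256 echoes because the 12.8 ms window of
  the 128-echo setting samples the ~13 ms long component over barely
  one time constant (the 128-echo setting remains available and is
  exercised noiselessly in the tests).

All generators are pure functions of (parameters, seed). Ground-truth
parameter sets for the four formulations — dispersion-model parameters
per temperature (spin densities determined at 25 °C and shared), the
discrete (T2, RA) pairs, moisture, color and texture tables — ship as a
registry keyed by sample name, so tests and the pipeline reference the
study conditions symbolically.

What passing the synthetic round-trip tests shows: the estimator is
consistent and unbiased-at-median under the stated noise model at the
stated sample sizes. What it does not show: robustness to the
instrument effects the generator omits (field-switching transients,
dead-time truncation, correlated baseline drift) or to model
misspecification of real gels.

## Time-domain analysis

* **Mono-exponential fits**: `offset + amplitude·exp(-t/T)`; the
  sequence tag selects the expected orientation and seeds the initial
  guess (time constant from the 1/e crossing). Failure to bracket a
  positive time constant inside the sampled window raises.
* **Discrete decomposition**: variable projection — outer bounded
  least squares over log10 T2, inner non-negative least squares for the
  amplitudes; deterministic nested multistart. RA_i = 100·A_i/ΣA by
  construction. Components collapsing within 1 % in T2 (or losing all
  amplitude) are merged and the reduced model returned with a warning.
* **Inverse Laplace transform**: min ‖Ka − y‖² + λ²‖a‖² subject to
  a ≥ 0, solved by NNLS on the augmented system; default grid 100
  log-spaced T2 nodes over [10 µs, 1 s], default λ = 0.1 chosen from an
  L-curve scan at the 1 % noise level (an `l_curve_scan` helper exposes
  the ladder). Peaks are contiguous positive runs split at interior
  local minima; per-peak T2 is the amplitude-weighted mean in log10 T2
  (the natural average on a log grid); peak areas partition the total
  exactly. Grid nodes below the first echo are required by the grid
  contract but are only weakly constrained by data; with small λ and
  noisy decays they can host spurious dead-zone peaks, which is why the
  discrete fit — not the ILT — is the primary route to the published
  (T2, RA) table and the ILT end-to-end checks are asserted on
  multi-seed medians.
* **Zero method**: T1 = t(Mz = 0)/ln 2, with a linear-interpolation
  zero-crossing helper for sampled curves.

## Quality metrics

CIE76 ΔE (plain Euclidean distance in L*a*b*; it reproduces all three
published ΔE values exactly from the published color coordinates),
gumminess/chewiness products, plain-ratio relative changes, and Pearson
correlation. The published chewiness magnitudes are not the product of
the published hardness × cohesiveness × springiness columns in
consistent units; the module computes the product and leaves that
inconsistency alone. Correlating the table-mean hardness against the
short T2 component gives r ≈ −0.95; replicate-level raw data (not
published) would be needed to reproduce the −0.94 reported from
replicates.

## Known limitations

* **Identifiability of D_LM.** The LM translational term disperses in
  the same 0.1–3 MHz region where the broad rotational distribution is
  also dispersing, so D_LM is the most weakly identified parameter. At
  2 % profile noise the 20-seed median recovery of all six free
  parameters is within 15 % (D_MM within 3 %); at the 5 % instrument
  error bound the D_LM median error grows to ~20 % even though the
  optimizer reaches the global basin on every seed — the limitation is
  statistical, not numerical.
* **Four-sample low-frequency ranking.** With the published 25 °C
  parameter sets, the forward model puts the 60 %-glucose formulation's
  sub-MHz amplitude below the sucrose gel's (its 0.11 ns τ_rot starves
  the long-τ tail that carries the sub-MHz rotational plateau), so the
  "sucrose lowest below 1 MHz" ranking holds across all four samples at
  4 °C but not at 25 °C; pairwise sucrose-vs-SBF10 discrimination holds
  at both temperatures. Measured 25 °C profiles additionally contain a
  0.15–2 MHz enhancement in two syrup samples that is deliberately
  outside the model.
* **Single-temperature data** can only run stage 1; spin densities are
  then reference-temperature estimates without the cross-temperature
  consistency constraint.
* The ILT is a smoothing estimator: peak positions are grid-quantized
  and relative areas broaden by a few percentage points at realistic
  noise.

## Reported problem sizes

The recovery studies run at the study's own sizes: 31-point + 500 MHz
profile grids with 20 noise realizations for the dispersion fit, and
256-echo decays with 100 realizations for the T2 decomposition; both
complete in well under a minute of CPU.
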