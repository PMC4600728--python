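# Methods

## Rocking model and observables

A molecule's rigid-body orientation in its lattice site is encoded as a
series of proper rotations Ξ(t) relative to reference coordinates,
obtained by least-squares (Kabsch) superposition of a Cα selection after
mapping each symmetry copy back into the template frame with its stored
lattice transform. Fitting on Cα only, with NH wobble applied exclusively
to amide hydrogens, keeps the rotation extraction strictly independent of
internal dynamics; translations are removed by centroid subtraction, so
the analysis is rotation-only by construction (the rocking pivot in the
generator is the Cα centroid for the same reason).

The isotropic rocking correlation function is

    g_rock(τ) = ⟨ P₂( (Ξ(t)u_k) · (Ξ(t+τ)u_k) ) ⟩_{k, t, molecules}

averaged over a deterministic quasi-uniform (generalized-spiral) set of
100 unit vectors, all time origins (stride configurable), and molecules.
P₂ is applied per vector pair first, then averaged — the alternative of
averaging orientation tensors first agrees in expectation but differs
slightly at finite sampling. The vector average is evaluated exactly
through the fourth-moment tensor of the vector set (algebraically
identical to the explicit loop, verified against it in the tests). The
lag grid is log-spaced, ~25 points per decade, from one frame to one
fifth of the trajectory.

Molecule curves are averaged after outlier rejection: a curve is flagged
when its RMS deviation from the pointwise median curve exceeds 3× the
median of all curves' RMS deviations. This k·MAD-style rule is this
package's own definition; with few molecules and short trajectories an
occasional unlucky realization is flagged, which is the intended
behaviour.

The mean curve is fitted with a flat base plus two exponentials,
g(τ) ≈ S² + c_f e^(−τ/τ_f) + c_s e^(−τ/τ_s), amplitudes bounded
non-negative, both times restricted to (Δt, T], multi-start over a
log-spaced initialization grid. When the underlying decay is effectively
mono-exponential the two fitted times are degenerate and their
fast/slow labels arbitrary; `BiExpBaseFit.slow_component()` therefore
merges all components slower than a 10 ns libration cutoff
amplitude-weighted, preserving Σcᵢτᵢ — the moment that controls the
spin-lock relaxation contribution in the ωτ ≪ 1 regime. All relaxation
read-outs use this merged (1−S² = c_s, τ = τ_s) identification, with the
~1 ns fast component excluded: at 39.5 kHz MAS and 15 kHz spin-lock its
contribution is below 2% (asserted in the tests).

## Order-parameter conventions for the two-site jump

Two distinct closed forms coexist and are both exposed:

- a **single vector** jumping between two orientations separated by Φ
  (equal populations) has plateau S² = (1 + 3cos²Φ)/4 — the convention of
  the relaxation jump model, where Φ is the NH-vector jump angle;
- a **rigid body** rotated by Φ moves different vectors by different
  angles (vectors on the rotation axis not at all), so the plateau of an
  isotropically averaged vector set is
  (2 + 2cos²Φ + cosΦ)/5, derived here from the isotropic average
  ⟨P₂(u·R_Φu)⟩ = (4cos²Φ + 2cosΦ − 1)/5. Its range is [0.375, 1]: a
  rigid-body two-site jump cannot depress an isotropic-vector plateau
  below 0.375.

g_rock of a rigid-body jump converges to the second form; the numerical
relaxation model uses the first. Mixing them up changes plateaus by up to
0.15 at large angles.

## Synthetic processes (what they emulate, and what they do not)

No generative model of rocking is claimed for real crystals; the two
processes are controllable stand-ins producing known ground truth:

- **Two-site jump**: orientations at ±Φ/2 about a fixed axis,
  exponentially distributed dwell times with per-site escape rate k_ex;
  symmetric exchange, so the model-free correlation time is 1/(2k_ex).
- **Restrained diffusion**: independent Ornstein–Uhlenbeck processes
  (exact discretization) on the three rotation-vector components,
  composed via the exponential map each frame. Stationary by
  construction; per-axis standard deviation σ and relaxation time τ. The
  P₂ correlation decays mono-exponentially with time constant ≈ τ to
  leading order in σ²; the approximation is good for σ ≲ 0.3 rad. The
  map σ → plateau has no simple closed form and is computed by a seeded
  deterministic Monte-Carlo average (2×10⁵ pairs) and inverted by
  bisection (`sigma_for_plateau`).

Internal NH motion is a Gaussian axial wobble of the amide H about its
reference N–H direction (two OU tilt components, rms total tilt set by
the nominal cone semi-angle, N fixed). Real internal dynamics are richer
(anisotropic, multi-timescale, affecting all atoms); passing tests on
these processes therefore validate the *analysis machinery*, not any
claim about real crystal dynamics. Trajectories carry no translational
diffusion and no lattice drift — meaning the synthetic data are kinder
than MD, where slow lattice distortion contaminates g_rock at long lags.

Default study conditions for recovery experiments: 8 molecules
(4 symmetry copies × 2 cells), 10⁵ frames at 1 ns spacing (100 µs span),
rocking plateaus {0.995, 0.982, 0.957} with τ ∈ {0.2, 0.5, 1.0} µs.
The pairing puts the smallest amplitude with the shortest time: a 0.5%
amplitude decaying over 1 µs leaves too few independent blocks in a
100 µs window for a 25% timescale estimate, and no parameter choice can
fix an information deficit.

## Spin-lock relaxation under MAS

With the P₂-normalized correlation function C(τ) = S² + Σcᵢ e^(−τ/τᵢ)
and J(ω) = (2/5)Σcᵢτᵢ/(1+(ωτᵢ)²) — the 2/5 carried inside J, so that
R₁ = (d²/4)[J(ω_H−ω_N) + 3J(ω_N) + 6J(ω_H+ω_N)] + c²J(ω_N) with
c = Δσ·ω_N/√3 — the on-resonance spin-lock rate under MAS is

    R₁ρ^DD  = (d²/8)[ (4/3)(J(ω₁−ω_r)+J(ω₁+ω_r)) + (2/3)(J(ω₁−2ω_r)+J(ω₁+2ω_r))
                      + J(ω_H−ω_N) + 3J(ω_N) + 6J(ω_H) + 6J(ω_H+ω_N) ]
    R₁ρ^CSA = (c²/6)[ (4/3)(J(ω₁−ω_r)+J(ω₁+ω_r)) + (2/3)(J(ω₁−2ω_r)+J(ω₁+2ω_r))
                      + 3J(ω_N) ]

i.e. the static secular J(0) weight is redistributed over the MAS
sidebands of the spin-lock frequency with the magic-angle Wigner weights
|d²₀,±1|² = 1/3 and |d²₀,±2|² = 1/6, while the high-frequency
non-secular terms keep their solution-state form. Defaults r_NH = 1.02 Å
and Δσ(¹⁵N) = −170 ppm (axially symmetric, collinear with the bond), both
configurable; gyromagnetic ratios and ħ are CODATA 2018 values pinned in
`constants.py`. A warning is issued at the rotary-resonance conditions
ν₁ = ν_r, 2ν_r and an advisory when τ exceeds the inverse of the smallest
sampled frequency gap.

These expressions are *pinned* against an independent exact propagation
rather than trusted on transcription: `r1rho_numeric_jump` integrates the
classical (Bloch) spin-locked magnetization of ¹⁵N under the analytic
MAS-modulated dipolar + CSA frequency offset of each crystallite, with
two-site orientational exchange as a symmetric 6×6 superoperator, over a
144-orientation powder grid (48 spiral directions × 3 jump-plane
azimuths), 100 rotor steps per period, both proton spin states averaged
(which cancels dipole/CSA cross-correlation in the rate). The
powder-averaged decay is fitted log-linearly over a 50 ms spin-lock
window sampled each rotor period; decays with log-fit R² < 0.98 are
flagged non-exponential. A stochastic-trajectory mode (explicit random
telegraph jumps, vectorized Rodrigues steps) cross-checks the
superoperator treatment.

**Where the two agree.** In the weak-coupling, fast-exchange corner
(jump angles of a few degrees, k_ex ≳ 10⁶ s⁻¹) the propagation matches
the Redfield expressions to better than 10% (better than 1% when the
coupling is artificially weakened — confirming the transcription). At
the physical NH coupling (d/2π ≈ 11.5 kHz, comparable to the 15 kHz
spin-lock) higher-order effects genuinely depress the exact rate below
the perturbative one, increasingly so for larger jump angles and slower
exchange; at Φ = 30°, k_ex = 10⁴ s⁻¹ the exact rate is ~5× smaller.
This amplitude-dependence means a validity rule phrased purely in terms
of exchange rate versus sampled frequencies is incomplete. The powder
decay is also intrinsically multi-exponential, so the fitted rate depends
weakly on the fit window; the 50 ms window with modest total decay
approximates the powder-averaged initial rate, which is what the
perturbative expression predicts.

The (S², τ) rate surface is evaluated row-wise; iso-rate contours and
the two-branch τ solver locate the rate maximum in log τ (the surface is
unimodal in τ per row, asserted) and bisect on each side, returning an
explicit no-solution marker when the target exceeds the maximum. Solving
the 12 s⁻¹ contour at S² = 0.985 under the measurement conditions yields
a fast branch ≈ 0.6 µs and a slow branch ≈ 32 µs with the default
interaction constants; the slow branch moves across roughly 25–50 µs as
r_NH and Δσ vary within their plausible ranges, which is why relaxation
data alone bound the rocking timescale only to the
hundreds-of-nanoseconds-to-tens-of-microseconds window.

## Internal-dynamics observables

Order parameters use the Cartesian second-moment (Brüschweiler–Wright)
form S² = (3 ΣₐᵦQ²ₐᵦ − 1)/2 with Qₐᵦ = ⟨eₐe_b⟩ — algebraically identical
to the spherical-harmonic form. NH correlation functions are computed
within each molecule and then averaged over the symmetry-equivalent
copies (never across the concatenation boundary of the "long array").
Multi-exponential fits use non-negative least squares over a 40-member
log-spaced τ dictionary (Δt to the cap) followed by joint local
refinement of the ≤6 largest components; fitted times are capped at the
trajectory length. Individual (aᵢ, τᵢ) of a multi-exponential are
degenerate — only the reconstructed curve and the derived J(ω) are
well-determined, and the tests assert exactly that.

## Experimental-curve fitting

Decay rates: least-squares A·e^(−Rt); errors are the standard deviation
of rates refit on noise-resampled replicas (n ≥ 50; the fit is
scale-invariant in A). REDOR: exact delta-pulse two-spin propagation — the
S coherence carries conditional proton-space propagators V± interleaving
half-rotor-period dipolar phases (analytic integrals of the MAS
modulation) with recoupling pulses; signal = ½ Re Tr[V₊V₋†]. A B1 scale s
makes each recoupling pulse an s·π proton rotation; the default
inhomogeneity profile is a 7-point Gaussian mixture, mean 1.0, sd 5%
(probe-specific profiles are unpublished, so only the procedure is
reproduced). At s = 1 the simulation reproduces the universal
quarter-order Bessel-function curve to < 10⁻³ (64-point Gauss–Legendre in
cos β × 32 azimuths). χ² coupling fits run on a user grid with parabolic
refinement; Monte-Carlo errors resample at 3× the stated noise level
(conservative spectral-noise convention, configurable). Couplings convert
to S² = (D/D_rigid)² with D_rigid from r_NH; finite pulse widths and
multi-spin effects are out of scope.

## Packing metrics

V_m = V_cell/(Z·n_chains·M) with the general triclinic volume formula
(reduces exactly to abc for orthorhombic cells); V_s = 1 − 1.23/V_m.
Space-group multiplicities are explicit integers in the inputs — no
symbol parsing. The default chain mass is 8565 Da (ubiquitin 1–76,
average mass); the convention behind any published solvent-content value
(ions, ordered waters) is rarely stated, so comparisons use a tolerance
of a couple of percentage points.

## Determinism and problem sizes

Every stochastic component draws from `numpy.random.default_rng` seeded
from a single configured seed (per-molecule streams spawned via
`SeedSequence`); the pipeline report is byte-identical under a fixed
seed, with no timestamps in any output. Default problem sizes — 10⁵
frames × 8 molecules for recovery runs, 144-orientation powder grids,
2×10⁵-sample plateau calibration — were chosen to bound the statistical
error of each estimate well inside the tolerance it is compared at while
keeping a full run on one CPU in minutes.

## Known limitations

- The restrained-diffusion process is a small-angle approximation; above
  σ ≈ 0.3 rad the exponential-map composition is no longer a faithful
  rotational diffusion.
- The numeric relaxation model treats an isolated ¹⁵N with a static
  proton (no proton flips, no spin diffusion, no ¹H decoupling field) and
  axially symmetric CSA collinear with the bond.
- Off-resonance spin-lock tilt, R₂/NOE observables, and anisotropy
  decomposition of rocking are out of scope.
- g_rock from few molecules and finite trajectories carries correlated
  long-lag noise; the outlier rule and component merging mitigate but do
  not eliminate it.
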