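# rockdyn

Rigid-body "rocking" motion of protein molecules in crystal lattices,
analysed the way solid-state NMR and crystal MD studies do it: extract
per-molecule rotation series from multi-copy trajectories, build rocking
correlation functions, and connect their amplitudes and timescales to
¹⁵N spin relaxation measured under magic-angle spinning.

## The problem

A protein molecule sitting in a crystal is not rigidly fixed: it undergoes
small-amplitude reorientational fluctuations ("rocking") about its lattice
position. Rocking adds to the relaxation of every nuclear site equally,
so it shows up as a *floor* under the per-residue ¹⁵N R₁ρ rates measured
with a spin-lock under magic-angle spinning (MAS), and as a slight uniform
depression of dipolar order parameters. For ubiquitin, different crystal
forms show strikingly different floors: the loosely packed cubic form
(solvent content ≈ 58%) has a base R₁ρ of 12 s⁻¹ against 3.5 s⁻¹ for the
densely packed MPD form — an offset of 8.5 s⁻¹ attributable to rocking
with amplitude S² ≈ 0.985 and a correlation time somewhere between
hundreds of nanoseconds and tens of microseconds.

## What the package computes

- **Synthetic crystal trajectories** (`rockdyn.synthetic`, `rockdyn.lattice`):
  multi-copy lattices built from symmetry operators, animated with
  prescribed rigid-body rocking (two-site jump or restrained-diffusion
  Ornstein–Uhlenbeck rotation-vector process) plus per-residue NH wobble —
  ground truth for the entire analysis chain.
- **Rocking analysis** (`rockdyn.rocking`): least-squares (Kabsch) rotation
  series Ξ(t) per molecule from the Cα selection; isotropic rocking
  correlation functions g_rock(τ) = ⟨P₂((Ξ(t)u)·(Ξ(t+τ)u))⟩ over a
  quasi-uniform 100-vector set; outlier flagging; bi-exponential + flat
  base fits whose plateau is the rocking order parameter S².
- **Internal dynamics** (`rockdyn.internal`): symmetry superposition of
  all copies, per-residue S² (Brüschweiler–Wright second moments), NH
  correlation functions on a log lag grid, six-exponential + constant
  fits, spectral densities J(ω) = (2/5)Σcᵢτᵢ/(1+(ωτᵢ)²), ¹⁵N R₁, and the
  global scaling factor between two S² profiles.
- **Spin-lock relaxation** (`rockdyn.relaxation`): Redfield-theory ¹⁵N R₁ρ
  under MAS with an on-resonance spin-lock (NH dipolar + ¹⁵N CSA; the
  secular term redistributed over ω₁±ω_r and ω₁±2ω_r with magic-angle
  weights 4/3, 4/3, 2/3, 2/3 on the d²/8 scale), the (S², τ) rate surface
  with iso-rate contours, two-branch τ solving, and an exact numerical
  two-site-jump propagation (exchange superoperator, powder-averaged)
  valid outside the Redfield regime.
- **Experimental fitting** (`rockdyn.experiment`): single-exponential decay
  fits with Monte-Carlo errors; REDOR dephasing simulation (exact
  delta-pulse two-spin treatment, B1-inhomogeneity mixture) with grid χ²
  coupling fits; coupling → S² conversion.
- **Packing metrics** (`rockdyn.crystal`): Matthews coefficient and
  solvent content from unit-cell contents.

## Worked example

The built-in demo builds a four-molecule orthorhombic lattice, rocks each
molecule with a restrained-diffusion process targeting S² = 0.982 with
τ = 200 ns, recovers the rocking parameters from the trajectory, and maps
them onto the spin-lock relaxation contribution:

```sh
rockdyn run --out-dir demo --seed 1
```

prints (abridged):

```json
{
  "rock": {
    "fit": {"plateau_s2": 0.9841, "tau_s_s": 1.199e-06, "c_s": 0.00441,
            "c_f": 0.01156, "tau_f_s": 1.240e-07},
    "outliers": ["B"]
  },
  "relax": {
    "rocking_r1rho_s-1": 9.30,
    "tau_fast_s": 5.54e-07, "tau_slow_s": 3.35e-05
  },
  "solvent": {"v_m_A3_per_Da": 2.002, "v_s_percent": 38.56}
}
```

The fitted plateau (0.984) recovers the configured rocking amplitude; the
merged slow component maps to a rocking R₁ρ contribution of ~9 s⁻¹ at
600 MHz / 39.5 kHz MAS / 15 kHz spin-lock; and solving the 12 s⁻¹
iso-rate contour at that plateau returns the two timescale branches
(~0.55 µs and ~34 µs) between which relaxation data alone cannot
distinguish. The solvent stage reports the rod-form packing (V_s ≈ 39%).

Single computations are available directly:

```sh
$ rockdyn relax --s2 0.985 --tau 4e-7
8.31971                          # s^-1, the rocking contribution
$ rockdyn solvent --form cubic-PEG-ub
{"v_m_A3_per_Da": 2.8118, "v_s_percent": 56.26}
```

The 8.3 s⁻¹ computed for S² = 0.985, τ = 400 ns matches the 8.5 s⁻¹
base-rate offset measured between the cubic and MPD crystal forms.

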