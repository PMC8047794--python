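# Methods

## Physical model and assumptions

The simulated observable is the rate at which a swift probe electron
loses the excitation energy ω_n0 of a molecular transition while ending
in a Bessel vortex state of orbital angular momentum l. The treatment
is first-order perturbation theory (golden rule) with a purely
electrostatic electron–molecule coupling through the transition
potential V₀ₙ(r); the probe is paraxial, so initial and final states
factor into a longitudinal plane wave and a transverse profile. Three
standard approximations for swift electrons (ω ≪ beam energy) are
built in:

* **Non-recoil longitudinal kinematics.** The energy-conserving sum
  over final longitudinal wavenumbers is collapsed onto the single
  momentum transfer p = k_fz − k_iz = −ω/v; the sign convention is that
  the scattered electron's longitudinal wavenumber is reduced.
* **Relativistic velocity, electrostatic coupling.** v and
  k_parallel = γv follow γ = 1 + T/mc² (60 keV → v = 0.4462 c), but no
  retardation corrections are applied to the coupling.
* **Small-angle collection cutoff.** Final transverse wavenumbers are
  collected up to k_max = α·k_parallel (α the collection semi-angle in
  rad); at 60 keV and 200 mrad, k_max ≈ 13.7 bohr⁻¹.

The beam axis must pass through the molecular barycenter — decentering
modifies the selection rule — so every workflow recenters each grid on
the *unweighted* centroid of its nuclei before decomposing (mass
weighting is not used; for compact molecules the difference is a small
fraction of a bohr and far below the annulus scale).

All constant prefactors (2π factors, flux normalization) are absorbed
into a single arbitrary-units constant: only ratios across
(n, l, ω) carry information and spectra are conventionally normalized
to a unit peak. The brute-force oracle keeps its explicit azimuthal 2π,
which is why it equals 2π times the pipeline matrix element.

## Sign conventions and the selection rule

The final vortex state carries the azimuthal factor exp(−ilφ); the
multipole analysis uses the kernel exp(−imφ) and the synthesis
exp(+imφ). Together these give the selection rule **l = −m**. Both
signs live in one place each (`multipole.azimuthal_decompose`,
`rates.SELECTION_SIGN`), so the opposite convention is a single flip.
A field ∝ exp(+imφ) populates exactly the +m analysis component and
scatters exactly into channel l = −m; a real cos(mφ) field populates
±m equally and feeds l = ∓m symmetrically.

## Numerical pipeline and its controls

Per transition, the pipeline is: trapezoid Fourier transform along z at
p(ω) → interpolation onto a polar lattice about the axis → azimuthal
FFT → Bessel radial quadrature per (l, k⊥) → trapezoid k⊥ integral.

| control | default | meaning / rationale |
| --- | --- | --- |
| `n_r` | 200 | radial nodes, uniform, first node at Δr/2 (the r dr measure kills the axis point; no interpolation ambiguity at ρ = 0) |
| `r_max` | min(inscribed radius, r₀ + 6Δr) | the annular amplitude is ~e⁻³⁶ beyond the annulus; never exceeds the grid (requests beyond it raise, never extrapolate) |
| `n_phi` | 64 | azimuthal nodes; oversamples m_max ≤ 5 by >5x, pushing interpolation-aliasing into harmonics the DFT separates cleanly |
| `n_k` | 1600 | k⊥ trapezoid nodes on [0, k_max]; \|M_l(k)\|² oscillates with period ~π/r_max, and 1600 nodes hold the doubling change below 0.1% at all three reference beam settings (200 nodes gave 1.4%) |
| `interp` | `"cubic"` | Cartesian→polar resampling method. Bilinear (`"linear"`) injects spurious azimuthal harmonics at ~10⁻³ relative amplitude on desk-scale grids, i.e. ~10⁻⁶ in rates — exactly at the selection-rule validation floor; cubic puts the leakage at ~10⁻¹² while staying fast. The Cartesian lattice's 4-fold symmetry confines this noise to m ≡ m₀ (mod 4) harmonics. |
| `de_ev`, `dl` | 0.1 eV, 0.5 ħ | Gaussian broadening, interpreted as standard deviations; a `resolution_is_fwhm` switch reinterprets them as FWHM since the convention is not universal |

Beam defaults: 60 keV, 200 mrad, r₀ = 7 bohr, Δr = 3 bohr, l ∈ [−3, 3];
the annulus settings 20 × 3 and 24 × 3 bohr used for larger assemblies
are plain parameters. The Gaussian annulus normalization uses the
closed form N⁻² = 2π[(Δr²/4)e^{−2r₀²/Δr²} + r₀(Δr/2)√(π/2)(1 +
erf(√2 r₀/Δr))], cross-checked by quadrature in the tests. The radial
profile is a registry, so a top-hat annulus can be swapped in without
touching downstream code.

Dichroism D_|l| is computed from energy-convolved channel traces (not
raw sticks) so near-degenerate transitions of opposite sign can
partially cancel, as they do in excitonic couplets; a stick-level
variant exists for debugging. Where Γ₊ + Γ₋ falls below 10⁻⁸ of its
peak, D is masked (NaN), never 0/0.

## What the synthetic generators emulate — and what they do not

The fixtures stand in for TD-DFT transition potentials with fields whose
symmetry is known in closed form:

* `multipole_cube` — a single azimuthal harmonic A·r^|m|e^{−r²/2s²}·h(z)·trig(mφ),
  regular at the axis; `parity="exp"` yields a complex in-memory field
  with *pure* +m content (not writable as a cube). Defaults: 64³ points
  at 0.3 bohr; a 0.18897 bohr (0.1 Å) preset exists for convergence
  studies.
* `dipole_cube` — a point transition dipole μ·(r−r₀)/|r−r₀|³ with the
  singularity capped at 2 grid spacings (the aloof annulus never samples
  the core, and capping keeps cubes finite for I/O).
* `helical_assembly` — tangent point dipoles on a helix; the screw
  coupling of z and φ makes |Ṽ^{(+m)}| ≠ |Ṽ^{(−m)}| at p ≠ 0, i.e. a
  genuinely chiral potential, with the opposite handedness the exact
  mirror image. With pitch = 0 the assembly is even in z, which forces
  Ṽ^{(−m)} = conj(Ṽ^{(m)}) and hence zero dichroism — a sharp null test.
  Dummy hydrogens at the sites exercise centroid recentering end to end.

These fields reproduce the *structure* of real transition potentials
(multipole content, parity, chirality, 1/r² Coulomb tails) but not
their chemistry: magnitudes, energies and oscillator strengths are
inputs, and no excitonic coupling between fixtures is modelled. Passing
tests therefore demonstrate that the scattering pipeline is correct,
not that any particular molecule's spectrum is predicted; real spectra
require externally computed cubes.

## Validation strategy and problem sizes

Published OAM-EEL spectra depend on the authors' TD-DFT cubes, which
are not shipped anywhere; validation is therefore property-based, with
every expected value derived independently of the code path it checks:

* selection-rule purity on 48³ pure-harmonic cubes (leakage ~10⁻¹²
  against a 10⁻⁶ requirement);
* a brute-force 3D Riemann-sum matrix element on 32³ grids as an
  independent oracle (agreement ~10⁻⁴ against a 1% requirement). The
  oracle aliases once k⊥ approaches π/spacing, so comparisons use
  k⊥ ≤ 1 bohr⁻¹ on 0.5 bohr grids and a 60 mrad aperture for the
  integrated-rate comparison;
* the enantiomer mirror law and the planar-ring dichroism null
  (~10⁻¹⁵);
* exact quadratic response, convolution mass conservation on axes
  padded ≥ 8 widths, closed-form beam normalization vs quadrature, and
  aloof insensitivity at the 20 × 3 bohr annulus (truncating the
  potential inside ρ < r₀ − 3Δr moves rates by ~2·10⁻⁴).

Grid sizes (32³–64³, 0.35–1.0 bohr spacing) are chosen so the full
suite runs in well under a minute per criterion on one CPU; the
convergence criterion itself (doubling n_r, n_phi, n_k each moves
every rate by < 0.1%) guards the choice.

## Known limitations

* Only orthogonal, axis-aligned grids are supported; the grid z axis is
  the beam axis.
* Absolute cross-sections are out of scope (arbitrary units by design),
  as are recoil-exact kinematics, retardation, multiple scattering,
  partially coherent or decentered beams, and dose/damage modelling.
* The m ≥ 4 components of desk-scale grids carry interpolation noise at
  ~10⁻⁶ relative amplitude (4-fold lattice harmonics); for production
  work at |l| > 3 use finer grids (the 0.1 Å preset).
* `cubic` interpolation in recent scipy is not an exact interpolant on
  linear fields (≈10⁻⁶ relative); `linear` is exact there but second
  order overall. The oracle test bounds the total pipeline error either
  way.
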