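# oameels

Simulation of **orbital-angular-momentum-resolved electron energy-loss
spectroscopy (OAM-EELS)** of molecular and biomolecular electronic
transitions.

## The problem

Optical spectroscopies see molecular excitations through dipole selection
rules: dark (dipole-forbidden) transitions are invisible, and higher
multipolar character is inaccessible. A swift electron (30–300 keV) in a
transmission electron microscope couples to the same excitations through
its Coulomb field, and if the scattered electrons are sorted by their
orbital angular momentum l about the beam axis, the loss spectrum becomes
*doubly* dispersed — in energy **and** in OAM — and directly fingerprints
the azimuthal symmetry of each transition. An annular (ring-shaped) probe
of internal radius r₀ and waist Δr passes *around* the molecule (aloof
geometry), avoiding radiation damage while still exciting it.

`oameels` simulates this experiment for any set of electronic transition
potentials V₀ₙ(r) supplied as Gaussian cube files (e.g. exported from a
TD-DFT calculation), and ships analytic synthetic potentials so the whole
pipeline can be exercised and validated without any quantum-chemistry
software.

## The model

Within first-order perturbation theory, the loss rate into the OAM
channel l at the excitation energy ω_n0 is

    Γ_l(ω_n0) = ∫₀^{k_max} |M_l(k⊥)|² k⊥ dk⊥ ,
    M_l(k⊥)   = ∫₀^{r_max} J_|l|(k⊥ r) a(r) Ṽ^{(−l)}(r; p) r dr ,

where

* a(r) = N·exp(−(r−r₀)²/Δr²) is the annular probe amplitude, normalized
  to ∫|a|² 2πr dr = 1;
* Ṽ^{(m)}(r; p) are the cylindrical multipole components of the
  transition potential — the azimuthal Fourier coefficients of its
  longitudinal Fourier transform at the momentum transfer p = −ω/v
  (m = 0 monopole, ±1 dipole, ±2 quadrupole, …);
* J_|l| is a Bessel vortex final state collected up to
  k_max = α·k_parallel for a collection semi-angle α;
* kinematics are relativistic (γ = 1 + T/mc², v = c·√(1−γ⁻²)).

The azimuthal integral enforces the **selection rule l = −m**: the
scattered electron's OAM mirrors the multipole content of the transition
it excited, so dark transitions appear in |l| ≥ 2 channels. Sticks
Γ_l(ω_n0) are broadened by the product of two Gaussians (ΔE, Δl) into a
2D energy × OAM map, and chirality is quantified by the dichroic figure
of merit

    D_|l|(ω) = 100 · (Γ_{+l} − Γ_{−l}) / (Γ_{+l} + Γ_{−l})  [percent],

the electron-beam analogue of the optical circular-dichroism dissymmetry
factor: enantiomers give exact sign-flipped D_|l| spectra.

Defaults follow the reference configuration: 60 keV beam, 200 mrad
collection semi-angle, annulus 7 × 3 bohr, l ∈ [−3, 3], ΔE = 0.1 eV,
Δl = 0.5 ħ. All rates are in arbitrary units (spectra are normalized);
internal lengths/energies are atomic units, user-facing energies eV.

## Worked example

Generate two synthetic transitions — one with pure dipolar (m = 1) and
one with pure quadrupolar (m = 2) azimuthal symmetry — then simulate
their OAM-resolved spectrum:

```yaml
# synth.yaml
output_dir: run
fixtures:
  - {name: dipole_like, kind: multipole, m: 1, parity: cos, energy_ev: 5.06,
     npoints: 48, spacing: 0.35, radial_scale: 3.0}
  - {name: quadrupole_like, kind: multipole, m: 2, parity: cos, energy_ev: 5.36,
     npoints: 48, spacing: 0.35, radial_scale: 3.0}
```

```yaml
# spectrum.yaml
transitions: run/transitions.tsv
output_dir: run
```

```sh
oam-eels synth synth.yaml
oam-eels spectrum spectrum.yaml
head -16 run/sticks.tsv
```

prints

```
n	energy_eV	l	rate
1	5.0600000000e+00	-3	1.3888130505e-13
1	5.0600000000e+00	-2	2.0478780841e-34
1	5.0600000000e+00	-1	3.1930845902e-02
1	5.0600000000e+00	0	1.8592105898e-34
1	5.0600000000e+00	1	3.1930845902e-02
1	5.0600000000e+00	2	2.0478780841e-34
1	5.0600000000e+00	3	1.3888130505e-13
2	5.3600000000e+00	-3	4.1921048834e-33
2	5.3600000000e+00	-2	1.0000000000e+00
2	5.3600000000e+00	-1	1.9636962254e-32
2	5.3600000000e+00	0	2.0580795138e-33
2	5.3600000000e+00	1	1.9636962254e-32
2	5.3600000000e+00	2	1.0000000000e+00
2	5.3600000000e+00	3	4.1921048834e-33
```

Exactly as the selection rule demands, the m = 1 transition at 5.06 eV
fires only the l = ±1 channels and the m = 2 transition at 5.36 eV only
l = ±2 (the largest stick is normalized to 1; the ~1e−13 entries are the
numerical floor of the polar resampling). `run/` also contains the
energy-convolved channel traces (`channels.tsv`), the 2D energy × OAM
map (`map2d.txt`) and a provenance record (`run.json`). For a chiral
pair, `oam-eels dichroism` writes per-|l| D(ω) tables for both
structures; see `oameels.fixtures.helical_assembly` for a built-in
chiral test system.

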