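# Methods

`helixspec` models, at desk scale, the computational side of an amide I
vibrational study of the myosin relay helix peptide (the 35-residue,
acetyl-capped, acid-terminated sequence SFEQLCINYTNEKLQQFFNHHMFKVEQEEYLKEKI,
myosin II residues 465–499).  The package is organised along the path the
analysis takes: synthetic inputs → exciton Hamiltonian → linear and 2D-IR
spectra → peak-volume fitting → pump-probe/CD observables → conformational
and free-energy analysis.  This note records the models, their assumptions,
the defaults that matter, and what the synthetic data do and do not emulate.

## Synthetic backbones

Backbones are built by internal-coordinate (NeRF) chain construction with
fixed standard bond lengths and angles (tabulated in
`helixspec.synthetic_data`).  With uniform φ/ψ = −57.8°/−47.0° every interior
O(i)···H(i+4) distance comes out at 0.206 nm and the rise per residue at
0.154 nm — an ideal α-helix by the 0.35 nm hydrogen-bond criterion used
throughout.

Locally bent helices are made by a deterministic bounded least-squares
search over the φ/ψ dihedrals near each requested (i, i+4) break, seeded
with a counter-rotated crankshaft move (ψᵢ+40°, φᵢ₊₁−40°).  A strict stage
moves only the crankshaft dihedrals and pins every other hydrogen-bond
distance to its ideal value (this succeeds for breaks near the termini and
leaves the rest of the helix untouched); a relaxed stage frees the
dihedrals of residues i−1…i+5 and only requires non-target distances to
stay below the cutoff.  The accepted structure breaks exactly the requested
pairs and superimposes on the ideal helix to < 0.05 nm RMSD outside the
break spans.  Because the perturbation is dihedral-based, the downstream
arm is rigidly displaced in the global frame even though it is locally
unchanged; consequences for the Hamiltonian are discussed below.  The
crystal structures that motivate the bent conformer are not used; the break
construction is a modelling device, not a structure prediction.

Noisy trajectories add isotropic per-atom Gaussian noise to a base frame
and, optionally, toggle designated hydrogen bonds between formed and broken
geometries as a symmetric two-state Markov chain (stationary broken
fraction 1/2).  This reproduces break-and-reform *statistics* at a
controllable rate; it contains no forces, no solvent, and no correlation
structure beyond the two states, so tests that pass on it say nothing about
force-field accuracy — only that the analysis stages measure what they
claim to measure.

## Exciton Hamiltonian

One amide I oscillator per backbone carbonyl: every residue contributes its
own C=O (the C-terminal residue's carbonyl belongs to the terminal acid or
amide group) plus one for an acetyl cap — 36 for the relay helix peptide.
Whether the published 36 counts the terminal acid carbonyl or a side-chain
amide is not derivable from the count alone; this rule reproduces 36 and is
fixed as the package convention.

The site map is deliberately simple and self-contained, because published
electrostatic map parameter sets are external to this package: site
frequency = 1650 cm⁻¹ + 15 cm⁻¹·(e/nm)⁻¹ × the potential difference
φ(C) − φ(O) generated by fixed backbone partial charges (C +0.42, O −0.42,
N −0.30, H +0.30, OXT −0.42 e), excluding the chromophore's own residue and
its sequence neighbours as sources.  The coefficient was set once to give
an α-helical site-frequency spread of ≈ 12 cm⁻¹, the scale of amide I
inhomogeneity; the map is linear in its sources by construction, and the
`SiteMap` dataclass accepts replacement parameters, extra point charges, or
a zero coefficient (all sites at the base frequency).  Transition dipoles
are 0.37 D, tilted 20° from the C=O axis toward N in the O–C–N plane, at
the C=O midpoint displaced 0.01 nm toward N — conventional amide I
geometry.  Couplings are transition-dipole coupling with the vacuum
constant 5034.12 cm⁻¹·Å³·D⁻² (derived from CODATA constants in
`helixspec.core`), except nearest neighbours, which use a constant −7 cm⁻¹
helical default in place of a dihedral-indexed map.

A bent helix changes this Hamiltonian almost only in the rows and columns
of chromophores near the kink (site shifts up to ~7 cm⁻¹ there).  Entries
between chromophores far from the kink still move by up to ~0.2 cm⁻¹
because the downstream arm is rigidly displaced in the lab frame; exact
invariance of far entries is impossible for any dihedral-based bend, so the
locality property is stated (and tested) as a > 10× contrast between
near-kink and far entries.

## Linear spectra

Two routes, which must agree for a static Hamiltonian: (i) time-domain
propagation of the one-exciton wavefunction along the Hamiltonian
trajectory — per-frame matrix-exponential steps, unitary to machine
precision — with lifetime damping exp(−t/2T) and a direct cosine transform
onto the frequency grid; (ii) a stick spectrum from diagonalization, one
line per eigenmode at E_n with intensity |μ_n|², broadened by the lifetime
Lorentzian.  The damping convention makes the Lorentzian half width
1/(4πcT) ≈ 2.65 cm⁻¹ at the default T = 1 ps (the amide I lifetime is not
fixed by measurement here; 1 ps is the conventional scale and is
configurable).  Orientational averaging is the plain sum over the three lab
axes; no further rotational averaging is applied.  Dipole strength is
conserved under diagonalization to 1e-9 relative, every frame.

Eigenmode diagnostics are computed per frame, binned by eigenenergy, then
time-averaged: inverse participation ratio IPR = 1/Σφ⁴ (1 for a localized
mode, N = 36 for a uniform one), oscillator strength, density of states
(sums to N per frame), and mean squared site components.  Second
derivatives use a Savitzky–Golay filter (default window 11 points, order
3); note that for overlapping bands the second-derivative minima sit inward
of the true band centres — the tests check them against the analytic
second derivative, not against the centres.

## 2D-IR

Purely absorptive spectra are computed from the six double-sided pathways
(ground-state bleach, stimulated emission, excited-state absorption ×
rephasing/nonrephasing) by chaining one-exciton step propagators.
Two-quantum states are perturbative: the basis is the site-pair harmonic
ladder |nm⟩ with a diagonal anharmonic shift Δ on |nn⟩ only and harmonic
dipole scaling.  Δ defaults to 16 cm⁻¹ — inside the 10–20 cm⁻¹ range the
peak fitter scans, since no measured input value is available; it is an
assumption, not a fit.  With Δ = 0 the pathways cancel identically
(verified to 1e-12 relative), and uncoupled oscillators give exactly
additive spectra (no cross-peaks beyond lineshape tails).

Damping is exp(−t/2T) on both coherence intervals and exp(−T_w/T) on the
population interval, so a static system's signal decays exactly as
exp(−T_w/T) with wait time.  Orientational averaging is the isotropic
⟨jjjj⟩ axis sum consistent with the linear response; full four-point
orientational tensors (and polarization-resolved signals) are out of scope.
The frequency-domain transform is a direct DFT onto the requested grid
with cosine apodization on both time axes — equivalent in effect to a
zero-padded FFT but exact on arbitrary grids and free of grid-matching
bookkeeping.

Cost: the pathway sweep advances all pending two-exciton vectors through a
shared per-step propagator, so the number of 666×666 diagonalizations
grows linearly (not quadratically) in the scan lengths; N = 36 with
t₁ = t₃ = 1.5 ps on a static frame takes ~3 s on one CPU, and a 2000-frame
fluctuating trajectory stays within minutes.

## Peak-volume fitting

2D-IR snapshots are fit by four tilted-Gaussian peak pairs — diagonal low,
diagonal high (tilt fixed 30°), and the two cross-peaks (tilt 0°) — each a
positive lobe plus an equal-magnitude negative lobe displaced down ω_m by
that peak's anharmonicity.  Band positions are shared (one low and one high
frequency); widths, amplitudes and anharmonicities are per-peak.  The
"scanned" parameter ranges are implemented as box constraints with the
documented starting values in a single deterministic bounded least-squares
run (lmfit); two presets cover an experimental-style and a
computed-spectrum-style search space.  Reported volumes are positive-lobe
magnitudes 2π·A·σ_τ·σ_m (the negative lobe is the same magnitude by
construction and is not added or subtracted).  Dropping the cross-peak
terms is a nested model, so its optimal residual can never be lower —
matching how cross-peak presence is argued from residuals.

## Pump-probe and CD observables

The isotropic signal is (S∥ + 2S⊥)/3 pointwise.  Bi-exponential fits
P(t) = A₁e^(−B₁t) + A₂e^(−B₂t) use points with t > 0.5 ps by default,
deterministic initialisation (A₁ = first retained value, B₁ = 1 ps⁻¹,
A₂ = 0.1·A₁, B₂ = 0.1 ps⁻¹), positive-rate bounds, and the ordering
convention B₁ ≥ B₂.  Peak heights for ratio diagnostics are local maxima
within ±3 cm⁻¹ windows, which is robust to grid placement.  The μ⁴/μ²
consistency check is the identity r ↦ r²: pump-probe absorbance scales as
μ⁴ and linear absorbance as μ², so if oscillator strength alone set both,
the pump-probe peak ratio would be the square of the linear one.

Fractional helicity uses the Baldwin relation
f_H = (θ₂₂₂ − θ_C)/(θ_H − θ_C) with θ_C = 2220 − 53T and
θ_H = (−44000 + 250T)(1 − 3/N_r), T in °C.  The grouping of the
finite-length factor over the whole helix baseline is the Baldwin
convention; a switch selects the alternative reading
θ_H = −44000 + 250T(1 − 3/N_r) for sensitivity checks.  Values outside
[0, 1] are clamped and flagged rather than rejected.

## Conformational and free-energy analysis

Hydrogen-bond collective variables are O(i)···H(i+4) distances (an O···N
switch is provided; both conventions are consistent with the 0.21–0.89 nm
CV ranges the free-energy surfaces cover), classified broken above
0.35 nm.  PCA follows the two-pass protocol: rigid fit to the first frame,
average, refit to the average, then eigendecomposition of the coordinate
covariance; pseudo-trajectories sweep the mean structure along one
component between the minimum and maximum projections.

The metadynamics module is a desk-scale surrogate: an overdamped Langevin
walker on an analytic 2D potential, not molecular dynamics.  It exercises
the well-tempered schedule — hills every 500 steps, initial height
1.2 kJ/mol tempered by exp(−V/((γ−1)kT)), width 0.05 nm, bias factor
γ = 6 — at 298.15 K with reflective boundaries.  Three numerical choices
matter and are fixed: (i) the Langevin step (dt = 1e-4 in reduced units,
friction 1) keeps the per-step diffusive kick at ~0.02 nm, small against
the landscape features; (ii) hills are deposited together with their
mirror images across the domain walls, compensating the hill mass a
reflective boundary would otherwise lose and removing the edge inflation
of the free-energy estimate; (iii) the free energy is estimated as
−γ/(γ−1) times the *time-averaged* bias over the second half of the hill
depositions, which suppresses the ripple of the instantaneous bias.  The
calibrated double-well test potential places its Gaussian basins with
σ = (basin distance)/3 so that 0.05 nm hills resolve them — the same
fluctuation-matching rationale used to pick the hill width in the first
place; with narrower basins the hill-width smoothing alone biases the
recovered minima offset by more than the target accuracy.  At the stated
production budget (2×10⁶ steps, ~4000 hills, ≈50 s) the recovered basin
offset of the 3.36 kJ/mol double well is within 0.5 kJ/mol across seeds;
the test suite also runs a quarter-budget qualitative check.

Free-energy grids are analysed by 8-neighbour local minima, pairwise ΔG in
kJ/mol and in kT (kT = RT; 2.479 kJ/mol at the default 298.15 K, so
3.36 kJ/mol ≈ 1.4 kT and 4.67 kJ/mol ≈ 1.9 kT), and saddle estimates by
max-over-min level search (union-find over cells admitted in energy order —
the first level connecting two basins is the saddle).  Surfaces are
reported relative to their global minimum; any absolute offset convention
of an external surface is recorded in the grid's `offset_note`, not
imposed.

## Known limitations

- No solvent, no force field, no thermal conformational ensemble: spectra
  from the synthetic helix probe the exciton machinery, not TFE solution
  behaviour.
- The default site map is a one-parameter electrostatic caricature;
  quantitative frequency maps must be supplied through `SiteMap`.
- Two-quantum states are harmonic-pair perturbative; strong-coupling
  effects on overtone mixing are absent.
- Metadynamics operates on analytic potentials only; nothing here
  reweights or reproduces production molecular-dynamics surfaces.
- The bent-helix construction is geometric; it matches which hydrogen
  bonds are broken, not the crystal-structure bend geometry.
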