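# Methods

## The model

`memelast` implements a coarse-grained, implicit-solvent-free membrane
model of single-tail amphiphiles: each lipid is one head bead followed
by six tail beads.  Reduced units are used throughout — lengths in the
tail-bead diameter σ (written `sigma_LJ` in code), energies in ε,
k_B = 1, so T is in ε/k_B and P in ε/σ³.

Three interaction terms define the Hamiltonian:

* **FENE bonds** between consecutive beads of a chain,
  `V(r) = -(ν_FENE/2) Δr_m² ln[1 - ((r-r0)/Δr_m)²]`,
  with ν_FENE = 100, r0 = 0.7, Δr_m = 0.2.  The potential diverges at
  |r − r0| = Δr_m; any move or rescale that would cross that boundary
  is rejected (moves) or raises (`FeneDomainError`, rescales).
* **Bond-angle stiffness** `V(θ) = ν_ba (1 − cos θ)` with ν_ba = 4.7,
  θ measured as the deviation from collinearity of three consecutive
  beads (θ = 0 ⇒ straight chain), so the term penalises bending.
* **Soft-core pairs** `V_sc(r) = [V_LJ(r) − V_LJ(r_c)] θ(r_c − r)` with
  `V_LJ(r) = ε[(σ/r)¹² − 2(σ/r)⁶]` between all non-bonded bead pairs:
  tail–tail ε=1, σ=1, r_c=2σ (attractive well); head–tail σ=1.05,
  r_c=1σ; head–head, solvent–head and solvent–tail σ=1.1, r_c=1σ
  (purely repulsive, truncated at the LJ minimum).  Solvent–solvent
  pairs do not interact at all: the *phantom solvent* transmits
  pressure to the membrane without any solvent structure, and is an
  exact ideal gas on its own — which we exploit as a barostat oracle.

Heaviside convention: θ(0) = 0, so the interaction vanishes exactly at
r = r_c.  The shift makes the potential continuous there, so the
choice is physically inconsequential but fixed for reproducibility.

Directly bonded pairs are excluded from the soft-core sum (the FENE
term already governs that pair); second and further neighbours along a
chain do interact.  The exclusion is a flag on `ForceFieldParams`.

## Sampling

NPT Metropolis Monte Carlo.  One sweep = one attempted single-bead
displacement per bead (uniform in a cube of side 2·`displacement_max`)
plus one box move per non-fixed axis.  Box moves step uniformly in
ln L of one axis, rescale the coordinates affinely along it, and are
accepted with probability
`min(1, exp{-[ΔU + PΔV − N T ln(V'/V)]/T})`.
With this ln-V sampling measure the phantom gas has ⟨V⟩ = N T/P
exactly, which the test suite and the acceptance script verify at
N = 200 within 5 %.

Periodic boundaries are applied on all three axes.  The lateral axes
are the physically periodic ones; z-periodicity is a modelling choice
that gives the NPT z-moves a defined extent, with the solvent slabs
(default 8 σ per side) keeping the membrane from interacting with its
z-image.

Neighbour search uses linked cells at the bare interaction cutoff
(2 σ); the cell list is relinked on every accepted displacement and
rebuilt on accepted box moves, and boxes too small for three cells per
axis fall back to an all-pairs scan.  The energy is tracked
incrementally and validated against an independent vectorised numpy
implementation (`total_energy`) to 1e−6 ε over hundreds of sweeps;
single-move deltas agree with full recomputation to 1e−9 ε over 1000
random moves.

All randomness flows from one master seed: chunked kernel calls get
child seeds from a numpy `SeedSequence`, so identical settings give a
bit-identical trajectory.  Step-size adaptation toward 40 % acceptance
is available during equilibration only and is frozen in production and
in the Poisson relaxation, because adaptation breaks detailed balance.

"MC step" counts are interpreted as sweeps (one attempted move per
bead), and all protocol lengths (equilibration, anneal bump,
relaxation, burn-in) are configuration values.

## Phases and starting states

Three state points are preset: gel (P=2, T=1.08), fluid (P=1, T=1.3),
interdigitated (P=0.5, T=1.16), each with a thermalisation-bump
temperature (1.2 / 1.4 / 1.3) used briefly after an axial rescale.

Bilayers are built as two leaflets of straight chains on a square
lattice at the phase's equilibrium area per lipid (0.96 / 1.68 /
1.8 σ² — using the measured value shortens equilibration), heads
outward; the interdigitated construction offsets the leaflets by half
a lattice vector and overlaps them so opposing tails interpenetrate
(initial head-plane distance 4.8 σ).  Phantom solvent fills the
remaining volume uniformly at a target number density (default
0.3 σ⁻³, which puts a 64×64-lipid fluid system in the tens of
thousands of solvent beads).  The builder rejects any construction
with an active pair closer than 0.8 σ_pair.

Membrane descriptors, measured at analysis time:

* area per lipid A = L_x L_y / (lipids per leaflet);
* thickness d = distance between the mean head heights of the two
  leaflets, with leaflets assigned per measurement by the sign of the
  head height relative to the instantaneous midplane (a circular mean
  over z, so a bilayer drifting through the periodic boundary is
  handled, and flip-flopped lipids are reassigned);
* mean chain length l̄ = head-to-terminal-tail distance;
* chain order parameter S_z = ⟨(3cos²α − 1)/2⟩ over tail–tail bonds,
  α the bond angle to the z axis.

No published formulas exist for these descriptors in the source
material; the definitions above are the standard ones in the membrane
literature and are fixed here.

## Poisson's ratio by box rescaling

The protocol: from an equilibrated configuration, (1) all coordinates
and the box length along one lateral axis j are multiplied by (1+η);
(2) that axis is held fixed while the remaining axes continue to
fluctuate at constant pressure, briefly at the bumped temperature
(default 400 sweeps) and then at the phase temperature; (3) the
transverse traces ν_ij(t) = −(L_i(t) − L_i(0))/(η L_i(0)) are averaged
from a burn-in (default 5000 sweeps, where the traces have visibly
plateaued) to the end, with block-averaged standard errors.  L_i(0) is
the mean over the last quarter of the pre-strain run, not an
instantaneous value, to reduce baseline noise.  A linear-slope check
over the averaging window (drift below one standard error) flags
non-converged runs.

Rescaling along z is forbidden by the API: the z extension would have
to stretch intramolecular bonds, which breaks them.  The z response is
instead reported both from the box length L_z (which is dominated by
the solvent slab) and from the membrane thickness d; discrepancies
between the two are surfaced, not hidden.

Default η = 0.05.  η must be large enough to open free volume for
rearrangement and small enough not to damage the membrane;
`max_admissible_strain` reports the FENE-safe bound for a
configuration, and estimates at η and 2η should agree within errors
(checked on the oracle lattice).

**Protocol oracle.**  Because the protocol only uses box lengths, it is
agnostic to the microscopic model.  We exercise the complete machinery
on a periodic 2-D triangular lattice of central-force harmonic springs
(nodes typed as phantom beads so no pair terms act), whose continuum
Poisson's ratio is exactly 1/3.  An independent zero-temperature
oracle minimises the spring energy over node positions and the
transverse box length under the imposed strain.  The MC protocol at
T = 0.1, P = 0, spring stiffness 100 on an 8×8 lattice reproduces
1/3 within 0.05 (slightly below, from finite-strain corrections and
the entropic N T ln V term acting as a small effective tension).

## Bending rigidity from the undulation spectrum

The membrane height h(x, y) is gridded at 2 σ spacing: per cell, the
mean head height of each leaflet is taken, h = (z₊ + z₋)/2, and the
grid mean is subtracted.  Cells left empty by a leaflet are filled by
iterated 4-neighbour averaging; more than 10 % empty cells raises (a
ruptured membrane or too fine a grid).

The discrete Fourier transform is normalised by the cell area so the
continuum Monge-gauge Helfrich prediction

    ⟨|ĥ(q)|²⟩ = k_B T L² / (k_c q⁴ + σ q²)

holds without extra factors; Parseval's identity between real-space
variance and total spectral power is exact to 1e−10 and is asserted in
the tests (this fixes the normalisation convention unambiguously).
Mode powers are radially binned (width 2π/max(L_x, L_y)) and fitted by
ordinary least squares in the linearised form
`k_B T L²/(⟨|ĥ|²⟩ q²) = k_c q² + σ` over 0.5 ≤ q² ≤ 1 — the window
where neither the finite box (q ≫ 2π/L) nor bead discreteness
(q ≪ 2π/σ) distorts the spectrum at feasible sizes.  Fits with
k_c ≤ 0, zero-power modes in the window, or fewer than 10 frames are
flagged, never silently returned.

**Spectrum oracle.**  `make_helfrich_ensemble` draws i.i.d. frames
whose mode amplitudes have exactly the Helfrich variance (white
real-space Gaussian noise, Fourier-filtered by √S(q); Hermitian
symmetry comes free, so frames are real to machine precision).  On 500
tensionless frames at a 64×64 grid the fit recovers k_c within 10 %
per run and within 3 % on average over 20 repetitions, for k_c in
{5.2, 7.6, 10.56} — the per-phase rigidities.  The fitted tension on
tensionless ensembles is zero within its standard error.

## Young's modulus

Thin-plate theory for an isotropic plate links the measured constants:

    k_c = E d³ / [12 (1 − ν²)]   ⇔   E = 12 k_c (1 − ν²) / d³.

`phase_report` applies it only when the membrane is in-plane isotropic,
operationalised as |ν_xy − ν_yx| ≤ 2 × combined standard error
(threshold configurable); for anisotropic phases (the gel, whose
tilted chains break in-plane symmetry) E is withheld.  ν entering the
relation is the mean of ν_xy and ν_yx, and d is the mean thickness of
the spectrum run.  With the per-phase inputs (k_c = 5.2, ν = 0.50,
d = 5.48) and (k_c = 7.6, ν = 0.395, d = 4.86) the relation gives
E = 0.28 and 0.67 ε/σ³ for the fluid and interdigitated phases.

## Problem sizes

Full-scale production runs (64×64 lipids per leaflet for spectra,
12×24 for the Poisson protocol, ~2×10⁶ equilibration sweeps) are
supported through the run configuration but are cluster-scale jobs.
The shipped tests and the acceptance script run the same pipeline at
desk scale, a deliberate choice so every stage is exercised end to end
in minutes: an 8×8-lipid fluid bilayer over 2×10⁴ sweeps (which
remains intact, with fluid-like descriptors: l̄ ≈ 3.3, d ≈ 5.9,
A ≈ 1.55, S_z ≈ 0.25 after 2×10⁴ sweeps — still drifting slowly
toward the full-scale equilibrium), the 200-bead phantom gas, the
8×8 spring lattice, and 500-frame synthetic spectra.

## What the synthetic generators do and do not show

The Helfrich sampler draws *uncorrelated* frames from the exact target
distribution: it validates the gridding/FFT/fit chain, but says
nothing about equilibration or frame correlation of real
trajectories (production spectra should be sampled at a stride of
~100 sweeps, configurable).  The spring lattice validates the
strain-relax-average protocol and its error bars, but is a harmonic,
solvent-free, 2-D system: it does not probe leaflet reorganisation,
tilt anisotropy, or the solvent-dominated L_z response of real
bilayers.  The phantom gas validates the barostat acceptance rule
only.  Reduced-scale bilayer runs demonstrate stability and
qualitative fluid-phase behaviour, not converged Table-quality
descriptors: small boxes suppress long-wavelength undulations and
shift A, d, S_z relative to the 64×64 system.

## Numerical choices and known limitations

* Cosines are clamped to [−1, 1] before bond-angle evaluation.
* A broken FENE bond inside the kernel is signalled by a sentinel
  energy (1e30), which rejects the move; it never silently continues.
* Tie-break at the cutoff: strict `r < r_c` (θ(0) = 0).
* The gel phase's chain tilt direction relative to the box axes is not
  controlled by the builder; gel-phase anisotropy measurements
  (ν_xy ≠ ν_yx) depend on that orientation and need care at
  production scale.
* The spectrum fit assumes decorrelated frames; no autocorrelation
  correction is applied to its standard errors.
* No configurational-bias regrowth or collective moves: relaxation of
  deep gel states is slow, and full phase-diagram work at 64×64 scale
  needs the printed ~2×10⁶-sweep budgets.
* The package models neither electrostatics, nor double-tail lipids,
  nor explicit solvent; the finite-thickness elastic theory for
  protrusion/thickness modes is out of scope.

## Repository shape

The package is organised as a simulation tool (builder → engine →
protocol → analysis) with a thin `memelast` CLI, rather than as a
single fitted-model object: the one genuine model fit in the pipeline
(the Helfrich spectrum) returns a results object (`SpectrumFit`) with
estimates, standard errors and a `summary()`, in the spirit of the
statistical-modelling packages.
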