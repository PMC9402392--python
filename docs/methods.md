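# Methods

## Model

The package implements a two-basin native-centric (Gō-type) model at
Cα resolution.  A single reference chain is observed in two
conformations, *open* and *closed*; the potential encodes both.

**Energy function.**

```
E = Σ_bonds K_r (r − r0)²
  + Σ_angles K_θ (θ − θ0)²
  + Σ_dihedrals Σ_{n=1,3} K_φ(n) (1 − cos n(φ − φ0))
  + Σ_common ε_DG ([1 + (σ_NC/r)¹²][1 + G(r, r₁)][1 + G(r, r₂)] − 1)
  + Σ_open-specific  ε_OS (5(σ/r)¹² − 6(σ/r)¹⁰)
  + Σ_closed-specific ε_CS (5(σ/r)¹² − 6(σ/r)¹⁰)
  + Σ_non-contact ε₄ (σ_NC/r)¹²,     G(r, rₙ) = −exp(−(r − rₙ)²/2σ_g²)
```

Native bonded values (r0, θ0, φ0) come from the open-state structure.
The dual-Gaussian term multiplies a repulsive core by two inverted
Gaussians, so each common contact has minima of depth exactly ε_DG at
both native distances r₁ (open) and r₂ (closed); this removes the
repulsive shoulder a Lennard-Jones form would put between the two
minima when r₂ < r₁.  State-specific contacts use the 10–12 form whose
minimum is exactly −ε at r = σ.  Dihedrals use the signed IUPAC
convention in (−π, π]; periodicity is handled through the cosine.

**Units and defaults.** Lengths in nm, energies in ε = 1 kJ/mol,
temperature on a reduced scale with k_B = 0.008314 (T = 100 means
k_BT = 0.8314 ε).  K_r = 100 ε/nm², K_θ = 20 ε/rad², K_φ(1) = 1,
K_φ(3) = 0.5, ε_DG = 1, ε₄ = ε = 1, σ_NC = 0.4 nm, σ_g = 0.05 nm.
ε_OS = 1 is held fixed; ε_CS is the calibration knob (see below).
Open-specific contacts that involve the C-terminal helix region are
additionally multiplied by `cth_scale` — the single parameter probing
how strongly the tail grips the open state.

**Contact detection and classification.** Contacts are detected
independently in each conformer; default detection marks residue pairs
(sequence separation ≥ 4) with any heavy-atom pair within 0.45 nm.
This is a surface-proximity stand-in for atom-typed contact software;
the cutoff is configurable (0.40–0.50 nm is the sensible band) and is
recorded in the contact map's parameter block.  A pure Cα-distance mode
exists for Cα-only inputs.  Classification: detected in both states →
*common*; detected in exactly one state → *state-specific* if the
distance in the other state exceeds 1.5× (strictly) the in-state
distance, otherwise *discarded* — reported but excluded from the
potential, where the pair falls back to excluded volume.  Distances
entering the potential are always Cα–Cα distances in the native
structures, even under all-atom detection, because the model is
Cα-resolution.  Sequence separations ≤ 3 are the bonded terms' domain
and are excluded from all non-bonded sums.

**Dynamics.** Langevin dynamics via the BAOAB splitting: half-kick,
half-drift, Ornstein–Uhlenbeck velocity refresh
(c₁ = e^{−γΔt}, c₂ = √((1−c₁²)k_BT/m)), half-drift, half-kick.  With
γ = 0 the refresh is skipped and the scheme is velocity Verlet (NVE).
Defaults: Δt = 0.0005, γ = 1 (reduced time⁻¹), m = 1 per bead (masses
only set the time scale in a Cα model; the mapping to physical time is
not defined, so transition counts are comparable between runs of this
package, not to wall-clock rates).  Velocities are initialized
Maxwell–Boltzmann from the run seed (PCG64); trajectories are exactly
reproducible from seed + inputs.  Frames and an energy/temperature log
are saved every 2000 steps by default.

**ε_CS calibration.** With ε_OS fixed, ε_CS is scanned along an
ascending grid; each grid point gets one seeded simulation started from
the open native state.  The chosen value is the smallest whose
trajectory shows at least `min_transitions` committed transitions with
both basin populations inside `population_window`.  At production scale
the conventional demand is ≥ 50 transitions with near-equal basins
([0.4, 0.6]); test-scale runs use ≥ 2 transitions and [0.2, 0.8] over
2×10⁶ steps, which this package's synthetic system satisfies around
ε_CS ≈ 0.8–1.0.  The scan report (per-point transition counts and
populations) is always returned; if no point qualifies the failure
carries the full report.

**Analysis.** The reaction coordinate is a Cα–Cα distance between one
residue per lobe (56–143 for TmArgBP: ~2.2 nm open, ~0.7 nm closed; the
generator suggests its own pair).  Free-energy profiles are Boltzmann
inversions F(d) = −k_BT ln P(d) over 50 bins by default, min-shifted to
zero; empty bins are omitted, not smoothed.  State assignment is
hysteretic — commit to open above the open threshold, to closed below
the closed threshold, keep the previous committed state in between — so
single-surface recrossings do not inflate transition counts.  Default
thresholds sit at the midpoint of the two native distances ± 25 % of
their gap.  Salt-bridge analysis (for all-atom trajectories) reports
the closest acidic-oxygen (OD1/OD2/OE1/OE2) to basic-nitrogen
(NZ/NH1/NH2/NE, optionally histidine ND1/NE2) distance with a 0.5 nm
formation cutoff; Cα-only input is refused.

## Synthetic two-state protein

The generator emulates the architecture the model targets: a fixed lobe
(14 beads, helical), a mobile lobe (14 beads, helical) attached through
two hinge pivots on a common axis, and a 6-bead C-terminal tail that
touches the mobile lobe only in the open pose.  The closed pose rotates
the mobile segment rigidly about the pivot axis by 100°, giving an
all-bead open/closed RMSD ≈ 0.76 nm.  Contact classes are therefore
known by construction: intra-segment pairs keep their distances
(common), fixed-lobe × mobile-lobe pairs touch only when closed,
tail × mobile-lobe pairs only when open.  Contact planting uses
Cα-cutoff detection at 0.8 nm (the beads have no side chains; the
all-atom detection path is exercised by the salt-bridge fixture
instead).

Geometric choices that matter:

* hinge ramps leave the rotation axis **tangentially** (circular arcs),
  so beads adjacent to the pivots barely move between poses and the
  closed conformer costs only ~4–5 ε of bonded strain in a model whose
  bonded terms come from the open reference — small enough for thermal
  interconversion at k_BT = 0.83 ε;
* every ramp and the tail zigzag laterally by ±0.055 nm so no native
  bend angle comes near 180°, where the angle potential's gradient is
  singular (a straight ramp produced exactly that pathology: energy
  injection at collinear crossings);
* consecutive beads are 0.38 nm apart (Cα virtual bond), non-bonded
  pairs (separation ≥ 4) stay ≥ 0.35 nm in both poses, enforced with a
  retry-then-fail loop over jittered rebuilds (positional jitter
  0.004 nm from the seed).

What the toy does **not** emulate: side chains and packing anisotropy,
real secondary-structure geometry, contact-order heterogeneity of a
230-residue protein, and solvent effects.  Tests passing on the toy
show the machinery (detection, classification, potential, integrator,
analysis) is correct and that the dual-basin construction produces
two-state kinetics at this scale; they do not certify quantitative
agreement with any particular crystal-structure system, which is what
the accession-based regression (contact counts 528/14/33 and 558/27/35
for the truncated and grafted TmArgBP constructs) is for when the PDB
entries are available locally.

## Numerical choices

* Excluded volume is truncated **and shifted** at 2.5 nm; the unshifted
  term there is (0.4/2.5)¹² ≈ 2.8×10⁻¹⁰ ε, and shifting keeps E
  continuous so analytic forces match finite differences everywhere.
* Kernel inner loops (numba) are fully scalarized; a dynamics step on
  the 56-bead toy costs ~15 µs on one CPU, so the 10⁶–10⁷-step test
  runs finish in seconds to minutes.  Simulation lengths in the tests
  (10⁵ NVE, 10⁶ thermostat, 2–3×10⁶ per scan/series point) were chosen
  as the smallest sizes at which the measured statistics are stable.
* NVE conservation is judged from the first saved frame onward: a
  symplectic integrator conserves a shadow Hamiltonian offset O(Δt²)
  from the true energy (~1.4×10⁻³ ε at Δt = 5×10⁻⁴ here), so the
  constant offset is not drift; the measured post-offset drift is
  < 10⁻³ ε over 10⁵ steps.
* Kabsch superposition uses SVD with the determinant sign correction;
  the angle force clamps sin θ at 10⁻⁸ and the dihedral force clamps
  |n|² at 10⁻¹² (native geometries keep angles ≤ ~163°, so the clamps
  are dormant safety rails).
* PDB I/O converts Å↔nm at the boundary; author residue numbering is
  preserved end-to-end, first altloc kept, hydrogens dropped.
  Construct-to-construct numbering differences (e.g. an engineered
  insertion) are bridged by pairwise sequence alignment
  (`map_numbering`) before cross-structure comparisons.

## Open design points, resolved

* The residue set for the whole-chain RMSD after lobe-2 alignment is
  unstated in the source structures' literature; all shared residues
  are used.
* Structural superposition is residue-matched Kabsch on Cα atoms (the
  alternative, sequence-independent structural alignment, is
  unnecessary when author numbering already matches).
* Whether pairs detected in both states should also face the 1.5×
  ratio test: no — both-state detection is taken as *common* directly;
  the ratio rule only ratifies single-state detections.
* The generator's hinge angle is restricted to (20°, 120°); a 0° hinge
  would make the two states identical and is rejected rather than
  special-cased, since a one-state system has no transition to study.

## Known limitations

* No physical time mapping: friction and masses are reduced, so rates
  are internal currency only.
* The excluded-volume sum is a precomputed pair list without a spatial
  neighbor search; fine up to a few hundred beads, quadratic beyond.
* The GROMACS-dialect export writes a documented pairs dialect for the
  Gaussian contacts; it is an interchange format, not a tested drop-in
  for any specific engine version.
* Salt-bridge analysis requires side-chain atoms; it deliberately
  refuses Cα-only models rather than approximating charged-center
  positions from backbone geometry.
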