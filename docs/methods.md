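# Model and methods

`torquefold` simulates short alpha-helical peptides under an external
"folding machine": a mechanical apparatus that continuously rotates the
C-terminal residue about the chain axis while restraining both termini,
so that folding is driven by injected mechanical work rather than by
thermal search alone. This note documents the model, its parameters, the
calibration that fixed the defaults, and what the simulator does and does
not capture.

## Coarse-grained representation

Each residue carries five interaction sites: the backbone heavy atoms N,
CA, C, O and a single side-chain bead CB placed at the beta-carbon
position and carrying the whole side-chain mass (glycine has no CB).
This is the smallest representation that preserves

* the phi/psi/omega backbone dihedrals (and hence Ramachandran
  kinematics),
* carbonyl-based i -> i+4 hydrogen bonding, and
* side-chain sterics, including the chirality of L-amino acids (the CB
  site is placed on the L branch).

Units are GROMACS-style throughout: nm, ps, amu, kJ/mol; with these
choices 1 amu nm^2/ps^2 = 1 kJ/mol and no conversion factors appear.

## Potential energy

Five terms, each with analytic forces validated against a
central-difference oracle to < 1e-5 relative error:

1. **Bonds and angles** — harmonic, at conventional peptide equilibrium
   geometry (N-CA 0.1458 nm, CA-C 0.1525 nm, C-N 0.1329 nm, C=O
   0.1231 nm); `k_bond` = 20000 kJ/mol/nm^2, `k_angle` = 250 kJ/mol/rad^2.
   The chain builders generate coordinates exactly at these values, so a
   freshly built structure has zero bonded energy.
2. **Omega planarity** — harmonic in the wrapped deviation from 180
   degrees, `k_omega` = 80 kJ/mol/rad^2 (trans peptide bonds only; cis
   isomers are outside scope).
3. **Torsion surface** per residue:
   * a Gaussian *helix basin* at (phi, psi) = (-57, -47) degrees of depth
     `eps_helix * w_r` (10 kJ/mol for alanine) and width `sigma_basin` =
     38 degrees, where `w_r` is a per-residue helix-propensity weight
     (Ala 1.0 ... Pro 0.35, Gly 0.30) in the spirit of the experimental
     helix scales;
   * a *3-fold rotation barrier* `torsion_barrier3` = 22 kJ/mol with
     maxima at 0 and +/-120 degrees, the coarse-grained analogue of the
     sp3 rotation barrier. This term is load-bearing: it is what makes
     backbone twisting ratchet-like (see "Why the machine works" below);
   * a weak *trans bias* (1 kJ/mol) favouring the extended state.
4. **Hydrogen bonds** — a Gaussian attraction of depth `eps_hb` =
   22 kJ/mol between O_i and N_{i+4} centred at the canonical helical
   O...N distance 0.29 nm. The width `hb_sigma` = 0.12 nm is deliberately
   much wider than a real hydrogen bond: the long tail lets a *forming*
   bond reach across the transition state of the torsion that would
   complete it, which is essential for capture during machine-driven
   zipping (see calibration). The cost is a mild nonspecific compaction
   tendency, acceptable because compact coil states remain far above the
   0.2 nm folding threshold.
5. **Excluded volume** — purely repulsive truncated-and-shifted r^-12
   between all atom pairs more than two bonds apart, with per-role radii
   (contact distance = sum of radii) and cutoff at 1.5x contact. The
   radii are chosen so that the ideal helix and the extended chain are
   nearly strain-free while the eclipsed backbone configurations remain
   strongly forbidden: rotating a phi torsion through 0 degrees costs
   hundreds of kJ/mol (backbone carbonyl carbons collide), which is the
   steric wall that makes the two rotation directions inequivalent.

No electrostatics, no attractive dispersion, no solvent structure: the
implicit solvent (Langevin friction) absorbs them.

## The machine

All constants follow the published protocol: enforced rotation of every
atom of the C-terminal residue about the +X axis at 60 degrees/ps with
force constant 1500 kJ/mol/nm^2; YZ-plane restraints (10000 kJ/mol/nm^2)
on the C-terminal O and N (the residue may slide along the axis); a weak
X restraint (5 kJ/mol/nm^2) on the C-terminal O; full positional
restraints (10000 kJ/mol/nm^2) on the N-terminal N and CA. Anchors are
the atom positions at protocol start; the builders place the chain along
+X, so the anchors lie near the axis.

The rotation term is the flexible-axis enforced-rotation potential in its
single-slab limit: one centroid, one co-moving rotating reference. The
rotation group here is a single residue spanning well under half a
nanometre along the axis, for which the multi-slab machinery is
degenerate; the single-slab form preserves the defining properties —
torque about the axis, exactly zero force along the axis, zero net force
on the group, and a pivot-free (centroid-following) reference. Torque is
reported from the rotation forces only, and driver work is accumulated
every step as torque x signed angular rate x dt.

**Handedness convention.** "Clockwise" labels the productive direction:
the sense that winds the backbone into the right-handed helix. With the
chain built N -> C along +X, that is the right-hand-rule (+1) sense about
+X — clockwise when viewed from the N-terminal anchor looking along the
axis toward the driven C terminus. The sign is recorded in the config
(`machine.clockwise_sign`) so the convention is explicit in every saved
run.

## Dynamics

Implicit-solvent Langevin dynamics with the BAOAB splitting, dt =
0.002 ps, friction γ = 0.5 ps^-1, T = 300 K. BAOAB was chosen for its
accurate configurational sampling at finite dt; the NVE limit (γ = 0, no
noise) conserves energy to < 1e-4 relative drift over 1e5 steps on a
harmonic test system, and the thermostat holds the peptide's mean kinetic
temperature within 3% of 300 K. γ = 0.5 ps^-1 is lower than a
water-viscosity value; it was fixed during the calibration below because
the machine's fixed 60 degrees/ps drive rate demands conformational
relaxation fast enough to capture forced torsion hops, and because the
qualitative claims tested here are orderings between conditions, not
absolute times. One seeded random stream per run (velocity
initialisation, then per-step noise in fixed atom order) makes
trajectories bitwise reproducible; the compiled inner loop reproduces the
reference pure-Python BAOAB step exactly.

There are no constraints (no rigid bonds); the config validator warns
when dt sqrt(k_bond/m) exceeds a stability bound.

## Analysis definitions

* **RMSD** — Kabsch least-squares superposition (proper rotation
  enforced) over the backbone N, CA, C, O atoms of the core residues;
  the two alanine handles at each end receive the machine forces and are
  never scored.
* **Folding time** — first passage of the core RMSD at or below 0.2 nm
  against the native reference (by default the internally built ideal
  helix at phi = -57, psi = -47; a PDB fragment may be supplied instead).
  Non-folding runs are reported with the `t/duration` convention in which
  equal numbers mean folding was not observed.
* **Helicity** — fraction of interior core residues whose (phi, psi) lie
  within 30 degrees (wrapped Euclidean) of the helix angles.
* **Winding** — per-residue cumulative azimuth of CA about the axis
  through the N-terminal CA along +X, unwrapped over frames. Frames must
  be dense enough that increments stay below 180 degrees (at the default
  1 ps reporting interval the driven end advances at most 60 degrees per
  frame).

## Why the machine works here, and the calibration

An end-applied torque on a floppy chain is mostly absorbed by free
rotation of the nearest soft torsions — the freely-jointed-chain picture.
Three ingredients turn it into a productive ratchet:

1. the 3-fold torsion barrier gives every phi/psi a discrete set of
   wells; a torsion forced over the -120 degree barrier lands in the well
   containing the helix angles and, because the next barrier in line (the
   eclipsed configuration near 0 degrees) is sterically impassable for
   phi, it stops there — the remaining twist must propagate to the next
   residue;
2. the wide hydrogen-bond attraction tilts the barrier of exactly the
   torsion whose hop completes an i -> i+4 contact, so zipping at the
   helix/coil frontier is easier than fruitless spinning at the chain
   end;
3. the already-helical C-terminal segment is stiffened by its hydrogen
   bonds and transmits the torque like a driveshaft, co-rotating about
   the axis and delivering twist to the frontier.

Reversing the rotation drives every torsion toward the eclipsed wall and
the mirror-image (left-handed) region, which the basin does not reward
and the CB sterics resist: the counterclockwise machine injects the same
work but folds nothing.

The defaults were calibrated once on the alanine-rich 19-mer (P1 with
handles, 115 atoms) and frozen: under the clockwise machine the peptide
reaches 0.2 nm core RMSD typically within 400–700 ps (4–5 of 5 seeds
within the 800 ps driven budget), while unassisted and restrained-only
runs given four times the budget, and counterclockwise runs given the
same budget, essentially never do (their RMSD plateaus near 0.3–0.7 nm).
The driven budget of 800 ps and control budget of 3200 ps are the
package's standard problem sizes for the four-condition experiment and
preserve the published design's control-to-driven budget ratio in spirit;
they correspond to 4e5 and 1.6e6 integration steps.

## What the synthetic conditions do and do not show

The starting structures are ideal stretched chains on the axis and the
native references are ideal helices built from the same internal
geometry. Real peptides start from equilibrated solvated ensembles, have
sequence-specific side-chain packing, electrostatics and solvent
friction ~2x higher, and their native fragments deviate from ideal helix
geometry. Consequently passing the directional-asymmetry and winding
checks demonstrates the *mechanism* — directional, energy-dependent
folding driven by backbone torque with terminal restraints, and torque
propagation that violates the freely-jointed-chain idealisation — at
coarse-grained scale. It does not reproduce atomistic folding times (the
published driven times are tens to hundreds of nanoseconds of explicit-
solvent dynamics), nor sequence-resolution effects beyond the
helix-propensity weighting (e.g. the partial refolding of the
glycine-containing coiled-coil fragment is outside what five sites per
residue can resolve quantitatively).

## Numerical choices and degenerate inputs

* Dihedral gradients use the standard four-atom formulas; near-collinear
  bond geometries are regularised at |n|^2 >= 1e-14 (never reached at
  equilibrium bond angles).
* The repulsion pair list is a Verlet list with 0.25 nm skin rebuilt on a
  maximum-displacement criterion; energies are identical to the full
  O(N^2) sum.
* Kabsch superposition refuses selections with fewer than 3 points or
  collinear geometry; the identity RMSD is zero to ~1e-8 nm (SVD
  round-off).
* Glycine's missing CB simply drops the CB-related bonded and steric
  terms; a single-residue chain has no defined phi/psi and hence no
  torsion-surface energy.
* The winding of the anchor residue itself is undefined (it sits on the
  axis) and is reported as zero.

## Known limitations

* One rotation rate (60 degrees/ps) has been characterised; the rate is
  a first-class config parameter but slower rates need proportionally
  longer budgets.
* No electrostatics or salt; charged sequences (P3, P5) are treated by
  helix propensity and sterics only.
* The restrained-ends condition shares anchors with the driven
  conditions; anchor positions away from the axis are untested.
* First-passage folding detection uses a strict first crossing with no
  dwell requirement; a sustained-occupancy variant can be layered on the
  RMSD series but is not the default.
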