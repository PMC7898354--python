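# torquefold

Coarse-grained molecular dynamics of short alpha-helical peptides under a
mechanical "protein folding machine": an enforced-rotation potential spins
the C-terminal residue about the chain axis while both termini are
restrained, and folding is scored as the first passage of the core
backbone RMSD below 0.2 nm from the native helix.

The package is for computational structural biologists who want a
desk-scale testbed for *energy-dependent* folding: instead of waiting for
thermal search to find the native state, mechanical work is injected at
one end of the chain and its propagation along the backbone is measured.
The central result it reproduces, as a property of the model rather than
a number: rotating the C-terminus in the *clockwise* sense (looking down
the chain axis from the anchored N-terminal side) folds an alanine-rich
peptide into its right-handed alpha helix within the driven budget, while
the identical protocol run counterclockwise, or no protocol at all with
several times the budget, does not.

## Model in brief

Five sites per residue (N, CA, C, O, CB; no CB for glycine). Potential
terms: harmonic bonds/angles and omega planarity; a per-residue torsion
surface with a Gaussian helix basin at (phi, psi) = (-57°, -47°) weighted
by helix propensity, a 3-fold rotation barrier, and a weak trans bias;
a Gaussian O_i···N_{i+4} hydrogen-bond attraction; and truncated r^-12
sterics. Dynamics are Langevin (BAOAB, dt = 0.002 ps, 300 K). The
machine applies the published constants: rotation at 60 degrees/ps with
k = 1500 kJ/mol/nm², YZ-plane restraints of 10000 kJ/mol/nm² on the
C-terminal O and N, 5 kJ/mol/nm² on the C-terminal O along X, and
10000 kJ/mol/nm² on the N-terminal N and CA in all directions. Two
alanine "handle" residues are appended at each end to receive the
machine forces; handles never enter the RMSD. See `docs/methods.md` for
the full model description and the calibration of the defaults.

Five study peptides are built in (P1–P5: the designed Fs peptide and
three-helix-bundle helix, and fragments of Kv7.1, villin HP35, and
pyrin), each run under four conditions — `free`, `restrained`, `cw`,
`ccw` — with replicate management and summary tables in the
`t/duration` convention (equal numbers = folding not observed).

## Worked example

Run the Fs peptide (P1, `AAAA(AAARA)3`, 19 residues + 4 handle alanines)
under the clockwise machine for 800 ps:

```sh
$ fold run --peptide P1 --condition cw --duration-ps 800 --seed 104 --out-dir runs/p1_cw
P1 cw seed=104: folded at 433 ps (final RMSD 0.083 nm) -> 433/800
```

The peptide starts as a stretched chain on the X axis (core RMSD to the
ideal helix 1.16 nm), winds up from the driven end, and first touches the
0.2 nm folding threshold at 433 ps; the cell string `433/800` is the
report-table entry (first passage / run duration). The same seed under
`--condition ccw` prints `800/800` — the counter-rotated machine injects
comparable work but never folds the chain. The run directory contains
`rmsd.tsv` (time vs core RMSD), `driver.tsv` (reference angle, torque,
accumulated work), `traj.xyz` (frames, comment line = time in ps), the
run's `result.json`, and the resolved `config.yaml`.

The full published design — 5 peptides x 4 conditions x 3 replicates =
60 runs — is `fold plan` (hours of CPU); `fold report` rebuilds the
summary table from a results directory and `fold analyze` applies the
first-passage detector to any stored RMSD series.

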