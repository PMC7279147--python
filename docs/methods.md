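# Methods

This note documents the models implemented in `imotif_md`, the choices
made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## System model

A system is split into a static `Topology` (per-atom element, partial
charge q in e, Lennard-Jones ε in kJ/mol and σ in Å, hard-sphere radius,
molecule id and class, donor/acceptor/polar-hydrogen flags, covalent
bonds) and a dynamic `Trajectory` of frames (positions in Å, orthorhombic
box edge lengths, time in ns). Molecule classes are the species of the
nanotube/DNA/ligand constructs: `iM` (cytosine-rich DNA, coil or folded
i-motif), `DOX` (doxorubicin, cationic), `CNT` (nanotube carbons), `Gu`
(guanine functional groups), `WATER`, `ION`, `OTHER`.

Coordinates are stored unwrapped per molecule — a molecule never straddles
the periodic boundary inside a frame, because centres of mass and RMSD are
ill-defined on split molecules. `unwrap_molecules` enforces this on
ingest; it anchors each molecule at its first atom and is valid for
molecules smaller than half the box edge, which holds for every system
this package targets. Internally all indexing is 0-based; 1-based atom
ids appear only at file boundaries.

## Nonbonded pair energies

Group–group energies sum `4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] + k_e q_i q_j/r`
over atom pairs with minimum-image distance ≤ cutoff (12 Å default),
with Lorentz–Berthelot mixing (`ε_ij = √(ε_i ε_j)`,
`σ_ij = (σ_i+σ_j)/2`) and `k_e = 1389.35458 kJ Å mol⁻¹ e⁻²`. Truncation
is sharp: no shift, no switching, no tail correction, and no
reciprocal-space (mesh Ewald) term. The reciprocal-space part of a
production electrostatics solver cannot be decomposed into group pairs,
so only the real-space sum is meaningful per pair of groups; absolute
agreement with mesh-Ewald totals is therefore out of scope by design.
No intramolecular exclusions (1-2/1-3/1-4) are applied because every
reported energy is between distinct molecules or groups. Tables in the
amber Rmin/2 convention are converted on ingest
(`σ = 2·(Rmin/2)/2^{1/6}`).

Selections passed to `pair_energy` must be disjoint (overlap is an
error), and any interatomic distance below 0.1 Å aborts as a clash —
almost always a unit mistake. The implementation is vectorized NumPy
with round-based minimum image (exact for orthorhombic boxes); the test
suite checks it against an independent 27-image brute-force double loop
to 1e-9 relative on random systems. Group order is canonicalized
internally so `E(A,B)` and `E(B,A)` are bit-identical.

Windowed means follow the production convention of averaging over the
trailing 10.8 ns of a run; the window length is a parameter everywhere.

## Contact clustering

Two molecules are in contact when any pair of their atoms (hydrogens
included — the criterion is "at least two atoms", with no exclusions)
is closer than the cutoff, strictly: 3.5 Å by default. Clusters are
connected components of the molecule contact graph (single linkage, via
`scipy.sparse.csgraph`). The default excluded classes are CNT, Gu, DOX,
WATER and ION, so the partition describes the DNA arrangement only.
Labels are deterministic (each cluster is named by its smallest molecule
id). Because a fluctuating aggregate has no single well-defined count,
the time-series summary reports min/max/mode and the terminal-frame
value, supporting "4–5 clusters"-style statements.

## Hydrogen bonds

A bond is a (donor, hydrogen, acceptor) triple; the same donor–acceptor
pair through a different hydrogen is a different bond. Gates: donor
heavy atom to acceptor heavy atom distance < 3 Å, and the D–H···A angle
within 20° of linearity (∠DHA > 160°). The angle vertex is not
universal in the literature, so the alternative convention
(∠HDA ≤ 20°) is available behind `angle_convention="hda"`. Donors
flagged without a bonded polar hydrogen are skipped with a warning, not
an error. Occupancy is the exact fraction of window frames in which the
geometry holds. Reporting follows two conventions side by side: the
count of all bonds observed at least once and the count above a 10%
occupancy floor (both are emitted, since either may be meant by a
"number of hydrogen bonds" figure), plus per-ligand normalisation of
totals (exact division, e.g. 34 bonds over four ligands → 8.5). Both
donor→acceptor directions are analysed and unioned by default in the
pipeline and CLI.

## RMSD

`kabsch_align` removes the (mass-weighted) centres of mass, finds the
optimal proper rotation by SVD with reflection correction
(det = +1 enforced), and returns the minimal weighted RMSD. Collinear
references are rejected (the rotation about the line is undefined).
Mass weighting is the default — COM subtraction implies a mass-weighted
frame — with an unweighted flag. Series are computed against the first
frame of the analysis window in three styles: `all`, `exclude-DOX`
(ligand atoms removed; flattening of this series relative to `all`
shows the ligands dominate the apparent motion) and `cnt-dox` (the
nanotube + ligand subsystem). The test suite cross-checks against an
independent quaternion-eigenvalue oracle and MDAnalysis.

## SASA

Shrake–Rupley with a deterministic golden-spiral point lattice
(960 points per atom by default; the 240/960/3840 ladder is used in a
convergence test). A point on atom i's probe-expanded sphere
(radius r_i + 1.4 Å) is accessible when outside every other expanded
sphere; occluders are all non-water, non-ion atoms, selected or not
(the quantity of interest is exposure to solvent, so solvent never
occludes). Per-atom radii come from the topology table, with
Bondi-style element radii as the fallback. The probe radius 1.4 Å is
the community-standard water probe. Both the per-frame series and the
window mean are reported, since either a snapshot or an average may be
meant by a printed SASA value.

## Steered pulling

The analysis chain assumes the constant-velocity protocol: a harmonic
restraint of stiffness k on a collective variable ξ (a COM–COM
distance), its centre moving at constant velocity (1.95 Å/ns in the
production protocol). Work is attributed to restraint-centre
displacement — `W(t_n) = Σ_{m<n} k(c_m − ξ_m)(c_{m+1} − c_m)`, left
rule, midpoint variant behind a flag — matching work-vs-distance plots
where distance is the driven coordinate. The spring constant is not
recoverable from a trace file and must be supplied.

Plateau detection resamples the curve onto a uniform 0.05 Å
displacement grid and reports maximal intervals of length ≥ 3 Å whose
work range stays below 5 kJ/mol; the level is the median work on the
interval, jumps are successive level differences. Both thresholds are
exposed (plateaus in published work curves are identified visually;
these defaults are this package's own operational definition).
`binding_energy_estimate` reports each curve's final plateau level and
the min–max range across runs (per-trajectory reporting, supporting
"45–80 kJ/mol depending on the starting configuration"-style
statements). When no interval qualifies on a noisy stochastic trace,
the final level falls back to the median work over the trailing 3 Å —
the protocol ends in the desorbed regime by construction, so the tail
median is an unbiased plateau height; the fallback is flagged per
curve.

### Langevin simulator

Ground truth comes from overdamped Euler–Maruyama dynamics on a known
1-D PMF:

    ξ ← ξ + (dt/γ)(−U′(ξ) + k(c(t) − ξ)) + √(2 k_B T dt/γ)·N(0,1)

with k_B T = 2.494 kJ/mol at 300 K and friction γ in kJ mol⁻¹ ns Å⁻²
(default 1.0, giving a free diffusion constant k_BT/γ ≈ 2.5 Å²/ns,
a reasonable molecular scale). The integrator refuses to run when
`dt·(k + max|U″|)/γ ≥ 0.1`; the curvature bound is evaluated over the
thermally accessible range (three thermal widths below the start point
to the end of the pull), since the divergent inner wall of a Morse
potential is never visited. Traces are recorded at a stride giving
≈ 0.002 Å of centre travel per sample, which keeps the work integral at
its dense-sampling variance. Everything is deterministic under a seed.

The recovery study (acceptance suite and `analysis/05_pulling_work.py`)
pulls out of a Morse well of depth D = 50 kJ/mol (width 1 Å⁻¹) with
k = 100 kJ/mol/Å², 12 Å of travel, at velocities 1.0/0.3/0.1 Å/ns and
10 seeds each. These sizes keep each velocity's ensemble within
seconds on one CPU while the slowest pull's dissipation
(≈ γvL ≈ 1 kJ/mol) is far inside the 15% recovery band. The mean
plateau work obeys the second-law bound ⟨W⟩ ≥ ΔF ≈ D at every velocity
and decreases toward D as v → 0.

## Synthetic scenarios

`make_scenario` realises a scripted timeline as a trajectory plus a
`ScenarioTruth` sidecar (planted per-frame partitions, H-bond keys with
their active frames, drift/noise/seed, PMF parameters). Molecules are
bead chains (1.5 Å spacing) with donor sites (N with one polar H) and
acceptor sites (O); they are deliberately not chemically faithful DNA
or doxorubicin — every analysis here is geometry- and parameter-driven,
so chemical realism would add nothing to verification. Placement puts
each scripted cluster group at a well-separated grid anchor (chains in
a group stacked 3.0 Å apart, inside the 3.5 Å criterion; distinct
groups > 6 Å apart); ligands are positioned by their active planted
bond (acceptor exactly 2.8 Å from the donor, D–H···A 5° from linear) or
parked in a reserved region. Gaussian noise (σ = 0.05 Å) is applied to
every atom except those defining planted bonds, so planted geometries
are exact and bonds exist in exactly the configured frames; a rigid
drift exercises the superposition step. The preset scenarios mirror the
qualitative behaviours of the simulated constructs: a five-chain
aggregate plus one detached chain (2 clusters), chains oscillating
between 4 and 5 clusters, and open-coil vs folded ligand binding with
planted occupancies (0.90/0.50/0.30/0.12/0.05 and 0.70/0.30/0.15).

What passing these tests shows: the analysis operators are correct on
inputs whose answers are known exactly. What it does not show:
agreement with any particular explicit-solvent production run — the
toys have no solvent, no realistic force field, no conformational
dynamics, and their energy scales are arbitrary. Published
multi-nanosecond observables (absolute pair energies, SASA values,
work magnitudes) require the original ~100k-atom trajectories and are
not reproduction targets here.

## Numerical choices

- Minimum image via `d − L·⌊d/L + 1/2⌋`, exact for orthorhombic boxes;
  each component lands in [−L/2, L/2).
- Cluster cutoff comparison is strict (`<`), per the criterion's
  "smaller than".
- Pair energies use r ≤ cutoff (inclusive); ties are measure-zero.
- The SASA point lattice is deterministic, so all results are exactly
  reproducible; areas converge as the point count grows.
- Degenerate inputs fail loudly: empty selections, overlapping energy
  groups, sub-0.1 Å contacts, non-monotone times, all-excluded
  clustering, collinear RMSD references, unstable Langevin timesteps
  (with a suggested dt).

## Known limitations

- Orthorhombic boxes only; no triclinic support.
- Real-space electrostatics only; totals are not comparable to
  mesh-Ewald energies.
- `unwrap_molecules` assumes molecular extent below half the box edge.
- The LAMMPS dump dialect is restricted to `id type x y z` (or scaled
  `xs ys zs`) with orthorhombic bounds; binary formats (DCD/XTC/TRR)
  are out of scope.
- The pulling simulator is 1-D and overdamped; it provides ground truth
  for the work/plateau analysis, not a model of real detachment
  kinetics.
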