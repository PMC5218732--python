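# Methods

## The model

`hydroqsar` scores ligand binding to the estrogen receptor alpha (ERα)
ligand-binding pocket (LBP) by combining three ingredients:

1. **A hydrophobicity density field on the ligand surface.**  The ligand is
   described by a grid on its solvent-accessible surface (SAS; van der Waals
   spheres inflated by a 1.4 Å water probe).  At grid point *j*,

       log P_j = C1 |Σᵢ qᵢ/r²ᵢⱼ| + C2 Σᵢ qᵢ²/r³ᵢⱼ + C3 Σᵢ αᵢ/r³ᵢⱼ
               + C4 Σᵢ αᵢ/r⁶ᵢⱼ + C_cav

   summed over the ligand's atoms, with net atomic charges *qᵢ*, effective
   atomic polarizabilities *αᵢ* and atom–point distances *rᵢⱼ*.  The
   coefficients (C1 = −8.85·10⁻², C2 = −1.45·10⁻¹, C3 = 1.57·10⁻²,
   C4 = −4.88·10⁻¹, C_cav = 2.34·10⁻³) are constants of the solvation
   model the field derives from, not fitting parameters here.  Points with
   log P_j > 0 are hydrophobic.  The **hydrophobic contact score**

       log P_C = Σₖ Σ_{j ∈ Cₖ, log P_j > 0} log P_j · w_j

   integrates hydrophobic points lying inside the van der Waals surface of
   the *k*-th hydrophobic pocket residue (set Cₖ), with *w_j* the point's
   area weight.

2. **A geometric interaction fingerprint** FP1–FP6: Asp351 salt bridge
   (FP1), Glu353 hydrogen bond (FP2), His524 hydrogen bond (FP3), Thr347
   hydrogen bond (FP4), the ligand's internal hydrogen-bond count (FP5) and
   log P_C (FP6).  Candidate features that are detected but not scored by
   the default model: Leu346 backbone-carbonyl bond, Arg394 acceptance
   (negligible in the reference model), Phe404 T-stack (subsumed by the
   A-ring arrangement requirement).

3. **A linear QSAR** of the log relative binding affinity,
   log RBA = Σᵢ cᵢ·FPᵢ + C, with RBA on the percent scale where
   17β-estradiol (E2) = 100.  The shipped coefficients are
   c = (0.923, 2.209, 1.689, 1.487, 0.614, 3.861) with C = −9.341: the
   intercept is the affinity of a ligand making no scored interaction
   (≈10⁻⁹ RBA), and each binary bit multiplies RBA by 10^c (Glu353 bond
   ≈162-fold, His524 ≈50-fold, Thr347 ≈30-fold, salt bridge ≈8-fold, each
   internal hydrogen bond ≈4-fold).

Docked-pose handling follows the consensus rule: poses from repeated
independent docking runs are leader-clustered at 1.0 Å heavy-atom RMSD
(computed in the shared receptor frame, no superposition, symmetry-aware by
default); clusters observed ≥3 times are bioactive-conformation candidates;
candidates are filtered by pocket geometry, scored by the QSAR and ranked
by predicted RBA.

## Assumptions

- Receptor and ligand share one coordinate frame; the receptor is treated
  as rigid within a complex.  Receptor flexibility enters only through the
  His524 conformational classes (below).
- Aliphatic amines are protonated at pH 7.4 (simple rule; no pKa model).
- Hydrogen-bond donors/acceptors are perceived from element and bonding
  pattern (O/N, with/without H); halogens are not acceptors.
- An aromatic ring vertically aligned with Phe404 (the "pincer") is an
  absolute requirement for a scored pose.

## Tunable parameters

| parameter | default | unit | why |
|---|---|---|---|
| probe radius | 1.4 | Å | standard water probe |
| grid density | 4.0 | points/Å² | smallest density at which doubling changes log P_C of the E2-sized fixture by <1% (see *Numerical choices*) |
| vdW radii | Bondi | Å | standard set; configurable table |
| polarizabilities | Miller-type additive | Å³ | per-element, carbon split by hybridization; configurable |
| charge scheme | Gasteiger (PEOE) | e | deterministic, graph-based; pluggable interface |
| H-bond | d ≤ 3.5 Å, θ ≥ 120° | | literature geometry; the source's exact criteria are in a supplement unavailable in text — these are stand-ins, fully configurable |
| salt bridge | ≤ 4.0 Å | Å | N⁺ to carboxylate O |
| ring stack | ≤ 5.5 Å, 60–90° | Å, deg | T-shaped window, inclusive bounds |
| hydroxyl pair range | 10–12 | Å | phenol-O to distal-O span that reaches His524 (O-to-O, not centroid) |
| open-pocket length | > 13 | Å | max heavy-atom pairwise distance |
| His524 class cutoffs | 16.0 / 18.5 | Å | nearest imidazole N to Glu353 carboxylate centroid; calibrated on the constructed class fixtures |
| cluster RMSD / min count | 1.0 Å / 3 | | consensus rule |
| GA | pop 50, gen 100, crossover 0.9, mutation 1/9, elitism 1 | | small 9-bit space; exhaustive search provided as cross-check |

## His524 classes and pose filtering

His524 adopts three side-chain conformations: **closed** (imidazole
placed to hydrogen-bond a distal hydroxyl at the D-ring site),
**moved-back** (retracted, hydrophobic accommodation) and **open**
(swung out, extending the pocket for ligands longer than 13 Å).  The
classifier bands the distance from the imidazole nitrogens to the Glu353
carboxylate centroid (the fixed pocket anchor): ≤16 Å closed, ≤18.5 Å
moved-back, beyond open.  The pose filter requires the Glu353 bond (HB1)
always; on a closed receptor a ligand whose second hydroxyl lies 10–12 Å
from the phenol must also realize the His524 bond (HB2); moved-back
imposes nothing further; open requires ligand length >13 Å.

## What the synthetic generators emulate — and what they do not

`fixtures.make_toy_complex` builds pseudo-residues (carboxylate, imidazole,
hydroxyl, phenyl, aliphatic clusters) carrying real ERα residue names and
numbers at controlled geometry, so each interaction feature can be switched
on or off independently and the full code path (PDB I/O included) runs
without external structures.  The pocket shell (3 aliphatic clusters around
the A-ring, 5 around the distal ring) gives the contact integral a
realistic magnitude.  Toy complexes do **not** reproduce real ERα
coordinates, side-chain rotamer statistics, or crystallographic disorder;
passing tests demonstrate correctness of the geometry/field/regression
machinery, not predictive accuracy on real complexes.  Absolute log P_C
values depend on grid density, probe radius and the hydrophobic-residue
list; the fixtures therefore assert sign, monotonicity, invariance and
convergence rather than absolute field values.

`fixtures.make_synthetic_table` draws fingerprint rows emulating the
composition of a 31-ligand training set (Glu353 bond common, salt bridge
and Thr347 bond rare, log P_C uniform on 0.80–2.44) with Gaussian noise of
0.3 log units on the response — about the residual scale a fit with
R² ≈ 0.96 implies at that spread.  `make_pose_set` plants clusters of
given multiplicity: the first at the input pose (self-docking semantics),
others at lattice offsets several thresholds apart.

## Numerical choices

- **Area-weighted integration.**  The contact sum multiplies each grid
  point by its area weight so log P_C is density-independent; a bare point
  sum (available as `--raw-sum`) scales with grid density and is not
  comparable across implementations.
- **Grid density 4.0/Å².**  The integrand has two sharp boundaries (the
  log P_j > 0 level set and the residue vdW indicator), so quadrature
  error decays slowly; at 4.0 points/Å² doubling the density moves the
  E2-sized fixture's log P_C by <1%, at 2.0 it moved ~4–10%.
- **Deterministic tessellation and frame.**  Fibonacci-sphere shells are
  generated in the ligand's principal-axis frame (third-moment sign
  convention, right-handed), so grids co-rotate rigidly with the molecule
  and log P_C is invariant under rigid-body motion to <10⁻⁶.  Exactly
  coincident SAS spheres are owned by the lower-indexed atom.
- **Double counting.**  A grid point inside two residues' vdW surfaces
  contributes to both contact sets (literal double sum); a unique-count
  mode is available.
- **LOO Q².**  Computed by the hat-matrix identity
  e₍loo₎ = e/(1−h); a leverage-1 observation makes LOO undefined and
  raises.  The brute-force n-refit oracle is kept in the test suite.
- **GA fitness and parsimony.**  Fitness is LOO Q².  Final selection treats
  subsets within 0.01 Q² of the best as tied and resolves toward fewer
  features (then lexicographic order): strict-equality ties never occur in
  continuous data, and without the tolerance chance slivers of
  cross-validated fit admit pure-noise bits in roughly a fifth of
  synthetic draws.  0.01 is the conventional reporting precision of Q².
- **Charges.**  Gasteiger iteration residue (<10⁻⁶ e) is spread uniformly
  so totals equal the formal charge exactly.
- **Degenerate inputs.**  Zero-atom ligands, unparameterized elements,
  points on atomic centers, rank-deficient designs and empty pose lists
  raise with specific messages; empty pockets score log P_C = 0 with a
  warning.
- **Tie-breaks.**  Cluster leaders are chosen by engine score then run
  index (medoid fallback when scores are absent); equal predicted RBA
  breaks by cluster count then leader order; receptor-selection ties break
  lexicographically on receptor label.

## Open design points resolved here

- The contact sum is integrated (area-weighted), not a bare count — the
  literal reading is kept behind a switch.
- GA fitness uses LOO Q² (validation metric of the method) rather than R²
  or an information criterion.
- The hydroxyl-pair separation is measured oxygen-to-oxygen.
- Ligands with zero or censored RBA are excluded from fits (log undefined).
- Arg394 acceptance and the Leu346 bond are detected and reported but not
  scored by the default model.

## Problem sizes

The test suite and the acceptance script run on toy complexes of 20–40
atoms, synthetic tables of n = 31, pose sets of ≤10 runs, and 1000-fixture
clustering sweeps with ≤8 poses of a 3-heavy-atom molecule — sizes at which
every oracle (exhaustive subset search, brute-force LOO, all-pairs
distances, leader enumeration) is exact and fast.

## Known limitations

- Docking itself is out of scope; poses are ingested from SDF/PDBQT.
- No structure preparation beyond hydrogen completion (no minimization,
  protonation-state prediction or loop modeling).
- PDBQT ingestion maps heavy atoms by file order against the template and
  rebuilds merged non-polar hydrogens by idealized geometry — adequate for
  rigid analyses, approximate for torsionally distorted hydrogens.
- The greedy consensus clustering equals the exhaustive oracle when
  binding sites are separated by much more than the RMSD threshold (the
  regime the consensus rule assumes); for overlapping sites it may split a
  borderline cluster, though it never reports a candidate the oracle
  rejects.
- Absolute log P_C values are calibration-dependent (grid settings and
  residue list); cross-study comparison requires fixing those knobs.
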