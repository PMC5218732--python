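"""Synthetic test inputs: toy complexes, fingerprint tables and pose sets.

Everything here is generated programmatically so the whole pipeline can be
exercised without external structures.  Toy complexes place minimal
pseudo-residues (carboxylate, imidazole, hydroxyl, phenyl ring, aliphatic
side chains) carrying real ERalpha residue names and numbering (Glu353,
His524, Thr347, Asp351, Phe404, Leu387, ...) at controlled geometry, so
exactly the requested interaction features satisfy the default criteria.
Synthetic fingerprint tables emulate the composition of the 31-ligand
training set (mostly Glu353-bonded ligands, a minority with salt bridges or
Thr347 bonds, hydrophobic contact scores in the 0.8-2.44 range).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hydroqsar.qsar import FP_NAMES, published_model
from hydroqsar.structure_model import (
    AtomRecord,
    ComplexStructure,
    MolecularStructure,
    PocketResidue,
    write_complex_pdb,
)

VALID_SWITCHES = frozenset(
    {"HB_E353", "HB_H524", "HB_T347", "salt_bridge", "internal_hb"})
TEMPLATES = ("phenol", "diol_11A", "amine_tail", "e2_like")

_HB_DIST = 2.8       # donor-acceptor heavy distance used for planted bonds
_SB_DIST = 3.5       # amine-N to carboxylate-O distance for salt bridges
_FAR = 7.0           # displacement that keeps a residue in the pocket but
                     # outside every interaction criterion


@dataclass(frozen=True)
class ToyComplexSpec:
    """Recipe for a toy complex with controlled interaction geometry."""

    ligand_template: str = "diol_11A"
    feature_switches: frozenset = frozenset()
    his524_class: str = "closed"
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ligand_template not in TEMPLATES:
            raise ValueError(f"unknown template {self.ligand_template!r}")
        unknown = set(self.feature_switches) - VALID_SWITCHES
        if unknown:
            raise ValueError(f"unknown feature switches: {sorted(unknown)}")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        if self.his524_class not in ("closed", "moved_back", "open"):
            raise ValueError(f"unknown His524 class {self.his524_class!r}")


@dataclass(frozen=True)
class SyntheticTableSpec:
    """Recipe for a synthetic fingerprint/affinity table."""

    n: int = 31
    true_coefficients: tuple = (0.923, 2.209, 1.689, 1.487, 0.614, 3.861)
    intercept: float = -9.341
    noise_sd: float = 0.3
    bit_probabilities: tuple = (0.25, 0.85, 0.4, 0.15)
    logpc_range: tuple = (0.80, 2.44)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 5:
            raise ValueError("need at least 5 rows")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.logpc_range
        if not (0.0 <= lo <= hi <= 4.0):
            raise ValueError("logpc_range must lie within [0, 4]")


# ---------------------------------------------------------------------------
# Ligand templates
# ---------------------------------------------------------------------------

def _ring_positions(center: np.ndarray, radius: float = 1.39,
                    start_deg: float = 180.0) -> np.ndarray:
    ang = np.deg2rad(start_deg - 60.0 * np.arange(6))
    return center + radius * np.column_stack(
        [np.cos(ang), np.sin(ang), np.zeros(6)])


class _Builder:
    def __init__(self, name: str):
        self.atoms: list[AtomRecord] = []
        self.bonds: list[tuple[int, int, int]] = []
        self.name = name

    def add(self, element: str, coords, name: str = "") -> int:
        idx = len(self.atoms)
        self.atoms.append(AtomRecord(serial=idx + 1, element=element,
                                     coords=np.asarray(coords, float),
                                     name=name or f"{element}{idx+1}"))
        return idx

    def bond(self, i: int, j: int, order: int = 1) -> None:
        self.bonds.append((i, j, order))

    def ring(self, center, start_deg: float = 180.0) -> list[int]:
        pos = _ring_positions(np.asarray(center, float), start_deg=start_deg)
        idx = [self.add("C", p) for p in pos]
        for k in range(6):
            self.bond(idx[k], idx[(k + 1) % 6], 2 if k % 2 == 0 else 1)
        return idx

    def ring_hydrogens(self, ring_idx: list[int],
                       skip: set[int] = frozenset()) -> None:
        center = np.mean([self.atoms[i].coords for i in ring_idx], axis=0)
        for i in ring_idx:
            if i in skip:
                continue
            d = self.atoms[i].coords - center
            d = d / np.linalg.norm(d)
            h = self.add("H", self.atoms[i].coords + 1.08 * d)
            self.bond(i, h)

    def build(self) -> MolecularStructure:
        st = MolecularStructure(atoms=self.atoms, bonds=self.bonds,
                                name=self.name)
        st.perceive_rings()
        st.flag_polar_hydrogens()
        return st


def _add_phenol_oxygen(b: _Builder, ring_idx: list[int], carbon: int,
                       direction: np.ndarray) -> tuple[int, int]:
    """Attach O-H to a ring carbon along ``direction``; returns (O, H)."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    c = b.atoms[carbon].coords
    o = b.add("O", c + 1.36 * d)
    h = b.add("H", c + (1.36 + 0.96) * d)
    b.bond(carbon, o)
    b.bond(o, h)
    return o, h


def _internal_hb_motif(b: _Builder, ring_idx: list[int], ortho_carbon: int,
                       phenol_o: int) -> None:
    """Attach an ortho CH2-OH whose hydroxyl donates back to the phenol
    oxygen (one internal hydrogen bond, donor 4 bonds from acceptor)."""
    center = np.mean([b.atoms[i].coords for i in ring_idx], axis=0)
    cdir = b.atoms[ortho_carbon].coords - center
    cdir = cdir / np.linalg.norm(cdir)
    cf = b.atoms[ortho_carbon].coords + 1.50 * cdir
    cf_idx = b.add("C", cf)
    b.bond(ortho_carbon, cf_idx)
    # O on a 1.43-A circle around cf, at exactly _HB_DIST from the phenol O
    o1 = b.atoms[phenol_o].coords
    o3 = _circle_intersection(cf, 1.43, o1, _HB_DIST)
    o3_idx = b.add("O", o3)
    b.bond(cf_idx, o3_idx)
    hdir = (o1 - o3) / np.linalg.norm(o1 - o3)
    h_idx = b.add("H", o3 + 0.96 * hdir)
    b.bond(o3_idx, h_idx)
    # two hydrogens complete the CH2
    perp = np.array([0.0, 0.0, 1.0])
    for sgn in (1.0, -1.0):
        h = b.add("H", cf + 1.09 * (0.4 * cdir + sgn * 0.9 * perp)
                  / np.linalg.norm(0.4 * cdir + sgn * 0.9 * perp))
        b.bond(cf_idx, h)


def _circle_intersection(c1: np.ndarray, r1: float, c2: np.ndarray,
                         r2: float) -> np.ndarray:
    """A point in the z=0 plane at distance r1 from c1 and r2 from c2."""
    d = float(np.linalg.norm(c2[:2] - c1[:2]))
    if d > r1 + r2 or d < abs(r1 - r2):
        raise ValueError("internal hydrogen-bond motif geometrically "
                         "unrealizable on this template")
    a = (r1 * r1 - r2 * r2 + d * d) / (2 * d)
    h = np.sqrt(max(r1 * r1 - a * a, 0.0))
    ex = (c2[:2] - c1[:2]) / d
    ey = np.array([-ex[1], ex[0]])
    p = c1[:2] + a * ex + h * ey
    return np.array([p[0], p[1], 0.0])


def make_ligand(template: str, internal_hb: bool = False
                ) -> tuple[MolecularStructure, dict]:
    """Build a ligand template; returns the structure and anchor metadata
    (indices of the phenol O/H, distal O/H, amine N when present)."""
    b = _Builder(template)
    meta: dict = {}
    ring1 = b.ring(np.zeros(3))
    o1, h1 = _add_phenol_oxygen(b, ring1, ring1[0], np.array([-1.0, 0, 0]))
    meta["phenol_o"], meta["phenol_h"] = o1, h1
    meta["ring1"] = ring1
    skip1 = {ring1[0]}
    if internal_hb:
        skip1.add(ring1[1])

    if template in ("diol_11A", "e2_like"):
        bridge = b.add("C", [2.75, 0.0, 0.0])
        b.bond(ring1[3], bridge)
        hb_ = b.add("H", [2.75, 0.0, 1.09])
        b.bond(bridge, hb_)
        ring2 = b.ring(np.array([5.5, 0.0, 0.0]), start_deg=0.0)
        b.bond(bridge, ring2[3])
        # distal hydroxyl: O2 at +x end, 11.0 A from the phenol O
        o2, h2 = _add_phenol_oxygen(b, ring2, ring2[0],
                                    np.array([1.0, 0, 0]))
        meta["distal_o"], meta["distal_h"] = o2, h2
        meta["ring2"] = ring2
        b.ring_hydrogens(ring1, skip1 | {ring1[3]})
        b.ring_hydrogens(ring2, {ring2[0], ring2[3]})
        if template == "e2_like":
            # sp3 bulk mimicking the C/D rings of a steroid core
            for k, pos in enumerate([(3.4, 1.6, 0.9), (4.6, -1.5, -0.9)]):
                c = b.add("C", pos)
                b.bond(ring2[4] if k else ring2[2], c)
                for m in range(3):
                    d = np.array([0.3, (-1) ** m * 0.8, 0.6 * (m - 1)])
                    d = d / np.linalg.norm(d)
                    h = b.add("H", np.asarray(pos) + 1.09 * d)
                    b.bond(c, h)
    elif template == "amine_tail":
        prev = ring1[3]
        x = 1.39
        for _ in range(6):
            x += 1.5
            c = b.add("C", [x, 0.0, 0.0])
            b.bond(prev, c)
            for sgn in (1.0, -1.0):
                h = b.add("H", [x, sgn * 0.9, 0.63])
                b.bond(c, h)
            prev = c
        n = b.add("N", [x + 1.47, 0.0, 0.0], name="NT")
        b.bond(prev, n)
        for sgn in (1.0, -1.0):
            cm = b.add("C", [x + 2.0, sgn * 1.3, 0.0])
            b.bond(n, cm)
            for m in range(3):
                d = np.array([0.8, sgn * 0.4, 0.7 * (m - 1)])
                d = d / np.linalg.norm(d)
                h = b.add("H", b.atoms[cm].coords + 1.09 * d)
                b.bond(cm, h)
        meta["amine_n"] = n
        b.ring_hydrogens(ring1, skip1 | {ring1[3]})
    else:  # phenol
        b.ring_hydrogens(ring1, skip1)

    if internal_hb:
        _internal_hb_motif(b, ring1, ring1[1], o1)
    return b.build(), meta


# ---------------------------------------------------------------------------
# Pseudo-residues
# ---------------------------------------------------------------------------

def _residue(name: str, seq: int, atoms: list[tuple[str, str, np.ndarray]]
             ) -> PocketResidue:
    recs = [AtomRecord(serial=k + 1, element=el, coords=np.asarray(xyz, float),
                       name=nm, parent_id=f"{name}{seq}")
            for k, (el, nm, xyz) in enumerate(atoms)]
    return PocketResidue(res_name=name, chain="A", seq_num=seq, atoms=recs)


def _glu353(o1: np.ndarray, h1: np.ndarray, on: bool) -> PocketResidue:
    direction = (h1 - o1) / np.linalg.norm(h1 - o1)
    # when off, retract out of plane: breaks the bond geometry while moving
    # the pocket anchor (and thus the His524 class bands) as little as
    # possible
    oe1 = o1 + _HB_DIST * direction + (np.zeros(3) if on
                                       else np.array([0.0, 0.0, 5.0]))
    cd = oe1 + 1.25 * direction + np.array([0.0, 0.6, 0.0])
    oe2 = cd + np.array([0.0, 1.2, 0.3])
    return _residue("GLU", 353, [("C", "CD", cd), ("O", "OE1", oe1),
                                 ("O", "OE2", oe2)])


def _thr347(o1: np.ndarray, h1: np.ndarray, on: bool) -> PocketResidue:
    # acceptor 30 deg off the donor axis: inside the angle criterion but
    # distinct from the Glu353 site
    axis = (h1 - o1) / np.linalg.norm(h1 - o1)
    side = np.array([-axis[1], axis[0], 0.0])
    direction = np.sqrt(0.75) * axis + 0.5 * side
    og1 = o1 + (_HB_DIST if on else _FAR + 2.0) * direction
    cb = og1 + np.array([0.0, 1.2, 0.8])
    hg1 = og1 + 0.96 * np.array([0.0, 0.0, 1.0])
    return _residue("THR", 347, [("C", "CB", cb), ("O", "OG1", og1),
                                 ("H", "HG1", hg1)])


def _his524(anchor: np.ndarray, o2: np.ndarray | None, his_class: str,
            hb_on: bool) -> PocketResidue:
    """Imidazole placed by His524 class; when ``hb_on`` the NE2 acceptor
    sits at hydrogen-bond distance from the distal hydroxyl oxygen."""
    if hb_on:
        if o2 is None:
            raise ValueError("HB_H524 requires a ligand with a distal "
                             "hydroxyl (diol_11A or e2_like template)")
        ang = np.deg2rad(100.0)
        ne2 = o2 + _HB_DIST * np.array([np.cos(ang), np.sin(ang), 0.0])
    else:
        base = o2 if o2 is not None else np.array([8.25, 0.0, 0.0])
        if his_class == "closed":
            ne2 = base + np.array([-1.0, 4.5, 0.0])
        elif his_class == "moved_back":
            ne2 = base + np.array([1.5, 4.0, 0.0])
        else:  # open
            ne2 = base + np.array([5.5, 4.5, 0.0])
    away = (ne2 - anchor) / np.linalg.norm(ne2 - anchor)
    center = ne2 + 1.16 * away
    # regular pentagon in the z=0 plane, NE2 at the anchor-facing vertex
    theta0 = np.arctan2(-away[1], -away[0])
    names = ["NE2", "CE1", "ND1", "CG", "CD2"]
    elements = ["N", "C", "N", "C", "C"]
    atoms = []
    for k in range(5):
        ang = theta0 + 2 * np.pi * k / 5
        pos = center + 1.16 * np.array([np.cos(ang), np.sin(ang), 0.0])
        atoms.append((elements[k], names[k], pos))
    nd1 = atoms[2][2]
    hd1 = nd1 + 1.01 * (nd1 - center) / np.linalg.norm(nd1 - center)
    atoms.append(("H", "HD1", hd1))
    return _residue("HIS", 524, atoms)


def _asp351(n_pos: np.ndarray | None, on: bool) -> PocketResidue:
    base = n_pos if n_pos is not None else np.array([10.0, 0.0, 0.0])
    direction = np.array([0.0, -1.0, 0.0])
    od1 = base + (_SB_DIST if on else _FAR) * direction
    cg = od1 + np.array([0.0, -1.25, 0.0])
    od2 = cg + np.array([1.1, -0.5, 0.0])
    return _residue("ASP", 351, [("C", "CG", cg), ("O", "OD1", od1),
                                 ("O", "OD2", od2)])


def _phe404(ring_centroid: np.ndarray) -> PocketResidue:
    """Phenyl ring 5.0 A above the ligand A-ring, perpendicular (T-shaped)."""
    center = ring_centroid + np.array([0.0, 0.0, 5.0])
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    atoms = []
    for k in range(6):
        ang = 2 * np.pi * k / 6
        # ring in the x-z plane: normal along y, ligand ring normal along z
        pos = center + 1.39 * np.array([np.cos(ang), 0.0, np.sin(ang)])
        atoms.append(("C", names[k], pos))
    return _residue("PHE", 404, atoms)


def _aliphatic_cluster(name: str, seq: int, base: np.ndarray
                       ) -> PocketResidue:
    """Aliphatic carbon side-chain cluster: a hydrophobic contact patch."""
    offsets = [(0, 0, 0), (1.4, 0.4, -0.5), (-1.2, 0.8, -0.6),
               (0.2, -1.3, -0.8)]
    names = ["CB", "CG", "CD1", "CD2"]
    atoms = [("C", nm, np.asarray(base, float) + np.asarray(off, float))
             for nm, off in zip(names, offsets)]
    return PocketResidue(res_name=name, chain="A", seq_num=seq,
                         atoms=[AtomRecord(serial=k + 1, element=el,
                                           coords=np.asarray(xyz, float),
                                           name=nm)
                                for k, (el, nm, xyz) in enumerate(atoms)],
                         hydrophobic=True)


# hydrophobic side chains lining the toy pocket, emulating the residue
# shell of the ERalpha LBP around the A-ring (first block) and the C/D-ring
# region (second block); offsets are relative to the respective ring center
_RING1_SHELL = [("LEU", 387, (0.0, 0.0, -3.8)),
                ("LEU", 384, (0.0, 4.2, -1.5)),
                ("ALA", 350, (0.0, -4.2, -1.5))]
_RING2_SHELL = [("MET", 388, (0.0, 0.0, -3.8)),
                ("MET", 343, (0.0, 4.2, 1.5)),
                ("ILE", 424, (0.0, -4.2, 1.5)),
                ("VAL", 418, (-2.75, 0.0, -4.4)),
                ("LEU", 391, (-2.75, 0.0, 4.6))]


# ---------------------------------------------------------------------------
# Toy complex assembly
# ---------------------------------------------------------------------------

def make_toy_complex(spec: ToyComplexSpec,
                     pdb_path: str | Path | None = None) -> ComplexStructure:
    """Assemble a toy complex realizing exactly the switched-on features.

    Deterministic given the spec seed; optional PDB output for parser tests.
    Raises when a requested combination is geometrically unrealizable (salt
    bridge without an amine template, His524 bond without a distal hydroxyl,
    His524 bond on a non-closed receptor).
    """
    sw = set(spec.feature_switches)
    if "salt_bridge" in sw and spec.ligand_template != "amine_tail":
        raise ValueError("salt_bridge requires the amine_tail template "
                         "(no protonatable amine on this ligand)")
    if "HB_H524" in sw and spec.ligand_template not in ("diol_11A",
                                                        "e2_like"):
        raise ValueError("HB_H524 requires a distal hydroxyl "
                         "(diol_11A or e2_like template)")
    if "HB_H524" in sw and spec.his524_class != "closed":
        raise ValueError("HB_H524 is only realizable on a closed receptor "
                         "(the imidazole must reach the distal hydroxyl)")

    ligand, meta = make_ligand(spec.ligand_template,
                               internal_hb="internal_hb" in sw)
    coords = {k: ligand.atoms[v].coords.copy()
              for k, v in meta.items() if isinstance(v, int)}

    glu = _glu353(coords["phenol_o"], coords["phenol_h"], "HB_E353" in sw)
    anchor_pos = np.mean([a.coords for a in glu.atoms
                          if a.name in ("OE1", "OE2")], axis=0)
    ring1_center = np.mean([ligand.atoms[i].coords
                            for i in meta["ring1"]], axis=0)
    pocket = [glu,
              _thr347(coords["phenol_o"], coords["phenol_h"],
                      "HB_T347" in sw),
              _his524(anchor_pos, coords.get("distal_o"),
                      spec.his524_class, "HB_H524" in sw),
              _phe404(ring1_center)]
    pocket += [_aliphatic_cluster(name, seq, ring1_center + np.array(off))
               for name, seq, off in _RING1_SHELL]
    if "ring2" in meta:
        ring2_center = np.mean([ligand.atoms[i].coords
                                for i in meta["ring2"]], axis=0)
        pocket += [_aliphatic_cluster(name, seq,
                                      ring2_center + np.array(off))
                   for name, seq, off in _RING2_SHELL]
    if spec.ligand_template == "amine_tail":
        pocket.append(_asp351(coords.get("amine_n"), "salt_bridge" in sw))

    if "HB_H524" in sw:
        # point the distal hydroxyl hydrogen at the imidazole acceptor
        his = next(r for r in pocket if r.res_name == "HIS")
        ne2 = his.atom_by_name("NE2").coords
        o2 = coords["distal_o"]
        direction = (ne2 - o2) / np.linalg.norm(ne2 - o2)
        ligand.atoms[meta["distal_h"]].coords = o2 + 0.96 * direction

    cmplx = ComplexStructure(ligand=ligand, pocket=pocket,
                             receptor_label=f"toy_{spec.ligand_template}",
                             receptor_class=spec.his524_class)
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        for st in [ligand]:
            st.set_coords(st.coords + rng.normal(0, spec.jitter,
                                                 st.coords.shape))
        for r in pocket:
            for a in r.atoms:
                a.coords = a.coords + rng.normal(0, spec.jitter, 3)
    if pdb_path is not None:
        write_complex_pdb(cmplx, pdb_path)
    return cmplx


# ---------------------------------------------------------------------------
# Synthetic fingerprint tables
# ---------------------------------------------------------------------------

def make_synthetic_table(spec: SyntheticTableSpec
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Draw a synthetic (X, y) fingerprint table.

    Binary bits are Bernoulli draws, FP5 a small non-negative integer, FP6
    uniform over the hydrophobic-contact range; y is the exact linear
    response plus Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    X = np.zeros((spec.n, 6))
    for j, p in enumerate(spec.bit_probabilities):
        X[:, j] = rng.random(spec.n) < p
    X[:, 4] = rng.binomial(2, 0.15, size=spec.n)
    lo, hi = spec.logpc_range
    X[:, 5] = rng.uniform(lo, hi, size=spec.n)
    c = np.asarray(spec.true_coefficients, float)
    y = spec.intercept + X @ c + rng.normal(0.0, spec.noise_sd, size=spec.n)
    return X, y


# ---------------------------------------------------------------------------
# Pose sets
# ---------------------------------------------------------------------------

def make_pose_set(base: MolecularStructure, n_runs: int, n_per_run: int,
                  cluster_plan: list[tuple[float, int]], seed: int = 0,
                  out_dir: str | Path | None = None):
    """Generate docked-pose fixtures around planted cluster centers.

    ``cluster_plan`` is a list of (jitter, multiplicity) pairs; remaining
    slots up to ``n_runs * n_per_run`` stay unused.  Returns
    ``(poses, labels)`` where labels give each pose's planted cluster index.
    With ``out_dir`` the poses are also written as one multi-record SDF per
    run (plus a ground-truth JSON).
    """
    from hydroqsar.pose_pipeline import DockedPose

    total = sum(m for _, m in cluster_plan)
    if total > n_runs * n_per_run:
        raise ValueError("cluster multiplicities exceed the pose budget")
    rng = np.random.default_rng(seed)
    # the first planned cluster sits on the input pose itself (the
    # "bioactive" site); later clusters go to well-separated lattice offsets
    lattice = [np.array([6.0 * i, 4.5 * j, 4.5 * k])
               for i in range(4) for j in range(4) for k in range(2)
               if (i, j, k) != (0, 0, 0)]
    order = rng.permutation(len(lattice))
    poses: list[DockedPose] = []
    labels: list[int] = []
    slot = 0
    for c_idx, (jit, mult) in enumerate(cluster_plan):
        center_offset = (np.zeros(3) if c_idx == 0
                         else lattice[order[c_idx - 1]])
        for _ in range(mult):
            st = base.copy()
            shift = center_offset
            if jit > 0:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                shift = center_offset + jit * rng.random() * direction
            st.set_coords(st.coords + shift)
            poses.append(DockedPose(run_index=slot % n_runs, conformer=st,
                                    engine_score=float(
                                        rng.normal(-8.0, 0.5))))
            labels.append(c_idx)
            slot += 1
    if out_dir is not None:
        _write_pose_files(poses, labels, n_runs, Path(out_dir))
    return poses, labels


def _write_pose_files(poses, labels, n_runs: int, out_dir: Path) -> None:
    from rdkit import Chem

    from hydroqsar.structure_model import to_rdkit

    out_dir.mkdir(parents=True, exist_ok=True)
    by_run: dict[int, list] = {}
    for pose, lab in zip(poses, labels):
        by_run.setdefault(pose.run_index, []).append((pose, lab))
    for run in range(n_runs):
        path = out_dir / f"run{run:02d}.sdf"
        writer = Chem.SDWriter(str(path))
        writer.SetKekulize(False)
        for pose, _ in by_run.get(run, []):
            mol = to_rdkit(pose.conformer)
            if pose.engine_score is not None:
                mol.SetProp("score", f"{pose.engine_score:.4f}")
            writer.write(mol)
        writer.close()
    truth = {"labels": labels,
             "runs": [p.run_index for p in poses]}
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1))


def materialize_fixture_suite(out_dir: str | Path, seed: int = 7) -> dict:
    """Write the full fixture suite (PDB complexes, SDF ligand + poses,
    synthetic table, ground truth) to a directory; returns a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": []}

    combos = {
        "hb_e353_only": ToyComplexSpec(feature_switches=frozenset(
            {"HB_E353"})),
        "all_off": ToyComplexSpec(),
        "closed_full": ToyComplexSpec(feature_switches=frozenset(
            {"HB_E353", "HB_H524"})),
        "amine_salt": ToyComplexSpec(ligand_template="amine_tail",
                                     feature_switches=frozenset(
                                         {"HB_E353", "salt_bridge"}),
                                     his524_class="open"),
    }
    for label, spec in combos.items():
        path = out / f"{label}.pdb"
        make_toy_complex(spec, pdb_path=path)
        manifest["files"].append(path.name)

    cmplx = make_toy_complex(ToyComplexSpec(feature_switches=frozenset(
        {"HB_E353", "HB_H524"})))
    from hydroqsar.structure_model import to_rdkit
    from rdkit import Chem
    lig_path = out / "ligand.sdf"
    w = Chem.SDWriter(str(lig_path))
    w.SetKekulize(False)
    w.write(to_rdkit(cmplx.ligand))
    w.close()
    manifest["files"].append(lig_path.name)

    make_pose_set(cmplx.ligand, n_runs=10, n_per_run=1,
                  cluster_plan=[(0.2, 5), (0.2, 3), (0.2, 2)], seed=seed,
                  out_dir=out / "poses")
    manifest["files"].append("poses/")

    from hydroqsar.qsar import write_fingerprint_table
    X, y = make_synthetic_table(SyntheticTableSpec(seed=seed))
    table_path = out / "synthetic_table.tsv"
    write_fingerprint_table(table_path, X, y)
    manifest["files"].append(table_path.name)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
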