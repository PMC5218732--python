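"""Geometric detection of protein-ligand interaction features.

The candidate features of the ERalpha pharmacophore: a salt bridge with
Asp351, hydrogen bonds with Leu346/Thr347/Glu353/Arg394/His524, a T-shaped
pi-stack with Phe404, ligand internal hydrogen bonds, and the arrangement of
a phenyl at the A-ring region.  His524 side-chain conformations are
classified into closed / moved-back / open pocket shapes.

All detectors operate on raw geometry (distances, angles, ring planes) and
are invariant under rigid-body motion of the whole complex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import pdist

from hydroqsar.structure_model import (
    ComplexStructure,
    MolecularStructure,
    PocketResidue,
)

FEATURES = (
    "salt_bridge_D351", "hb_L346", "hb_T347", "hb_E353", "hb_R394",
    "hb_H524", "pistack_F404", "internal_hb", "aring_ok",
)

CLOSED, MOVED_BACK, OPEN, UNKNOWN = "closed", "moved_back", "open", "unknown"


@dataclass(frozen=True)
class GeometricCriteria:
    """Distance/angle cutoffs for interaction detection.

    Hydrogen bond: donor-acceptor heavy distance <= ``hbond_max_dist`` and
    donor-H...acceptor angle >= ``hbond_min_angle``.  Salt bridge: amine N to
    carboxylate O distance.  Ring stack: centroid distance plus interplanar
    angle window (near-perpendicular = T-shaped).  ``hydroxyl_pair_range`` is
    the phenol-O to distal-hydroxyl-O span that places the second hydroxyl at
    the His524 site; ``length_open_threshold`` is the ligand length beyond
    which the open pocket is required.  His524 class cutoffs are distances
    from the imidazole nitrogens to the Glu353 carboxylate anchor.
    """

    hbond_max_dist: float = 3.5
    hbond_min_angle: float = 120.0
    saltbridge_max_dist: float = 4.0
    ring_centroid_max_dist: float = 5.5
    ring_interplanar_range: tuple[float, float] = (60.0, 90.0)
    length_open_threshold: float = 13.0
    hydroxyl_pair_range: tuple[float, float] = (10.0, 12.0)
    his524_closed_max: float = 16.0
    his524_movedback_max: float = 18.5

    def __post_init__(self) -> None:
        for name in ("hbond_max_dist", "saltbridge_max_dist",
                     "ring_centroid_max_dist", "length_open_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.ring_interplanar_range
        if not (0.0 <= lo <= hi <= 180.0):
            raise ValueError("ring_interplanar_range must lie in [0, 180]")
        if not (0.0 <= self.hbond_min_angle <= 180.0):
            raise ValueError("hbond_min_angle must lie in [0, 180]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ring_interplanar_range"] = list(self.ring_interplanar_range)
        d["hydroxyl_pair_range"] = list(self.hydroxyl_pair_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeometricCriteria":
        d = dict(d)
        for key in ("ring_interplanar_range", "hydroxyl_pair_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RingDescriptor:
    """An aromatic ring summarized by its centroid m and unit normal n."""

    member_atoms: list[int]
    centroid: np.ndarray
    normal: np.ndarray

    @classmethod
    def from_coords(cls, member_atoms: list[int],
                    coords: np.ndarray) -> "RingDescriptor":
        coords = np.asarray(coords, float)
        centroid = coords.mean(axis=0)
        centered = coords - centroid
        _, _, vt = np.linalg.svd(centered)
        normal = vt[2]
        normal = normal / np.linalg.norm(normal)
        return cls(member_atoms=list(member_atoms), centroid=centroid,
                   normal=normal)


@dataclass
class FeatureHit:
    """A detected interaction feature with the geometry that satisfied it."""

    feature: str
    partner: str
    measured: dict = field(default_factory=dict)


@dataclass
class HBondGroup:
    """A hydrogen-bond donor or acceptor: heavy atom plus attached hydrogens."""

    heavy: np.ndarray
    hydrogens: list = field(default_factory=list)
    label: str = ""
    atom_index: int = -1

    def __post_init__(self) -> None:
        self.heavy = np.asarray(self.heavy, float)
        self.hydrogens = [np.asarray(h, float) for h in self.hydrogens]


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Primitive detectors
# ---------------------------------------------------------------------------

def detect_hbond(donor: HBondGroup, acceptor: HBondGroup,
                 criteria: GeometricCriteria | None = None,
                 feature: str = "hbond",
                 partner: str = "") -> FeatureHit | None:
    """Hydrogen bond: heavy-atom distance and donor-H...acceptor angle test.

    Returns the hit through the best (largest-angle) hydrogen, or ``None``.
    A donor without hydrogens cannot donate (warning).
    """
    criteria = criteria or GeometricCriteria()
    if not donor.hydrogens:
        warnings.warn(f"donor {donor.label or 'group'} has no hydrogen; "
                      "cannot donate a hydrogen bond")
        return None
    dist = float(np.linalg.norm(donor.heavy - acceptor.heavy))
    if dist > criteria.hbond_max_dist:
        return None
    best = max(_angle_deg(donor.heavy, h, acceptor.heavy)
               for h in donor.hydrogens)
    if best < criteria.hbond_min_angle:
        return None
    return FeatureHit(feature=feature, partner=partner or acceptor.label,
                      measured={"distance": dist, "angle": best,
                                "ligand_atom": donor.atom_index,
                                "direction": "donate"})


def detect_salt_bridge(ligand: MolecularStructure, asp_residue: PocketResidue,
                       criteria: GeometricCriteria | None = None
                       ) -> FeatureHit | None:
    """Salt bridge between a protonatable ligand amine and an Asp/Glu
    carboxylate: N to carboxylate-O distance test."""
    criteria = criteria or GeometricCriteria()
    if asp_residue.res_name not in ("ASP", "GLU"):
        raise ValueError(
            f"salt-bridge partner must be Asp/Glu, got {asp_residue.res_name}")
    ox_names = (("OD1", "OD2") if asp_residue.res_name == "ASP"
                else ("OE1", "OE2"))
    ox = [a.coords for a in asp_residue.atoms if a.name in ox_names]
    if not ox:
        ox = [a.coords for a in asp_residue.atoms if a.element == "O"]
    if not ox:
        return None
    for n_idx in basic_amine_indices(ligand):
        npos = ligand.atoms[n_idx].coords
        dists = [float(np.linalg.norm(npos - o)) for o in ox]
        dmin = min(dists)
        if dmin <= criteria.saltbridge_max_dist:
            return FeatureHit(feature="salt_bridge_D351",
                              partner=asp_residue.label,
                              measured={"distance": dmin,
                                        "ligand_atom": n_idx})
    return None


def detect_pi_stack(ligand_ring: RingDescriptor, protein_ring: RingDescriptor,
                    criteria: GeometricCriteria | None = None,
                    feature: str = "pistack_F404",
                    partner: str = "PHE404") -> FeatureHit | None:
    """Ring-ring stack: centroid distance + interplanar angle window
    (inclusive bounds; the default window is T-shaped/near-perpendicular)."""
    criteria = criteria or GeometricCriteria()
    if len(ligand_ring.member_atoms) < 3 or len(protein_ring.member_atoms) < 3:
        raise ValueError("pi-stack detection requires ring descriptors")
    dist = float(np.linalg.norm(ligand_ring.centroid - protein_ring.centroid))
    if dist > criteria.ring_centroid_max_dist:
        return None
    cosang = abs(float(np.dot(ligand_ring.normal, protein_ring.normal)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    lo, hi = criteria.ring_interplanar_range
    if not (lo <= angle <= hi):
        return None
    return FeatureHit(feature=feature, partner=partner,
                      measured={"distance": dist, "interplanar_angle": angle})


# ---------------------------------------------------------------------------
# Ligand perception helpers
# ---------------------------------------------------------------------------

def hydroxyl_groups(ligand: MolecularStructure) -> list[HBondGroup]:
    """Ligand O-H groups (hydroxyls, including phenols and carboxylic OH)."""
    groups = []
    for idx, a in enumerate(ligand.atoms):
        if a.element != "O":
            continue
        hs = [n for n in ligand.neighbors(idx)
              if ligand.atoms[n].element == "H"]
        if hs:
            groups.append(HBondGroup(
                heavy=a.coords,
                hydrogens=[ligand.atoms[h].coords for h in hs],
                label=f"O{idx}", atom_index=idx))
    return groups


def acceptor_indices(ligand: MolecularStructure) -> list[int]:
    """Ligand hydrogen-bond acceptors: O and N heavy atoms (halogens are
    not treated as acceptors)."""
    return [i for i, a in enumerate(ligand.atoms) if a.element in ("O", "N")]


def donor_indices(ligand: MolecularStructure) -> list[int]:
    """Ligand donors: O/N atoms bearing at least one hydrogen."""
    out = []
    for idx, a in enumerate(ligand.atoms):
        if a.element not in ("O", "N"):
            continue
        if any(ligand.atoms[n].element == "H" for n in ligand.neighbors(idx)):
            out.append(idx)
    return out


def basic_amine_indices(ligand: MolecularStructure) -> list[int]:
    """Nitrogens protonatable at physiological pH: aliphatic amines.

    Excludes amides (N adjacent to a carbonyl carbon), aromatic-ring
    nitrogens and nitriles.  Aliphatic amines are assumed protonated at
    pH 7.4 (simple rule; no pKa prediction).
    """
    aromatic = set()
    for ring in aromatic_rings(ligand):
        aromatic.update(ring.member_atoms)
    out = []
    for idx, a in enumerate(ligand.atoms):
        if a.element != "N" or idx in aromatic:
            continue
        nbrs = ligand.neighbors(idx)
        orders = [o for i, j, o in ligand.bonds if idx in (i, j)]
        if any(o > 1 for o in orders):
            continue  # imine / nitrile / nitro
        amide = False
        for n in nbrs:
            if ligand.atoms[n].element != "C":
                continue
            for i, j, o in ligand.bonds:
                if o == 2 and n in (i, j):
                    other = j if i == n else i
                    if ligand.atoms[other].element == "O":
                        amide = True
        if not amide:
            out.append(idx)
    return out


def aromatic_rings(ligand: MolecularStructure) -> list[RingDescriptor]:
    """Planar 5/6-membered C/N rings of sp2 atoms, as ring descriptors."""
    out = []
    xyz = ligand.coords
    for ring in ligand.rings:
        if len(ring) not in (5, 6):
            continue
        if any(ligand.atoms[i].element not in ("C", "N") for i in ring):
            continue
        heavy_deg = [sum(1 for n in ligand.neighbors(i)
                         if ligand.atoms[n].element != "H") +
                     sum(1 for n in ligand.neighbors(i)
                         if ligand.atoms[n].element == "H")
                     for i in ring]
        if any(d > 3 for d in heavy_deg):
            continue  # sp3 center in ring
        coords = xyz[ring]
        desc = RingDescriptor.from_coords(ring, coords)
        rms = np.sqrt(np.mean(((coords - desc.centroid) @ desc.normal) ** 2))
        if rms < 0.15:
            out.append(desc)
    return out


# ---------------------------------------------------------------------------
# Composite features
# ---------------------------------------------------------------------------

def count_internal_hbonds(ligand: MolecularStructure,
                          criteria: GeometricCriteria | None = None) -> int:
    """Number of intramolecular hydrogen bonds (donor-acceptor pairs meeting
    the geometric criteria, excluding pairs fewer than 4 bonds apart)."""
    criteria = criteria or GeometricCriteria()
    import networkx as nx

    g = ligand.graph()
    count = 0
    for d_idx in donor_indices(ligand):
        hs = [n for n in ligand.neighbors(d_idx)
              if ligand.atoms[n].element == "H"]
        for a_idx in acceptor_indices(ligand):
            if a_idx == d_idx:
                continue
            try:
                sep = nx.shortest_path_length(g, d_idx, a_idx)
            except nx.NetworkXNoPath:
                sep = 99
            if sep < 4:
                continue
            dist = float(np.linalg.norm(ligand.atoms[d_idx].coords
                                        - ligand.atoms[a_idx].coords))
            if dist > criteria.hbond_max_dist:
                continue
            best = max(_angle_deg(ligand.atoms[d_idx].coords,
                                  ligand.atoms[h].coords,
                                  ligand.atoms[a_idx].coords) for h in hs)
            if best >= criteria.hbond_min_angle:
                count += 1
    return count


def check_aring_arrangement(ligand: MolecularStructure,
                            phe_ring: RingDescriptor,
                            glu_anchor: np.ndarray | None = None,
                            criteria: GeometricCriteria | None = None) -> bool:
    """A-ring arrangement: some ligand aromatic ring sits in the Phe404
    pincer (centroid distance + interplanar angle test, inclusive bounds).

    Ligands without an aromatic ring fail outright (an aromatic ring is an
    absolute requirement of the pocket).  ``glu_anchor`` only orders the
    candidate rings (nearest to the anchor tried first).
    """
    criteria = criteria or GeometricCriteria()
    rings = aromatic_rings(ligand)
    if not rings:
        return False
    if glu_anchor is not None:
        anchor = np.asarray(glu_anchor, float)
        rings.sort(key=lambda r: float(np.linalg.norm(r.centroid - anchor)))
    for ring in rings:
        if detect_pi_stack(ring, phe_ring, criteria) is not None:
            return True
    return False


def ligand_length(ligand: MolecularStructure) -> float:
    """Maximum heavy-atom pairwise distance, Angstrom."""
    heavy = ligand.heavy_indices()
    if len(heavy) < 2:
        raise ValueError("ligand length needs at least two heavy atoms")
    return float(pdist(ligand.coords[heavy]).max())


# ---------------------------------------------------------------------------
# His524 conformational classes and pose filtering
# ---------------------------------------------------------------------------

def _imidazole_nitrogens(his: PocketResidue) -> list[np.ndarray]:
    named = [a.coords for a in his.atoms if a.name in ("ND1", "NE2")]
    if named:
        return named
    return [a.coords for a in his.atoms
            if a.element == "N" and a.name != "N"]


def glu_anchor(pocket: list[PocketResidue]) -> np.ndarray | None:
    """Glu353 carboxylate centroid, the fixed end of the pocket."""
    for r in pocket:
        if r.res_name == "GLU" and r.seq_num == 353:
            ox = [a.coords for a in r.atoms if a.name in ("OE1", "OE2")]
            if not ox:
                ox = [a.coords for a in r.atoms if a.element == "O"]
            if ox:
                return np.mean(ox, axis=0)
    return None


def classify_his524(pocket: list[PocketResidue],
                    criteria: GeometricCriteria | None = None) -> str:
    """Classify the His524 side-chain conformation.

    Distance from the imidazole nitrogens to the Glu353 carboxylate anchor:
    within ``his524_closed_max`` the imidazole can hydrogen-bond a distal
    hydroxyl at the D-ring site (closed); between the cutoffs it is retracted
    (moved_back); beyond it extends the pocket (open).  Missing side chain or
    anchor gives ``unknown``.
    """
    criteria = criteria or GeometricCriteria()
    his = None
    for r in pocket:
        if r.res_name == "HIS" and r.seq_num == 524:
            his = r
            break
    if his is None:
        for r in pocket:
            if r.res_name == "HIS":
                his = r
                break
    if his is None:
        return UNKNOWN
    nitrogens = _imidazole_nitrogens(his)
    anchor = glu_anchor(pocket)
    if not nitrogens or anchor is None:
        return UNKNOWN
    dmin = min(float(np.linalg.norm(n - anchor)) for n in nitrogens)
    if dmin <= criteria.his524_closed_max:
        return CLOSED
    if dmin <= criteria.his524_movedback_max:
        return MOVED_BACK
    return OPEN


def pose_his524_filter(pose_ligand: MolecularStructure, receptor_class: str,
                       hits: list[FeatureHit],
                       criteria: GeometricCriteria | None = None) -> bool:
    """Accept a docked pose based on its geometric relationship with His524.

    The Glu353 hydrogen bond (HB1) is always required.  Then, per receptor
    class: closed -- a ligand whose second hydroxyl sits 10-12 A from the
    phenolic oxygen must realize the His524 bond (HB2); moved_back -- no HB2
    requirement; open -- the ligand must be longer than the open-pocket
    threshold.
    """
    criteria = criteria or GeometricCriteria()
    features = {h.feature for h in hits}
    if "hb_E353" not in features:
        return False
    if receptor_class == MOVED_BACK:
        return True
    if receptor_class == OPEN:
        return ligand_length(pose_ligand) > criteria.length_open_threshold
    # closed (and unknown treated conservatively like closed)
    phenol_idx = None
    for h in hits:
        if h.feature == "hb_E353":
            phenol_idx = h.measured.get("ligand_atom", None)
    ohs = hydroxyl_groups(pose_ligand)
    if phenol_idx is None and ohs:
        phenol_idx = ohs[0].atom_index
    if phenol_idx is None:
        return True
    lo, hi = criteria.hydroxyl_pair_range
    phenol_pos = pose_ligand.atoms[phenol_idx].coords
    has_distal = any(
        g.atom_index != phenol_idx
        and lo <= float(np.linalg.norm(g.heavy - phenol_pos)) <= hi
        for g in ohs)
    if has_distal:
        return "hb_H524" in features
    return True


# ---------------------------------------------------------------------------
# Whole-complex feature scan
# ---------------------------------------------------------------------------

def _residue_acceptor_groups(res: PocketResidue) -> list[HBondGroup]:
    """Side-chain acceptor atoms of the pocket residues the model knows."""
    side = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2"), "THR": ("OG1",),
            "HIS": ("ND1", "NE2"), "SER": ("OG",)}
    names = side.get(res.res_name, ())
    groups = [HBondGroup(heavy=a.coords, label=res.label)
              for a in res.atoms if a.name in names]
    if res.res_name == "LEU":
        groups += [HBondGroup(heavy=a.coords, label=res.label)
                   for a in res.atoms if a.name == "O"]
    return groups


def _residue_donor_groups(res: PocketResidue) -> list[HBondGroup]:
    """Side-chain donors (heavy atom + attached hydrogens by proximity)."""
    donors = {"HIS": ("ND1", "NE2"), "ARG": ("NE", "NH1", "NH2"),
              "THR": ("OG1",), "SER": ("OG",)}
    names = donors.get(res.res_name, ())
    groups = []
    h_atoms = [a for a in res.atoms if a.element == "H"]
    for a in res.atoms:
        if a.name not in names:
            continue
        hs = [h.coords for h in h_atoms
              if np.linalg.norm(h.coords - a.coords) < 1.25]
        if hs:
            groups.append(HBondGroup(heavy=a.coords, hydrogens=hs,
                                     label=res.label))
    return groups


def detect_features(cmplx: ComplexStructure,
                    criteria: GeometricCriteria | None = None
                    ) -> list[FeatureHit]:
    """Scan a complex for every candidate interaction feature.

    Returns hits for: Asp351 salt bridge, Glu353/Thr347/His524/Leu346/Arg394
    hydrogen bonds, the Phe404 T-stack and A-ring arrangement, and the ligand
    internal hydrogen-bond count (as an ``internal_hb`` hit with a ``count``
    measurement when non-zero).
    """
    criteria = criteria or GeometricCriteria()
    ligand = cmplx.ligand
    hits: list[FeatureHit] = []
    ohs = hydroxyl_groups(ligand)

    def first_hbond(res: PocketResidue, feature: str,
                    allow_accept: bool = False) -> FeatureHit | None:
        # ligand hydroxyl donating to a residue acceptor atom
        for g in ohs:
            for acc in _residue_acceptor_groups(res):
                hit = detect_hbond(g, acc, criteria, feature=feature,
                                   partner=res.label)
                if hit is not None:
                    return hit
        if allow_accept:
            # residue donating to a ligand oxygen acceptor
            for don in _residue_donor_groups(res):
                for g in ohs:
                    acc = HBondGroup(heavy=g.heavy, label="ligand",
                                     atom_index=g.atom_index)
                    hit = detect_hbond(don, acc, criteria, feature=feature,
                                       partner=res.label)
                    if hit is not None:
                        hit.measured["direction"] = "accept"
                        hit.measured["ligand_atom"] = g.atom_index
                        return hit
        return None

    res_map = {(r.res_name, r.seq_num): r for r in cmplx.pocket}

    glu = res_map.get(("GLU", 353))
    if glu is not None:
        hit = first_hbond(glu, "hb_E353")  # ligand donates to Glu353
        if hit:
            hits.append(hit)
    thr = res_map.get(("THR", 347))
    if thr is not None:
        hit = first_hbond(thr, "hb_T347", allow_accept=True)
        if hit:
            hits.append(hit)
    his = res_map.get(("HIS", 524))
    if his is not None:
        hit = first_hbond(his, "hb_H524", allow_accept=True)
        if hit:
            hits.append(hit)
    leu = res_map.get(("LEU", 346))
    if leu is not None:
        hit = first_hbond(leu, "hb_L346")
        if hit:
            hits.append(hit)
    arg = res_map.get(("ARG", 394))
    if arg is not None:
        for don in _residue_donor_groups(arg):
            got = None
            for g in ohs:
                acc = HBondGroup(heavy=g.heavy, label="ligand",
                                 atom_index=g.atom_index)
                got = detect_hbond(don, acc, criteria, feature="hb_R394",
                                   partner=arg.label)
                if got:
                    got.measured["direction"] = "accept"
                    hits.append(got)
                    break
            if got:
                break
    asp = res_map.get(("ASP", 351))
    if asp is not None:
        hit = detect_salt_bridge(ligand, asp, criteria)
        if hit:
            hits.append(hit)

    phe = res_map.get(("PHE", 404))
    if phe is not None:
        ring_atoms = [a for a in phe.atoms
                      if a.name in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")]
        if len(ring_atoms) >= 3:
            phe_ring = RingDescriptor.from_coords(
                list(range(len(ring_atoms))),
                np.array([a.coords for a in ring_atoms]))
            anchor = glu_anchor(cmplx.pocket)
            for lring in aromatic_rings(ligand):
                stack = detect_pi_stack(lring, phe_ring, criteria)
                if stack is not None:
                    hits.append(stack)
                    break
            if check_aring_arrangement(ligand, phe_ring, anchor, criteria):
                hits.append(FeatureHit(feature="aring_ok", partner="PHE404"))

    n_internal = count_internal_hbonds(ligand, criteria)
    if n_internal > 0:
        hits.append(FeatureHit(feature="internal_hb", partner="ligand",
                               measured={"count": n_internal}))
    return hits
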