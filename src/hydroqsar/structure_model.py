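"""Molecular structures, complexes and per-atom physical parameters.

Atoms carry the three physical quantities the hydrophobicity density field
needs: a van der Waals radius (surface construction), a net atomic charge
``q_i`` and an effective atomic polarizability ``alpha_i``.  Charges default
to the iterative partial-equalization-of-orbital-electronegativity scheme
(Gasteiger), polarizabilities and radii to additive per-element tables; all
three are pluggable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
from Bio.PDB import PDBParser
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

# Bondi van der Waals radii, Angstrom.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "He": 1.40, "Ne": 1.54, "Ar": 1.88,
}

# Additive atomic hybrid polarizabilities, Angstrom^3 (Miller-type table).
# Carbon is split by hybridization; other elements use a single value.
POLARIZABILITY_TABLE: dict[str, float] = {
    "H": 0.387,
    "C.sp3": 1.061, "C.sp2": 1.352, "C.sp": 1.283,
    "N": 0.964, "O": 0.637, "F": 0.296,
    "P": 1.538, "S": 2.700, "Cl": 2.315, "Br": 3.013, "I": 5.415,
    "He": 0.205, "Ne": 0.395, "Ar": 1.641,
}

# Covalent radii for geometric bond perception, Angstrom.
_COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# Hydrophobic residues lining the ERalpha ligand binding pocket, by residue
# name and sequence number (hERalpha LBD numbering).  Configurable everywhere
# it is consumed.
DEFAULT_HYDROPHOBIC_RESIDUES: tuple[str, ...] = (
    "MET343", "LEU346", "LEU349", "ALA350", "LEU384", "LEU387", "MET388",
    "LEU391", "PHE404", "VAL418", "MET421", "ILE424", "LEU428", "LEU525",
    "MET528",
)

# Residue names regarded as hydrophobic when a positional list is not used.
HYDROPHOBIC_RESIDUE_NAMES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "PRO", "TRP"}


class UnknownElementError(KeyError):
    """An element is missing from a parameter table."""


@dataclass
class AtomRecord:
    """One atom with coordinates and the physical parameters used downstream.

    ``partial_charge`` is in elementary charge units, ``polarizability`` in
    cubic Angstrom, coordinates and radii in Angstrom.
    """

    serial: int
    element: str
    coords: np.ndarray
    name: str = ""
    vdw_radius: float = float("nan")
    partial_charge: float = float("nan")
    polarizability: float = float("nan")
    is_polar_hydrogen: bool = False
    parent_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")


@dataclass
class MolecularStructure:
    """A ligand or molecular fragment: atoms, bonds and ring membership."""

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    rings: list[list[int]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n < 1:
            raise ValueError("structure must contain at least one atom")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"invalid bond ({i},{j}) for {n} atoms")

    # -- geometry ---------------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, c in zip(self.atoms, xyz):
            a.coords = c.copy()

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        """Apply the rigid-body map x -> R x + t to every atom in place."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        self.set_coords(self.coords @ R.T + t)

    def copy(self) -> "MolecularStructure":
        return MolecularStructure(
            atoms=[replace(a, coords=a.coords.copy()) for a in self.atoms],
            bonds=list(self.bonds),
            rings=[list(r) for r in self.rings],
            name=self.name,
        )

    # -- graph ------------------------------------------------------------
    def graph(self, heavy_only: bool = False) -> nx.Graph:
        g = nx.Graph()
        for idx, a in enumerate(self.atoms):
            if heavy_only and a.element == "H":
                continue
            g.add_node(idx, element=a.element)
        for i, j, order in self.bonds:
            if g.has_node(i) and g.has_node(j):
                g.add_edge(i, j, order=order)
        return g

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element != "H"]

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for i, j, _ in self.bonds:
            if i == idx:
                out.append(j)
            elif j == idx:
                out.append(i)
        return out

    def perceive_rings(self) -> None:
        """Populate ``rings`` with the minimum cycle basis of the bond graph."""
        g = self.graph()
        self.rings = [sorted(c) for c in nx.minimum_cycle_basis(g)]
        self.rings.sort()

    def flag_polar_hydrogens(self) -> None:
        for idx, a in enumerate(self.atoms):
            if a.element != "H":
                continue
            a.is_polar_hydrogen = any(
                self.atoms[n].element in ("N", "O", "S") for n in self.neighbors(idx)
            )


@dataclass
class PocketResidue:
    """A binding-pocket residue: identity plus its atoms."""

    res_name: str
    chain: str
    seq_num: int
    atoms: list[AtomRecord]
    hydrophobic: bool = False

    @property
    def label(self) -> str:
        return f"{self.res_name}{self.seq_num}"

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def atom_by_name(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for a in self.atoms:
            a.coords = R @ a.coords + t


@dataclass
class ComplexStructure:
    """A ligand posed in a receptor pocket, sharing one coordinate frame."""

    ligand: MolecularStructure
    pocket: list[PocketResidue]
    receptor_label: str = ""
    receptor_class: str = "unknown"

    def residue(self, label: str) -> PocketResidue | None:
        """Look up a pocket residue by 'LEU346'-style label or bare number."""
        for r in self.pocket:
            if r.label == label or str(r.seq_num) == str(label):
                return r
        return None

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        self.ligand.transform(rotation, translation)
        for r in self.pocket:
            r.transform(rotation, translation)


# ---------------------------------------------------------------------------
# Parameter assignment
# ---------------------------------------------------------------------------

def assign_radii(structure: MolecularStructure,
                 table: dict[str, float] | None = None) -> MolecularStructure:
    """Assign van der Waals radii from a per-element table (default Bondi)."""
    table = BONDI_RADII if table is None else table
    for a in structure.atoms:
        if a.element not in table:
            raise UnknownElementError(
                f"no van der Waals radius for element {a.element!r}")
        a.vdw_radius = table[a.element]
    return structure


def _carbon_hybridization(structure: MolecularStructure, idx: int) -> str:
    degree = len(structure.neighbors(idx))
    if degree >= 4:
        return "sp3"
    if degree == 3:
        return "sp2"
    return "sp"


def assign_polarizabilities(structure: MolecularStructure,
                            table: dict[str, float] | None = None
                            ) -> MolecularStructure:
    """Assign effective atomic polarizabilities alpha_i from an additive table.

    Carbon entries may be hybridization-resolved (``C.sp3``/``C.sp2``/``C.sp``,
    inferred from the bond graph degree); every other element uses one value.
    """
    table = POLARIZABILITY_TABLE if table is None else table
    for idx, a in enumerate(structure.atoms):
        key = a.element
        if key == "C" and "C.sp3" in table:
            key = f"C.{_carbon_hybridization(structure, idx)}"
        if key not in table and a.element in table:
            key = a.element
        if key not in table:
            raise UnknownElementError(
                f"no polarizability entry for element {a.element!r}")
        a.polarizability = table[key]
        if a.polarizability < 0:
            raise ValueError(f"polarizability for {key} must be non-negative")
    return structure


def _gasteiger_charges(structure: MolecularStructure) -> np.ndarray:
    mol = to_rdkit(structure)
    from rdkit.Chem import AllChem

    try:
        Chem.SanitizeMol(mol)
    except Exception:
        # tolerate odd valences from geometric bond perception
        mol.UpdatePropertyCache(strict=False)
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_FINDRADICALS
            | Chem.SanitizeFlags.SANITIZE_SETHYBRIDIZATION,
            catchErrors=True)

    AllChem.ComputeGasteigerCharges(mol, nIter=24, throwOnParamFailure=False)
    q = np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()], float)
    if not np.all(np.isfinite(q)):
        bad = {structure.atoms[i].element for i in np.where(~np.isfinite(q))[0]}
        raise UnknownElementError(
            f"charge scheme unparameterized for element(s): {sorted(bad)}")
    # Renormalize tiny iteration residue onto heavy atoms so the total equals
    # the formal molecular charge exactly.
    formal = float(Chem.GetFormalCharge(mol))
    q += (formal - q.sum()) / len(q)
    return q


ChargeScheme = Callable[[MolecularStructure], np.ndarray]

CHARGE_SCHEMES: dict[str, ChargeScheme] = {"gasteiger": _gasteiger_charges}


def assign_partial_charges(structure: MolecularStructure,
                           scheme: str | ChargeScheme = "gasteiger"
                           ) -> MolecularStructure:
    """Assign net atomic charges q_i using a pluggable scheme.

    The default is iterative partial equalization of orbital electronegativity
    (Gasteiger).  The assigned charges sum to the formal molecular charge to
    better than 1e-6 e.
    """
    fn = CHARGE_SCHEMES[scheme] if isinstance(scheme, str) else scheme
    charges = np.asarray(fn(structure), dtype=float)
    if charges.shape != (len(structure.atoms),):
        raise ValueError("charge scheme returned wrong-length vector")
    for a, q in zip(structure.atoms, charges):
        a.partial_charge = float(q)
    return structure


def parameterize(structure: MolecularStructure,
                 charge_scheme: str | ChargeScheme = "gasteiger",
                 radius_table: dict[str, float] | None = None,
                 polarizability_table: dict[str, float] | None = None
                 ) -> MolecularStructure:
    """Assign radii, charges and polarizabilities in one call."""
    assign_radii(structure, radius_table)
    assign_partial_charges(structure, charge_scheme)
    assign_polarizabilities(structure, polarizability_table)
    structure.flag_polar_hydrogens()
    return structure


# ---------------------------------------------------------------------------
# RDKit interconversion
# ---------------------------------------------------------------------------

_BOND_ORDERS = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                3: Chem.BondType.TRIPLE, 12: Chem.BondType.AROMATIC}


def to_rdkit(structure: MolecularStructure) -> Chem.Mol:
    """Build an RDKit molecule (explicit hydrogens, conformer attached)."""
    rw = Chem.RWMol()
    for a in structure.atoms:
        at = Chem.Atom(a.element)
        at.SetNoImplicit(True)
        rw.AddAtom(at)
    for i, j, order in structure.bonds:
        rw.AddBond(i, j, _BOND_ORDERS.get(order, Chem.BondType.SINGLE))
    mol = rw.GetMol()
    conf = Chem.Conformer(len(structure.atoms))
    for idx, a in enumerate(structure.atoms):
        conf.SetAtomPosition(idx, tuple(map(float, a.coords)))
    mol.AddConformer(conf, assignId=True)
    for at in mol.GetAtoms():
        at.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return mol


def from_rdkit(mol: Chem.Mol, name: str = "") -> MolecularStructure:
    """Convert an RDKit molecule (with a conformer) to a MolecularStructure."""
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no conformer (3D coordinates required)")
    conf = mol.GetConformer()
    atoms = []
    for at in mol.GetAtoms():
        p = conf.GetAtomPosition(at.GetIdx())
        atoms.append(AtomRecord(serial=at.GetIdx() + 1, element=at.GetSymbol(),
                                coords=np.array([p.x, p.y, p.z]),
                                name=at.GetSymbol() + str(at.GetIdx() + 1)))
    bonds = []
    for b in mol.GetBonds():
        order = {Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2,
                 Chem.BondType.TRIPLE: 3, Chem.BondType.AROMATIC: 12}.get(
                     b.GetBondType(), 1)
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    ri = mol.GetRingInfo()
    rings = [sorted(r) for r in ri.AtomRings()]
    st = MolecularStructure(atoms=atoms, bonds=bonds, rings=sorted(rings),
                            name=name or (mol.GetProp("_Name")
                                          if mol.HasProp("_Name") else ""))
    st.flag_polar_hydrogens()
    return st


# ---------------------------------------------------------------------------
# File input
# ---------------------------------------------------------------------------

def read_ligand_sdf(path: str | Path,
                    multi: bool = False
                    ) -> MolecularStructure | list[MolecularStructure]:
    """Read a ligand (or every record with ``multi=True``) from an SDF/MOL file.

    Explicit hydrogens are preserved; rings come from RDKit ring perception.
    """
    path = Path(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    structures = []
    for rec_no, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{path}: failed to parse SDF record {rec_no + 1}")
        mol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(mol)
        structures.append(from_rdkit(mol))
        if not multi:
            return structures[0]
    if not structures:
        raise ValueError(f"{path}: no molecules found")
    return structures


def perceive_bonds_by_distance(structure: MolecularStructure,
                               tolerance: float = 0.45) -> None:
    """Fill ``bonds`` with pairs closer than the sum of covalent radii + tol."""
    xyz = structure.coords
    bonds = []
    for i in range(len(structure.atoms)):
        ri = _COVALENT_RADII.get(structure.atoms[i].element, 0.77)
        for j in range(i + 1, len(structure.atoms)):
            rj = _COVALENT_RADII.get(structure.atoms[j].element, 0.77)
            if np.linalg.norm(xyz[i] - xyz[j]) <= ri + rj + tolerance:
                bonds.append((i, j, 1))
    structure.bonds = bonds
    structure.perceive_rings()


def _element_of(atom) -> str:
    el = (atom.element or "").strip()
    if not el:
        el = "".join(c for c in atom.get_name() if c.isalpha())[:1]
    return el.capitalize() if len(el) > 1 else el.upper()


def _pick_altloc(residue) -> list:
    """Flatten a Biopython residue to one atom per name, keeping the
    highest-occupancy alternate location (with a warning)."""
    out = []
    for atom in residue.get_unpacked_list():
        out.append(atom)
    by_name: dict[str, list] = {}
    for atom in out:
        by_name.setdefault(atom.get_name(), []).append(atom)
    picked = []
    for name, group in by_name.items():
        if len(group) > 1:
            group.sort(key=lambda a: -(a.get_occupancy() or 0.0))
            warnings.warn(
                f"altloc conflict for atom {name}: keeping highest occupancy")
        picked.append(group[0])
    picked.sort(key=lambda a: a.get_serial_number())
    return picked


def _parse_conect(path: Path) -> dict[int, set[int]]:
    table: dict[int, set[int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("CONECT"):
                continue
            fields = [line[i:i + 5].strip() for i in range(6, 31, 5)]
            nums = [int(f) for f in fields if f]
            if not nums:
                continue
            center = nums[0]
            table.setdefault(center, set()).update(nums[1:])
    return table


def read_pdb_complex(path: str | Path, ligand_code: str,
                     pocket_radius: float = 6.0,
                     receptor_label: str = "") -> ComplexStructure:
    """Read a receptor-ligand complex from a PDB file.

    The ligand is the HETATM residue matching ``ligand_code``; its bonds come
    from CONECT records when present, otherwise from covalent-radius geometry.
    The pocket is every non-water residue with at least one atom within
    ``pocket_radius`` of a ligand heavy atom.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    model = next(iter(structure))

    ligand_res = None
    het_codes = set()
    protein_residues = []
    for chain in model:
        for res in chain:
            hetflag = res.id[0]
            resname = res.get_resname().strip()
            if resname in _WATER_NAMES or hetflag == "W":
                continue
            if hetflag != " ":
                het_codes.add(resname)
                if resname == ligand_code and ligand_res is None:
                    ligand_res = (chain.id, res)
                    continue
            protein_residues.append((chain.id, res))
    if ligand_res is None:
        raise ValueError(
            f"{path}: ligand code {ligand_code!r} not found; "
            f"available het codes: {sorted(het_codes) or 'none'}")

    chain_id, res = ligand_res
    lig_atoms = []
    serial_to_idx = {}
    for atom in _pick_altloc(res):
        idx = len(lig_atoms)
        serial = atom.get_serial_number()
        serial_to_idx[serial] = idx
        lig_atoms.append(AtomRecord(
            serial=serial, element=_element_of(atom),
            coords=np.array(atom.get_coord(), float),
            name=atom.get_name(), parent_id=f"{ligand_code}"))
    ligand = MolecularStructure(atoms=lig_atoms, name=ligand_code)

    conect = _parse_conect(path)
    bonds = set()
    for serial, partners in conect.items():
        if serial in serial_to_idx:
            for p in partners:
                if p in serial_to_idx:
                    i, j = sorted((serial_to_idx[serial], serial_to_idx[p]))
                    bonds.add((i, j))
    if bonds:
        ligand.bonds = [(i, j, 1) for i, j in sorted(bonds)]
        ligand.perceive_rings()
    else:
        perceive_bonds_by_distance(ligand)
    ligand.flag_polar_hydrogens()

    lig_xyz = np.array([a.coords for a in ligand.atoms
                        if a.element != "H"], float)
    if lig_xyz.size == 0:
        lig_xyz = ligand.coords
    pocket = []
    for ch, res in protein_residues:
        atoms = _pick_altloc(res)
        xyz = np.array([a.get_coord() for a in atoms], float)
        d = np.linalg.norm(xyz[:, None, :] - lig_xyz[None, :, :], axis=-1)
        if d.min() <= pocket_radius:
            recs = [AtomRecord(serial=a.get_serial_number(),
                               element=_element_of(a),
                               coords=np.array(a.get_coord(), float),
                               name=a.get_name(),
                               parent_id=f"{res.get_resname().strip()}{res.id[1]}")
                    for a in atoms]
            pr = PocketResidue(res_name=res.get_resname().strip(), chain=ch,
                               seq_num=res.id[1], atoms=recs)
            pr.hydrophobic = (pr.label in DEFAULT_HYDROPHOBIC_RESIDUES
                              or pr.res_name in HYDROPHOBIC_RESIDUE_NAMES)
            pocket.append(pr)
    pocket.sort(key=lambda r: (r.chain, r.seq_num))
    return ComplexStructure(ligand=ligand, pocket=pocket,
                            receptor_label=receptor_label or path.stem)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_complex_pdb(cmplx: ComplexStructure, path: str | Path) -> None:
    """Write a complex back out as PDB (ATOM for pocket, HETATM + CONECT
    for the ligand)."""
    lines = []
    serial = 0
    for res in cmplx.pocket:
        for a in res.atoms:
            serial += 1
            lines.append(_pdb_line("ATOM", serial, a.name or a.element,
                                   res.res_name, res.chain, res.seq_num,
                                   a.coords, a.element))
    lig_serials = {}
    for idx, a in enumerate(cmplx.ligand.atoms):
        serial += 1
        lig_serials[idx] = serial
        lines.append(_pdb_line("HETATM", serial, a.name or a.element,
                               cmplx.ligand.name[:3].upper() or "LIG", "X",
                               900, a.coords, a.element))
    adj: dict[int, list[int]] = {}
    for i, j, _ in cmplx.ligand.bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    for i in sorted(adj):
        partners = sorted(lig_serials[j] for j in adj[i])
        for k in range(0, len(partners), 4):
            chunk = partners[k:k + 4]
            lines.append("CONECT%5d" % lig_serials[i]
                         + "".join("%5d" % p for p in chunk))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _pdb_line(record: str, serial: int, name: str, resname: str, chain: str,
              seqnum: int, coords: np.ndarray, element: str) -> str:
    name_field = name if len(name) >= 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:>5d} {name_field[:4]:<4s}"
            f"{resname:>4s} {chain:1s}{seqnum:>4d}    "
            f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")


# ---------------------------------------------------------------------------
# Pocket utilities
# ---------------------------------------------------------------------------

def extract_hydrophobic_pocket(cmplx: ComplexStructure,
                               residue_list: Iterable[str] | None = None
                               ) -> list[PocketResidue]:
    """Return the pocket residues counted as hydrophobic, in stable order.

    ``residue_list`` entries may be residue names (``"LEU"``), full labels
    (``"PHE404"``) or bare sequence numbers (``"404"``/``404``); ``None``
    uses the default ERalpha pocket list.
    """
    entries = (set(DEFAULT_HYDROPHOBIC_RESIDUES) if residue_list is None
               else {str(e).upper() for e in residue_list})
    out = []
    for r in cmplx.pocket:
        if (r.label in entries or r.res_name in entries
                or str(r.seq_num) in entries):
            r.hydrophobic = True
            out.append(r)
    out.sort(key=lambda r: (r.chain, r.seq_num))
    if not out:
        warnings.warn("no hydrophobic residues in pocket: log P_C will be 0")
    return out


def complete_nonpolar_hydrogens(structure: MolecularStructure,
                                ch_length: float = 1.09) -> MolecularStructure:
    """Add missing hydrogens on carbons by standard geometry.

    Docking engines often merge non-polar hydrogens onto heavy atoms, which
    corrupts the surface hydrophobicity integral; this restores them at
    idealized positions pointing away from existing neighbors.
    """
    st = structure.copy()
    target_valence = {"C": 4}
    for idx in list(range(len(st.atoms))):
        a = st.atoms[idx]
        want = target_valence.get(a.element)
        if want is None:
            continue
        nbrs = st.neighbors(idx)
        order_sum = sum(o for i, j, o in st.bonds if idx in (i, j))
        deficit = want - order_sum
        if deficit <= 0:
            continue
        dirs = _hydrogen_directions(a.coords,
                                    [st.atoms[n].coords for n in nbrs], deficit)
        for d in dirs:
            h = AtomRecord(serial=len(st.atoms) + 1, element="H",
                           coords=a.coords + ch_length * d,
                           name=f"H{len(st.atoms)+1}", parent_id=a.parent_id)
            st.atoms.append(h)
            st.bonds.append((idx, len(st.atoms) - 1, 1))
    st.flag_polar_hydrogens()
    return st


def _hydrogen_directions(center: np.ndarray, nbr_coords: list[np.ndarray],
                         count: int) -> list[np.ndarray]:
    """Unit directions for new hydrogens, repelled from existing substituents."""
    if not nbr_coords:
        base = np.array([[1.0, 0, 0], [-1/3, 2*np.sqrt(2)/3, 0],
                         [-1/3, -np.sqrt(2)/3, np.sqrt(6)/3],
                         [-1/3, -np.sqrt(2)/3, -np.sqrt(6)/3]])
        return [base[i] for i in range(count)]
    units = [(c - center) / np.linalg.norm(c - center) for c in nbr_coords]
    out = []
    anti = -np.sum(units, axis=0)
    if np.linalg.norm(anti) < 1e-8:
        # symmetric substituents: pick any perpendicular
        ref = units[0]
        anti = np.cross(ref, [0.0, 0.0, 1.0])
        if np.linalg.norm(anti) < 1e-8:
            anti = np.cross(ref, [0.0, 1.0, 0.0])
    anti = anti / np.linalg.norm(anti)
    out.append(anti)
    if count > 1:
        # tetrahedral fan around the anti direction
        perp = np.cross(anti, units[0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(anti, [1.0, 0.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        tetra = np.deg2rad(109.47)
        for k in range(count - 1):
            phi = 2 * np.pi * (k + 1) / max(count, 2)
            d = (np.cos(tetra) * anti
                 + np.sin(tetra) * (np.cos(phi) * perp
                                    + np.sin(phi) * np.cross(anti, perp)))
            out.append(d / np.linalg.norm(d))
    return out[:count]
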