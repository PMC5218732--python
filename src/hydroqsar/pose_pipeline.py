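"""Consensus selection and QSAR ranking of externally docked poses.

Docking is repeated independently (typically 10 runs); conformations
observed three or more times (pairwise RMSD below 1.0 A, computed in the
common receptor frame without superposition) are taken as candidates of the
bioactive conformation.  Candidates are filtered by the His524 geometric
rules and the A-ring arrangement, scored by the QSAR model, and ranked by
predicted RBA.  Receptor structures are chosen per His524 class by
topological-fingerprint Tanimoto similarity between the query ligand and
each receptor's co-crystallized ligand.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from hydroqsar.pharmacophore import (
    GeometricCriteria,
    RingDescriptor,
    check_aring_arrangement,
    detect_features,
    glu_anchor,
    pose_his524_filter,
)
from hydroqsar.qsar import (
    Prediction,
    QsarModel,
    build_fingerprint,
    predict_log_rba,
    published_model,
)
from hydroqsar.structure_model import (
    AtomRecord,
    ComplexStructure,
    MolecularStructure,
    assign_polarizabilities,
    assign_partial_charges,
    assign_radii,
    complete_nonpolar_hydrogens,
    from_rdkit,
    to_rdkit,
)
from hydroqsar.surface_field import (
    FieldCoefficients,
    assign_contact_residues,
    compute_logpc,
    evaluate_grid,
    generate_sas_grid,
)


@dataclass
class DockedPose:
    """One docked ligand conformation in the receptor frame."""

    run_index: int
    conformer: MolecularStructure
    source_receptor: str = ""
    engine_score: float | None = None


@dataclass
class PoseCluster:
    """Consensus group of docked poses."""

    members: list[DockedPose]
    representative: DockedPose
    predicted: Prediction | None = None

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClusterConfig:
    """Consensus-clustering settings."""

    rmsd_threshold: float = 1.0
    min_count: int = 3
    runs_expected: int = 10
    symmetry_aware: bool = True

    def __post_init__(self) -> None:
        if self.rmsd_threshold <= 0:
            raise ValueError("rmsd_threshold must be positive")
        if self.min_count < 1:
            raise ValueError("min_count must be at least 1")


@dataclass
class ReceptorLibraryEntry:
    """A receptor structure with its co-crystallized ligand and His524 class."""

    receptor: ComplexStructure
    cocrystal_ligand: MolecularStructure
    receptor_class: str


# ---------------------------------------------------------------------------
# Pose ingestion
# ---------------------------------------------------------------------------

def _match_to_template(pose: MolecularStructure,
                       template: MolecularStructure,
                       source: str) -> MolecularStructure:
    """Canonicalize pose atom order to the template; re-add merged non-polar
    hydrogens from standard geometry when the engine stripped them."""
    t_heavy = [template.atoms[i].element for i in template.heavy_indices()]
    p_heavy_idx = pose.heavy_indices()
    p_heavy = [pose.atoms[i].element for i in p_heavy_idx]
    if p_heavy != t_heavy:
        raise ValueError(
            f"{source}: pose heavy atoms {p_heavy} do not match template "
            f"{t_heavy}")
    # heavy atoms in file order map onto template heavy atoms in order
    out_atoms: list[AtomRecord] = []
    heavy_map: dict[int, int] = {}
    for new_idx, (t_idx, p_idx) in enumerate(
            zip(template.heavy_indices(), p_heavy_idx)):
        a = pose.atoms[p_idx]
        heavy_map[t_idx] = new_idx
        out_atoms.append(AtomRecord(serial=new_idx + 1, element=a.element,
                                    coords=a.coords.copy(),
                                    name=template.atoms[t_idx].name))
    st = MolecularStructure(atoms=out_atoms, name=template.name)
    # heavy-heavy bonds from the template graph
    bonds = []
    for i, j, order in template.bonds:
        if i in heavy_map and j in heavy_map:
            bonds.append((heavy_map[i], heavy_map[j], order))
    st.bonds = bonds
    # attach hydrogens: prefer pose hydrogens when present, else rebuild
    pose_h = [i for i, a in enumerate(pose.atoms) if a.element == "H"]
    template_h = [i for i, a in enumerate(template.atoms) if a.element == "H"]
    if len(pose_h) == len(template_h):
        inv_heavy = {p: h for h, p in zip(
            [heavy_map[t] for t in template.heavy_indices()], p_heavy_idx)}
        for t_h, p_h in zip(template_h, pose_h):
            a = pose.atoms[p_h]
            new_idx = len(st.atoms)
            st.atoms.append(AtomRecord(serial=new_idx + 1, element="H",
                                       coords=a.coords.copy(),
                                       name=template.atoms[t_h].name))
            parents = pose.neighbors(p_h)
            if parents and parents[0] in inv_heavy:
                st.bonds.append((inv_heavy[parents[0]], new_idx, 1))
    else:
        st = complete_nonpolar_hydrogens(st)
    st.perceive_rings()
    st.flag_polar_hydrogens()
    return st


def _read_pdbqt_models(path: Path) -> list[MolecularStructure]:
    """Minimal PDBQT pose reader: coordinates + element per MODEL."""
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                current = []
            elif line.startswith("ENDMDL"):
                if current:
                    models.append(current)
                current = []
            elif line.startswith(("ATOM", "HETATM")):
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                atype = line[77:79].strip() or line[12:16].strip()
                el = atype.rstrip("AD").capitalize() or "C"
                if el in ("Oa", "Na", "Sa"):
                    el = el[0]
                current.append(AtomRecord(serial=len(current) + 1, element=el,
                                          coords=np.array([x, y, z])))
    if current:
        models.append(current)
    out = []
    for atoms in models:
        st = MolecularStructure(atoms=atoms, name=path.stem)
        out.append(st)
    return out


def load_poses(paths, ligand_template: MolecularStructure) -> list[DockedPose]:
    """Load docked poses from multi-model SDF or PDBQT files.

    Files are treated as independent runs in sorted order; atom order is
    canonicalized against the template ligand graph.  Empty files give zero
    poses with a warning.
    """
    from rdkit import Chem

    poses: list[DockedPose] = []
    for run_index, p in enumerate(sorted(Path(x) for x in paths)):
        if p.suffix.lower() == ".pdbqt":
            raw = _read_pdbqt_models(p)
            for st in raw:
                conf = _match_to_template(st, ligand_template, str(p))
                poses.append(DockedPose(run_index=run_index, conformer=conf,
                                        source_receptor=p.stem))
            if not raw:
                warnings.warn(f"{p}: no poses found")
            continue
        supplier = Chem.SDMolSupplier(str(p), removeHs=False, sanitize=False)
        n_before = len(poses)
        for rec_no, mol in enumerate(supplier):
            if mol is None:
                raise ValueError(f"{p}: unreadable SDF record {rec_no + 1}")
            mol.UpdatePropertyCache(strict=False)
            Chem.FastFindRings(mol)
            st = from_rdkit(mol)
            conf = _match_to_template(st, ligand_template, f"{p}#{rec_no + 1}")
            score = None
            if mol.HasProp("score"):
                score = float(mol.GetProp("score"))
            poses.append(DockedPose(run_index=run_index, conformer=conf,
                                    source_receptor=p.stem,
                                    engine_score=score))
        if len(poses) == n_before:
            warnings.warn(f"{p}: no poses found")
    return poses


# ---------------------------------------------------------------------------
# RMSD and clustering
# ---------------------------------------------------------------------------

def _graph_automorphisms(mol: MolecularStructure,
                         limit: int = 5000) -> list[dict[int, int]]:
    g = mol.graph(heavy_only=True)
    gm = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"])
    autos = []
    for mapping in gm.isomorphisms_iter():
        autos.append(mapping)
        if len(autos) >= limit:
            break
    return autos


def heavy_atom_rmsd(a: DockedPose | MolecularStructure,
                    b: DockedPose | MolecularStructure,
                    symmetry_aware: bool = True) -> float:
    """Heavy-atom RMSD in the shared receptor frame (no superposition).

    With ``symmetry_aware`` the minimum over element-preserving graph
    automorphisms of the ligand is returned, so topologically equivalent
    atoms (e.g. a flipped benzene) do not inflate the deviation.
    """
    ma = a.conformer if isinstance(a, DockedPose) else a
    mb = b.conformer if isinstance(b, DockedPose) else b
    ha = ma.heavy_indices()
    hb = mb.heavy_indices()
    if [ma.atoms[i].element for i in ha] != [mb.atoms[i].element for i in hb]:
        raise ValueError("poses have different ligand graphs")
    xa = ma.coords[ha]
    xb = mb.coords[hb]
    plain = float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
    if not symmetry_aware:
        return plain
    pos_a = {idx: k for k, idx in enumerate(ha)}
    pos_b = {idx: k for k, idx in enumerate(hb)}
    best = plain
    for mapping in _graph_automorphisms(ma):
        perm = np.empty(len(ha), dtype=int)
        ok = True
        for src, dst in mapping.items():
            if src not in pos_a or dst not in pos_b:
                ok = False
                break
            perm[pos_a[src]] = pos_b[dst]
        if not ok:
            continue
        r = float(np.sqrt(np.mean(np.sum((xa - xb[perm]) ** 2, axis=1))))
        best = min(best, r)
    return best


def _pose_sort_key(p: DockedPose):
    score = p.engine_score if p.engine_score is not None else np.inf
    return (score, p.run_index)


def cluster_poses(poses: list[DockedPose],
                  config: ClusterConfig | None = None) -> list[PoseCluster]:
    """Greedy leader clustering of poses in deterministic order.

    Poses are sorted by engine score (best first) then run index; the first
    unassigned pose seeds a cluster and every later pose joins the first
    cluster whose leader it matches within the RMSD threshold.  Clusters
    reaching ``min_count`` members are consensus candidates.
    """
    if not poses:
        raise ValueError("no poses to cluster")
    config = config or ClusterConfig()
    ordered = sorted(poses, key=_pose_sort_key)
    clusters: list[PoseCluster] = []
    for pose in ordered:
        placed = False
        for cl in clusters:
            if heavy_atom_rmsd(pose, cl.representative,
                               config.symmetry_aware) < config.rmsd_threshold:
                cl.members.append(pose)
                placed = True
                break
        if not placed:
            clusters.append(PoseCluster(members=[pose], representative=pose))
    for cl in clusters:
        # leader has best engine score already (sorted); medoid fallback
        if all(m.engine_score is None for m in cl.members) and cl.count > 2:
            coords = [m.conformer.coords[m.conformer.heavy_indices()]
                      for m in cl.members]
            sums = [sum(float(np.sqrt(np.mean(np.sum((c - d) ** 2, axis=1))))
                        for d in coords) for c in coords]
            cl.representative = cl.members[int(np.argmin(sums))]
    clusters.sort(key=lambda c: (-c.count, _pose_sort_key(c.representative)))
    return clusters


def candidate_clusters(clusters: list[PoseCluster],
                       config: ClusterConfig | None = None
                       ) -> list[PoseCluster]:
    """The consensus candidates: clusters observed ``min_count`` or more times."""
    config = config or ClusterConfig()
    return [c for c in clusters if c.count >= config.min_count]


def brute_force_candidates(poses: list[DockedPose],
                           config: ClusterConfig | None = None) -> bool:
    """Exhaustive oracle: does any subset of >= min_count poses share a
    representative within the RMSD threshold?  (Test cross-check for the
    greedy clustering; exponential, use on small pose sets only.)"""
    config = config or ClusterConfig()
    n = len(poses)
    for leader in range(n):
        close = [j for j in range(n)
                 if heavy_atom_rmsd(poses[j], poses[leader],
                                    config.symmetry_aware)
                 < config.rmsd_threshold]
        if len(close) >= config.min_count:
            return True
    return False


# ---------------------------------------------------------------------------
# Scoring and ranking
# ---------------------------------------------------------------------------

@dataclass
class RankedCandidate:
    cluster: PoseCluster
    fingerprint: object
    prediction: Prediction
    rank: int
    passed_filter: bool = True


def score_pose_complex(cmplx: ComplexStructure,
                       model: QsarModel | None = None,
                       criteria: GeometricCriteria | None = None,
                       coeffs: FieldCoefficients | None = None,
                       probe_radius: float = 1.4,
                       density: float = 4.0):
    """Full per-complex scoring: features -> surface field -> fingerprint
    -> predicted log RBA.  Returns (hits, fingerprint, prediction, logpc)."""
    model = model or published_model()
    criteria = criteria or GeometricCriteria()
    ligand = cmplx.ligand
    if not all(np.isfinite(a.vdw_radius) for a in ligand.atoms):
        assign_radii(ligand)
    if not all(np.isfinite(a.partial_charge) for a in ligand.atoms):
        assign_partial_charges(ligand)
    if not all(np.isfinite(a.polarizability) for a in ligand.atoms):
        assign_polarizabilities(ligand)
    hits = detect_features(cmplx, criteria)
    grid = generate_sas_grid(ligand, probe_radius=probe_radius,
                             density=density)
    evaluate_grid(grid, ligand, coeffs)
    assign_contact_residues(grid, cmplx.pocket)
    logpc = compute_logpc(grid, cmplx.pocket)
    fp = build_fingerprint(hits, logpc)
    pred = predict_log_rba(fp, model)
    return hits, fp, pred, logpc


def rank_candidates(clusters: list[PoseCluster], receptor: ComplexStructure,
                    model: QsarModel | None = None,
                    criteria: GeometricCriteria | None = None,
                    config: ClusterConfig | None = None,
                    coeffs: FieldCoefficients | None = None,
                    density: float = 4.0) -> list[RankedCandidate]:
    """Filter, score and rank consensus candidates by predicted log RBA.

    Representatives failing the His524 pose filter or the A-ring arrangement
    are dropped (reported with ``passed_filter=False``, rank 0).  Survivors
    are sorted by descending prediction; ties break by cluster count then
    representative sort order.  An empty survivor list is the "not
    identified" outcome.
    """
    model = model or published_model()
    criteria = criteria or GeometricCriteria()
    config = config or ClusterConfig()
    cands = candidate_clusters(clusters, config)
    if not cands:
        warnings.warn("no consensus candidates (all clusters below min count)")
        return []
    receptor_class = receptor.receptor_class
    if receptor_class in ("", "unknown"):
        from hydroqsar.pharmacophore import classify_his524
        receptor_class = classify_his524(receptor.pocket, criteria)
    results: list[RankedCandidate] = []
    for cl in cands:
        pose_complex = ComplexStructure(
            ligand=cl.representative.conformer.copy(),
            pocket=receptor.pocket,
            receptor_label=receptor.receptor_label,
            receptor_class=receptor_class)
        hits, fp, pred, _ = score_pose_complex(
            pose_complex, model, criteria, coeffs, density=density)
        ok = pose_his524_filter(pose_complex.ligand, receptor_class, hits,
                                criteria)
        if ok:
            ok = any(h.feature == "aring_ok" for h in hits)
        results.append(RankedCandidate(cluster=cl, fingerprint=fp,
                                       prediction=pred, rank=0,
                                       passed_filter=bool(ok)))
    survivors = [r for r in results if r.passed_filter]
    survivors.sort(key=lambda r: (-r.prediction.log_rba, -r.cluster.count,
                                  _pose_sort_key(r.cluster.representative)))
    for rank, r in enumerate(survivors, start=1):
        r.rank = rank
    if not survivors:
        warnings.warn("all consensus candidates removed by geometric filters "
                      "(NI outcome)")
    return survivors + [r for r in results if not r.passed_filter]


# ---------------------------------------------------------------------------
# Topological similarity and receptor selection
# ---------------------------------------------------------------------------

def topo_fingerprint(mol: MolecularStructure, n_bits: int = 2048,
                     max_path: int = 7) -> np.ndarray:
    """Deterministic path-based hashed topological fingerprint (boolean)."""
    from rdkit.Chem import rdmolops

    rd = to_rdkit(mol)
    bv = rdmolops.RDKFingerprint(rd, maxPath=max_path, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=bool)
    for bit in bv.GetOnBits():
        arr[bit] = True
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a & b| / |a | b|; 1.0 when both sets are empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint widths differ")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(a & b) / union)


def select_receptors(query: MolecularStructure,
                     library: list[ReceptorLibraryEntry]
                     ) -> dict[str, ReceptorLibraryEntry]:
    """Pick, per His524 class, the receptor whose co-crystallized ligand is
    most similar to the query (Tanimoto on topological fingerprints; ties
    break lexicographically on receptor label)."""
    qfp = topo_fingerprint(query)
    chosen: dict[str, ReceptorLibraryEntry] = {}
    for cls in ("closed", "moved_back", "open"):
        entries = [e for e in library if e.receptor_class == cls]
        if not entries:
            warnings.warn(f"receptor library has no entry of class {cls!r}")
            continue
        scored = [(-tanimoto(qfp, topo_fingerprint(e.cocrystal_ligand)),
                   e.receptor.receptor_label, i)
                  for i, e in enumerate(entries)]
        scored.sort()
        chosen[cls] = entries[scored[0][2]]
    return chosen
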