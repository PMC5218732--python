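"""Empirical hydrophobicity density field on the ligand solvent-accessible
surface, and its integral over hydrophobic contact points (log P_C).

The ligand is described by a grid on its SAS (van der Waals spheres inflated
by a probe radius).  At each grid point j the hydrophobicity density is

    log P_j = C1 |sum_i q_i / r_ij^2| + C2 sum_i q_i^2 / r_ij^3
            + C3 sum_i alpha_i / r_ij^3 + C4 sum_i alpha_i / r_ij^6 + C_cav

over the N_A ligand atoms, with net atomic charges q_i and effective atomic
polarizabilities alpha_i.  Points with log P_j > 0 are hydrophobic.  The
hydrophobic contact score log P_C integrates hydrophobic grid points lying
inside the van der Waals surface of hydrophobic pocket residues:

    log P_C = sum_k sum_{j in C_k, log P_j > 0} log P_j * w_j

where C_k collects contact points of the k-th hydrophobic residue and w_j is
the point's surface area weight (a ``raw_sum`` switch drops the weight and
reproduces a bare point count sum, which scales with grid density).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from hydroqsar.structure_model import (
    BONDI_RADII,
    MolecularStructure,
    PocketResidue,
)


@dataclass(frozen=True)
class FieldCoefficients:
    """Empirical solvent-effect coefficients of the hydrophobicity field.

    Defaults are the published G-SFED-derived values; they are constants of
    the method, not fitting parameters of this package.
    """

    C1: float = -8.85e-2
    C2: float = -1.45e-1
    C3: float = 1.57e-2
    C4: float = -4.88e-1
    Ccav: float = 2.34e-3


@dataclass
class SurfacePoint:
    """One SAS grid point with its hydrophobicity density and contacts."""

    coords: np.ndarray
    parent_atom: int
    area_weight: float
    logp: float = float("nan")
    contact_residues: set = field(default_factory=set)

    @property
    def hydrophobic(self) -> bool:
        return self.logp > 0.0


class SurfaceGrid:
    """SAS grid stored as flat arrays (one row per accessible point)."""

    def __init__(self, coords: np.ndarray, parent_atom: np.ndarray,
                 area_weight: np.ndarray, probe_radius: float,
                 density: float, ligand_ref: str = ""):
        self.coords = np.asarray(coords, float).reshape(-1, 3)
        self.parent_atom = np.asarray(parent_atom, int)
        self.area_weight = np.asarray(area_weight, float)
        self.probe_radius = float(probe_radius)
        self.density = float(density)
        self.ligand_ref = ligand_ref
        n = len(self.coords)
        self.logp = np.full(n, np.nan)
        self.contacts: list[set[str]] = [set() for _ in range(n)]

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def total_area(self) -> float:
        return float(self.area_weight.sum())

    @property
    def points(self) -> list[SurfacePoint]:
        return [SurfacePoint(coords=self.coords[i],
                             parent_atom=int(self.parent_atom[i]),
                             area_weight=float(self.area_weight[i]),
                             logp=float(self.logp[i]),
                             contact_residues=self.contacts[i])
                for i in range(len(self))]


# ---------------------------------------------------------------------------
# Grid construction
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere tessellation (n x 3)."""
    k = np.arange(n, dtype=float)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def canonical_frame(xyz: np.ndarray) -> np.ndarray:
    """Rotation matrix of the principal-axis frame with a deterministic
    sign convention (third-moment positive, right-handed)."""
    xyz = np.asarray(xyz, float)
    centered = xyz - xyz.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # descending variance
    for col in range(3):
        proj = centered @ vecs[:, col]
        skew = np.sum(proj ** 3)
        if abs(skew) < 1e-9:
            # symmetric distribution: fix sign by largest-magnitude component
            comp = vecs[:, col]
            lead = np.argmax(np.abs(comp))
            skew = comp[lead]
        if skew < 0:
            vecs[:, col] = -vecs[:, col]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return vecs


def generate_sas_grid(ligand: MolecularStructure, probe_radius: float = 1.4,
                      density: float = 4.0) -> SurfaceGrid:
    """Tessellate the ligand SAS with a deterministic per-atom point set.

    Each atom gets a Fibonacci-sphere shell of radius r_vdW + probe with
    ~``density`` points per square Angstrom; points buried inside another
    atom's SAS sphere are removed.  Shell orientations are tied to the
    ligand's principal-axis frame so the grid co-rotates rigidly with the
    molecule and surface integrals are frame-invariant.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    atoms = ligand.atoms
    if not atoms:
        raise ValueError("ligand has no atoms")
    radii = np.array([a.vdw_radius for a in atoms], float)
    if not np.all(np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError("van der Waals radii must be assigned before "
                         "surface generation")
    centers = ligand.coords
    shell_r = radii + probe_radius
    frame = canonical_frame(centers) if len(atoms) > 1 else np.eye(3)

    eps = 1e-9
    pts, parents, weights = [], [], []
    for i, (c, R) in enumerate(zip(centers, shell_r)):
        n = max(12, int(math.ceil(density * 4.0 * np.pi * R * R)))
        dirs = _fibonacci_sphere(n) @ frame.T
        shell = c + R * dirs
        keep = np.ones(n, dtype=bool)
        for k, (ck, Rk) in enumerate(zip(centers, shell_r)):
            if k == i:
                continue
            d = np.linalg.norm(shell - ck, axis=1)
            buried = d < Rk - eps
            # coincident spheres: the lower-indexed atom owns the shared shell
            if k < i:
                buried |= np.abs(d - Rk) <= eps
            keep &= ~buried
        w = 4.0 * np.pi * R * R / n
        pts.append(shell[keep])
        parents.append(np.full(int(keep.sum()), i))
        weights.append(np.full(int(keep.sum()), w))

    grid = SurfaceGrid(np.vstack(pts), np.concatenate(parents),
                       np.concatenate(weights), probe_radius, density,
                       ligand_ref=ligand.name)
    return grid


# ---------------------------------------------------------------------------
# Field evaluation
# ---------------------------------------------------------------------------

def logp_density(ligand: MolecularStructure, point: np.ndarray,
                 coeffs: FieldCoefficients | None = None) -> float | np.ndarray:
    """Hydrophobicity density log P_j at one point or an (N,3) batch."""
    coeffs = coeffs or FieldCoefficients()
    pts = np.asarray(point, float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)

    q = np.array([a.partial_charge for a in ligand.atoms], float)
    alpha = np.array([a.polarizability for a in ligand.atoms], float)
    if not np.all(np.isfinite(q)) or not np.all(np.isfinite(alpha)):
        raise ValueError("charges and polarizabilities must be assigned "
                         "before field evaluation")
    xyz = ligand.coords
    r = np.linalg.norm(pts[:, None, :] - xyz[None, :, :], axis=-1)
    if np.any(r <= 1e-12):
        raise ValueError("grid point coincides with an atomic center")
    r2 = r * r
    r3 = r2 * r
    r6 = r3 * r3
    val = (coeffs.C1 * np.abs((q / r2).sum(axis=1))
           + coeffs.C2 * ((q * q) / r3).sum(axis=1)
           + coeffs.C3 * (alpha / r3).sum(axis=1)
           + coeffs.C4 * (alpha / r6).sum(axis=1)
           + coeffs.Ccav)
    return float(val[0]) if single else val


def evaluate_grid(grid: SurfaceGrid, ligand: MolecularStructure,
                  coeffs: FieldCoefficients | None = None) -> SurfaceGrid:
    """Fill per-point log P_j values on the grid (in place)."""
    grid.logp = np.asarray(logp_density(ligand, grid.coords, coeffs), float)
    return grid


# ---------------------------------------------------------------------------
# Contact assignment and integration
# ---------------------------------------------------------------------------

def assign_contact_residues(grid: SurfaceGrid,
                            pocket: list[PocketResidue]) -> SurfaceGrid:
    """Mark each grid point with every pocket residue whose van der Waals
    surface contains it (distance to some residue atom <= that atom's r_vdW).
    """
    for contact in grid.contacts:
        contact.clear()
    for res in pocket:
        xyz = res.coords
        radii = np.array([a.vdw_radius if np.isfinite(a.vdw_radius)
                          else BONDI_RADII.get(a.element, 1.7)
                          for a in res.atoms], float)
        d = np.linalg.norm(grid.coords[:, None, :] - xyz[None, :, :], axis=-1)
        inside = np.any(d <= radii[None, :], axis=1)
        for idx in np.where(inside)[0]:
            grid.contacts[idx].add(res.label)
    return grid


def compute_logpc(grid: SurfaceGrid, pocket: list[PocketResidue],
                  area_weighted: bool = True,
                  unique_count: bool = False) -> float:
    """Integrate hydrophobic grid points on the hydrophobic contact surface.

    Only residues flagged hydrophobic contribute.  A point inside two
    residues' vdW surfaces contributes once per residue set C_k (literal
    double sum); ``unique_count=True`` counts each point once.
    ``area_weighted=False`` gives the bare (density-dependent) point sum.
    """
    if np.any(np.isnan(grid.logp)):
        raise ValueError("grid has not been evaluated (call evaluate_grid)")
    hydro_labels = [r.label for r in pocket if r.hydrophobic]
    if not hydro_labels:
        return 0.0
    w = grid.area_weight if area_weighted else np.ones(len(grid))
    total = 0.0
    if unique_count:
        label_set = set(hydro_labels)
        for idx in range(len(grid)):
            if grid.logp[idx] > 0 and grid.contacts[idx] & label_set:
                total += grid.logp[idx] * w[idx]
        return total
    for label in hydro_labels:
        for idx in range(len(grid)):
            if grid.logp[idx] > 0 and label in grid.contacts[idx]:
                total += grid.logp[idx] * w[idx]
    return total


def logpc_by_residue(grid: SurfaceGrid, pocket: list[PocketResidue],
                     area_weighted: bool = True) -> dict[str, float]:
    """Per-residue decomposition of log P_C (same conventions as
    :func:`compute_logpc` with double counting)."""
    w = grid.area_weight if area_weighted else np.ones(len(grid))
    out: dict[str, float] = {}
    for res in pocket:
        if not res.hydrophobic:
            continue
        s = 0.0
        for idx in range(len(grid)):
            if grid.logp[idx] > 0 and res.label in grid.contacts[idx]:
                s += grid.logp[idx] * w[idx]
        out[res.label] = s
    return out


def molecular_logp(ligand: MolecularStructure, grid: SurfaceGrid) -> float:
    """Area-weighted integral of log P_j over the entire SAS (QC diagnostic)."""
    if np.any(np.isnan(grid.logp)):
        raise ValueError("grid has not been evaluated (call evaluate_grid)")
    return float(np.sum(grid.logp * grid.area_weight))
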