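"""Dot-sampled solvent-accessible surfaces with outward normals.

The surface is built the classic way: each heavy atom is expanded by the
probe radius (1.4 Å water probe), quasi-uniform dots are placed on the
expanded sphere with a deterministic Fibonacci lattice at the requested
areal density, and dots buried inside any neighbouring expanded sphere are
pruned.  Each retained dot keeps its parent atom/residue and the outward
radial normal.  An external DMS dot file can be ingested instead, in which
case its points and normals are used verbatim.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structio import ResidueId, Structure, StructureError

__all__ = [
    "SurfaceCloud",
    "generate_surface",
    "read_dms",
    "vdw_radius",
    "DEFAULT_DENSITY",
    "PROBE_RADIUS",
]

logger = logging.getLogger(__name__)

#: Default dot density in dots/Å² (the value recommended for large molecules).
DEFAULT_DENSITY = 0.5
#: Water-probe radius in Å.
PROBE_RADIUS = 1.4

# Bondi-style van der Waals radii (Å), element-keyed; fallback 1.7.
_VDW = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "B": 1.92, "ZN": 1.39, "MG": 1.73, "CA": 2.31, "FE": 2.00, "NA": 2.27,
    "K": 2.75, "MN": 2.00, "CU": 1.40, "NI": 1.63, "CO": 2.00,
}
_VDW_DEFAULT = 1.70


def vdw_radius(element: str) -> float:
    return _VDW.get(element.upper(), _VDW_DEFAULT)


@dataclasses.dataclass
class SurfaceCloud:
    """Solvent-accessible dot surface.

    points : (N, 3) Å; normals : (N, 3) unit vectors; parents : per-point
    parent residue; parent_atom : index into the structure's heavy-atom
    list; density : dots/Å² used at generation time.
    """

    points: np.ndarray
    normals: np.ndarray
    parents: list[ResidueId]
    parent_atom: np.ndarray
    density: float = DEFAULT_DENSITY

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        self.parent_atom = np.asarray(self.parent_atom, dtype=int)
        n = len(self.points)
        if not (len(self.normals) == len(self.parents) == len(self.parent_atom) == n):
            raise ValueError("points/normals/parents length mismatch")

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceCloud":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return SurfaceCloud(
            points=self.points @ R.T + t,
            normals=self.normals @ R.T,
            parents=list(self.parents),
            parent_atom=self.parent_atom.copy(),
            density=self.density,
        )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * math.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _canonical_frame(centers: np.ndarray) -> np.ndarray:
    """Deterministic molecule-intrinsic orthonormal frame (rows are axes).

    Principal axes of the atom coordinates, with each axis sign fixed by an
    index-weighted projection statistic, so the frame co-rotates exactly
    with any rigid motion of the structure.  This makes the dot lattice —
    and hence the whole generated surface — equivariant under rigid
    transformations (up to symmetric molecules with degenerate principal
    moments, where the axes themselves are ill-defined).
    """
    mu = centers.mean(axis=0)
    X = centers - mu
    cov = X.T @ X
    _, vecs = np.linalg.eigh(cov)
    V = vecs[:, ::-1].copy()  # descending variance
    idx = np.arange(1, len(centers) + 1, dtype=float)
    for k in range(2):
        proj = X @ V[:, k]
        s = float(idx @ proj)
        if abs(s) < 1e-9:
            s = float(np.sum(proj ** 3))
        if s < 0:
            V[:, k] = -V[:, k]
    V[:, 2] = np.cross(V[:, 0], V[:, 1])  # right-handed third axis
    return V.T


def generate_surface(
    s: Structure,
    density: float = DEFAULT_DENSITY,
    probe: float = PROBE_RADIUS,
) -> SurfaceCloud:
    """Generate the dot-sampled solvent-accessible surface of a structure.

    For each heavy atom, dots are laid on the sphere of radius
    ``r_vdW + probe`` at ``density`` dots/Å²; dots strictly inside any other
    atom's expanded sphere are removed.  Normals point radially outward
    from the parent atom centre.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    heavy = s.heavy_atoms()
    if not heavy:
        raise StructureError("cannot generate a surface: no heavy atoms")
    centers = np.asarray([a.coords for a in heavy])
    radii = np.asarray([vdw_radius(a.element) + probe for a in heavy])
    tree = cKDTree(centers)
    rmax = float(np.max(radii))
    frame = _canonical_frame(centers)

    pts, nrm, parents, patom = [], [], [], []
    eps = 1e-9
    for i, atom in enumerate(heavy):
        R = radii[i]
        ndots = max(1, int(round(density * 4.0 * math.pi * R * R)))
        unit = _fibonacci_sphere(ndots) @ frame
        dots = centers[i] + R * unit
        # candidate occluders: any atom whose expanded sphere can reach these dots
        nbrs = tree.query_ball_point(centers[i], R + rmax)
        keep = np.ones(len(dots), dtype=bool)
        for j in nbrs:
            if j == i:
                continue
            d = np.linalg.norm(dots - centers[j], axis=1)
            keep &= d >= radii[j] - eps
        if not np.any(keep):
            continue
        pts.append(dots[keep])
        nrm.append(unit[keep])
        parents.extend([atom.parent] * int(np.count_nonzero(keep)))
        patom.append(np.full(int(np.count_nonzero(keep)), i, dtype=int))

    if not pts:
        raise StructureError("surface generation produced no accessible dots")
    return SurfaceCloud(
        points=np.concatenate(pts),
        normals=np.concatenate(nrm),
        parents=parents,
        parent_atom=np.concatenate(patom),
        density=density,
    )


def read_dms(path: str | Path, s: Structure) -> SurfaceCloud:
    """Read a DMS dot-surface file and resolve parents against ``s``.

    Expected records: ``RESNAME RESNUM ATOMNAME X Y Z TYPE [AREA] [NX NY NZ]``.
    Records without a normal triple are dropped (count logged).  Atom
    records (type code starting with ``A``) describe atom centres, not
    surface dots, and are skipped.
    """
    path = Path(path)
    heavy = s.heavy_atoms()
    index: dict[tuple[str, int, str], int] = {}
    for i, a in enumerate(heavy):
        index.setdefault((a.parent.resname, a.parent.number, a.name), i)

    pts, nrm, parents, patom = [], [], [], []
    dropped = 0
    unmatched: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok or line.startswith("#"):
                continue
            if len(tok) < 7:
                raise StructureError(f"{path.name}:{lineno}: short DMS record")
            resname, resnum_s, atomname = tok[0], tok[1], tok[2]
            try:
                resnum = int("".join(c for c in resnum_s if c.isdigit() or c == "-"))
                xyz = [float(v) for v in tok[3:6]]
            except ValueError as exc:
                raise StructureError(f"{path.name}:{lineno}: bad DMS record") from exc
            type_code = tok[6]
            if type_code.upper().startswith("A"):
                continue  # atom-centre record, not a surface dot
            # normal triple = last three floats if present beyond the area column
            rest = tok[7:]
            normal = None
            if len(rest) >= 3:
                try:
                    normal = [float(v) for v in rest[-3:]]
                except ValueError:
                    normal = None
            if normal is None:
                dropped += 1
                continue
            key = (resname, resnum, atomname)
            if key not in index:
                unmatched.append(f"{resname} {resnum} {atomname}")
                continue
            ai = index[key]
            pts.append(xyz)
            nn = np.asarray(normal, dtype=float)
            norm = np.linalg.norm(nn)
            nrm.append(nn / norm if norm > 0 else nn)
            parents.append(heavy[ai].parent)
            patom.append(ai)
    if unmatched:
        raise StructureError(
            f"{path.name}: {len(unmatched)} DMS records do not match the structure: "
            + "; ".join(unmatched[:5])
        )
    if dropped:
        logger.warning("%s: dropped %d DMS points without normals", path.name, dropped)
    if not pts:
        raise StructureError(f"{path.name}: no surface dots parsed")
    return SurfaceCloud(
        points=np.asarray(pts),
        normals=np.asarray(nrm),
        parents=parents,
        parent_atom=np.asarray(patom, dtype=int),
        density=float("nan"),
    )
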