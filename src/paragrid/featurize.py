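"""Balanced surface sampling, 22-channel atom features, and voxel grids.

Each heavy atom carries 22 channels: a 9-way element-class one-hot
(B, C, N, O, P, S, Se, halogen, metal), four atom properties
(hybridization, heavy valence, heterovalence, partial charge), five
pharmacophore flags (hydrophobic, aromatic, acceptor, donor, ring), and
four force-field channels (AMBER charge/radius, CHARMM charge/radius).
Chemistry-derived channels come from an RDKit molecular context built from
the structure; the force-field channels come from PQR files when supplied,
otherwise from a packaged residue template table.

Grids are cubes of odd edge length (default 41 voxels at 1 Å) centred on a
surface point and oriented so the grid z-axis coincides with the surface
normal; atoms are assigned to the voxel containing their frame-transformed
coordinates and co-located atoms sum channel-wise.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ._ff_tables import FF_TEMPLATE
from .structio import BINDING_CUTOFF, ResidueId, Structure, StructureError
from .surface import SurfaceCloud

__all__ = [
    "FEATURE_NAMES",
    "N_CHANNELS",
    "SampledPoints",
    "FeatureGrid",
    "GridDataset",
    "MolecularContext",
    "balanced_sample",
    "point_binding_mask",
    "atom_features",
    "compute_atom_features",
    "read_pqr",
    "local_frame",
    "voxelize",
    "augment_rotate90",
    "extract_grids",
    "GRID_SIZE",
    "GRID_RESOLUTION",
    "SAMPLES_PER_CLASS",
]

logger = logging.getLogger(__name__)

GRID_SIZE = 41
GRID_RESOLUTION = 1.0  # Å per voxel
SAMPLES_PER_CLASS = 800

FEATURE_NAMES = [
    "class_B", "class_C", "class_N", "class_O", "class_P", "class_S",
    "class_Se", "class_halogen", "class_metal",
    "hybridization", "heavy_valence", "heterovalence", "partial_charge",
    "hydrophobic", "aromatic", "acceptor", "donor", "ring",
    "amber_charge", "amber_radius", "charmm_charge", "charmm_radius",
]
N_CHANNELS = len(FEATURE_NAMES)
assert N_CHANNELS == 22

_CLASS_INDEX = {"B": 0, "C": 1, "N": 2, "O": 3, "P": 4, "S": 5, "SE": 6}
_HALOGENS = {"F", "CL", "BR", "I", "AT"}
_METALS = {
    "LI", "NA", "K", "RB", "CS", "MG", "CA", "SR", "BA", "MN", "FE", "CO",
    "NI", "CU", "ZN", "CD", "HG", "AL", "GA", "PB", "AG", "AU", "PT", "PD",
    "MO", "W", "V", "CR", "TI", "SN",
}

_HYBRIDIZATION_MAP = {
    "S": 1, "SP": 1, "SP2": 2, "SP3": 3, "SP3D": 4, "SP3D2": 5,
}


def element_class_onehot(element: str) -> np.ndarray:
    """9-way atom-class one-hot; all-zero for unclassifiable elements."""
    out = np.zeros(9)
    el = element.upper()
    if el in _CLASS_INDEX:
        out[_CLASS_INDEX[el]] = 1.0
    elif el in _HALOGENS:
        out[7] = 1.0
    elif el in _METALS:
        out[8] = 1.0
    else:
        logger.warning("element %r not classifiable: all-zero atom class", element)
    return out


# ---------------------------------------------------------------------------
# molecular context (RDKit)
# ---------------------------------------------------------------------------

class MolecularContext:
    """RDKit view of a structure, providing connectivity-derived channels.

    Built from the structure's PDB representation with proximity bonding;
    per-atom lookups are keyed on (chain, residue number, icode, atom name).
    When RDKit cannot construct or sanitize the molecule the context is
    empty and connectivity channels fall back to zero (count logged).
    """

    def __init__(self, structure: Structure):
        self.structure = structure
        self._by_key: dict[tuple[str, int, str, str], dict] = {}
        self._build()

    def _build(self) -> None:
        from rdkit import Chem
        from rdkit import RDLogger
        from rdkit.Chem import AllChem, ChemicalFeatures
        from rdkit import RDConfig
        import os

        RDLogger.DisableLog("rdApp.*")
        from .structio import _to_gemmi

        block = _to_gemmi(self.structure).make_pdb_string()
        mol = Chem.MolFromPDBBlock(block, sanitize=True, removeHs=False,
                                   proximityBonding=True)
        if mol is None:
            logger.warning("RDKit could not build a molecule; connectivity channels zeroed")
            return
        try:
            AllChem.ComputeGasteigerCharges(mol)
        except Exception:  # pragma: no cover - rdkit internal failures
            pass

        fdef = os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
        factory = ChemicalFeatures.BuildFeatureFactory(fdef)
        flagged: dict[str, set[int]] = {"Donor": set(), "Acceptor": set(), "Hydrophobe": set()}
        try:
            for feat in factory.GetFeaturesForMol(mol):
                fam = feat.GetFamily()
                if fam in flagged:
                    flagged[fam].update(feat.GetAtomIds())
                elif fam == "LumpedHydrophobe":
                    flagged["Hydrophobe"].update(feat.GetAtomIds())
        except Exception:  # pragma: no cover
            pass

        for atom in mol.GetAtoms():
            info = atom.GetPDBResidueInfo()
            if info is None:
                continue
            key = (
                info.GetChainId().strip(),
                info.GetResidueNumber(),
                info.GetInsertionCode().strip(),
                info.GetName().strip(),
            )
            try:
                q = float(atom.GetProp("_GasteigerCharge"))
            except (KeyError, ValueError):
                q = 0.0
            if not np.isfinite(q):
                q = 0.0
            idx = atom.GetIdx()
            heavy_nbrs = [n for n in atom.GetNeighbors() if n.GetAtomicNum() > 1]
            self._by_key[key] = {
                "hybridization": _HYBRIDIZATION_MAP.get(str(atom.GetHybridization()), 0),
                "heavy_valence": len(heavy_nbrs),
                "heterovalence": sum(1 for n in heavy_nbrs if n.GetAtomicNum() not in (1, 6)),
                "partial_charge": q,
                "hydrophobic": 1.0 if idx in flagged["Hydrophobe"] else 0.0,
                "aromatic": 1.0 if atom.GetIsAromatic() else 0.0,
                "acceptor": 1.0 if idx in flagged["Acceptor"] else 0.0,
                "donor": 1.0 if idx in flagged["Donor"] else 0.0,
                "ring": 1.0 if atom.IsInRing() else 0.0,
            }

    def lookup(self, atom) -> dict | None:
        key = (atom.parent.chain.strip(), atom.parent.number,
               atom.parent.icode.strip(), atom.name.strip())
        return self._by_key.get(key)


# ---------------------------------------------------------------------------
# PQR reading and force-field channels
# ---------------------------------------------------------------------------

def read_pqr(path: str | Path) -> dict[tuple[str, int, str], tuple[float, float]]:
    """Read a PQR file into {(resname, resnum, atom name): (charge, radius)}.

    PQR is PDB-like with whitespace-separated fields whose final two
    numeric columns are the partial charge (e) and radius (Å).
    """
    table: dict[tuple[str, int, str], tuple[float, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            tok = line.split()
            if len(tok) < 9:
                raise StructureError(f"{Path(path).name}:{lineno}: short PQR record")
            try:
                charge, radius = float(tok[-2]), float(tok[-1])
            except ValueError as exc:
                raise StructureError(f"{Path(path).name}:{lineno}: bad PQR numerics") from exc
            name, resname = tok[2], tok[3]
            # residue number is the last integer-looking token before x y z
            resnum_tok = tok[5] if tok[4].isalpha() and len(tok) >= 11 else tok[4]
            try:
                resnum = int("".join(c for c in resnum_tok if c.isdigit() or c == "-"))
            except ValueError as exc:
                raise StructureError(f"{Path(path).name}:{lineno}: bad PQR residue number") from exc
            table[(resname, resnum, name)] = (charge, radius)
    return table


def _ff_channels(atom, pqr_amber, pqr_charmm, miss_counter) -> tuple[float, float, float, float]:
    key = (atom.parent.resname, atom.parent.number, atom.name.strip())
    tkey = (atom.parent.resname, atom.name.strip())
    if pqr_amber is not None:
        qa, ra = pqr_amber.get(key, (None, None))
    else:
        tmpl = FF_TEMPLATE.get(tkey)
        qa, ra = (tmpl[0], tmpl[1]) if tmpl else (None, None)
    if pqr_charmm is not None:
        qc, rc = pqr_charmm.get(key, (None, None))
    else:
        tmpl = FF_TEMPLATE.get(tkey)
        qc, rc = (tmpl[2], tmpl[3]) if tmpl else (None, None)
    if qa is None or qc is None:
        miss_counter.append(key)
    return (qa or 0.0, ra or 0.0, qc or 0.0, rc or 0.0)


def atom_features(
    atom,
    context: MolecularContext | None = None,
    pqr_amber: dict | None = None,
    pqr_charmm: dict | None = None,
) -> np.ndarray:
    """22-channel feature vector for one heavy atom."""
    if not atom.is_heavy:
        raise ValueError("features are defined for heavy atoms only")
    out = np.zeros(N_CHANNELS)
    out[:9] = element_class_onehot(atom.element)
    props = context.lookup(atom) if context is not None else None
    if props is not None:
        out[9] = props["hybridization"]
        out[10] = props["heavy_valence"]
        out[11] = props["heterovalence"]
        out[12] = props["partial_charge"]
        out[13] = props["hydrophobic"]
        out[14] = props["aromatic"]
        out[15] = props["acceptor"]
        out[16] = props["donor"]
        out[17] = props["ring"]
    misses: list = []
    out[18:22] = _ff_channels(atom, pqr_amber, pqr_charmm, misses)
    return out


def compute_atom_features(
    structure: Structure,
    pqr_amber: dict | None = None,
    pqr_charmm: dict | None = None,
    context: MolecularContext | None = None,
) -> np.ndarray:
    """(n_heavy, 22) feature matrix aligned with ``structure.heavy_atoms()``."""
    if context is None:
        context = MolecularContext(structure)
    heavy = structure.heavy_atoms()
    out = np.zeros((len(heavy), N_CHANNELS))
    misses: list = []
    unmatched = 0
    for i, atom in enumerate(heavy):
        out[i, :9] = element_class_onehot(atom.element)
        props = context.lookup(atom)
        if props is None:
            unmatched += 1
        else:
            out[i, 9] = props["hybridization"]
            out[i, 10] = props["heavy_valence"]
            out[i, 11] = props["heterovalence"]
            out[i, 12] = props["partial_charge"]
            out[i, 13:18] = [props["hydrophobic"], props["aromatic"],
                             props["acceptor"], props["donor"], props["ring"]]
        out[i, 18:22] = _ff_channels(atom, pqr_amber, pqr_charmm, misses)
    if unmatched:
        logger.warning("%d heavy atoms missing from the molecular context", unmatched)
    if misses:
        logger.warning("%d heavy atoms without force-field parameters (zeroed)", len(misses))
    return out


# ---------------------------------------------------------------------------
# balanced surface sampling
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SampledPoints:
    """Balanced positive/negative surface-point index sets."""

    positives: np.ndarray
    negatives: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.positives = np.asarray(self.positives, dtype=int)
        self.negatives = np.asarray(self.negatives, dtype=int)
        if len(self.positives) != len(self.negatives):
            raise ValueError("sampled classes must be balanced")

    def all_indices(self) -> np.ndarray:
        return np.concatenate([self.positives, self.negatives])

    def labels(self) -> np.ndarray:
        return np.concatenate([
            np.ones(len(self.positives), dtype=int),
            np.zeros(len(self.negatives), dtype=int),
        ])


def point_binding_mask(
    cloud: SurfaceCloud, antigen: Structure, cutoff: float = BINDING_CUTOFF
) -> np.ndarray:
    """Boolean mask of surface points within ``cutoff`` of an antigen heavy atom."""
    ag = antigen.heavy_coords()
    if ag.shape[0] == 0:
        raise StructureError("antigen has no heavy atoms")
    tree = cKDTree(ag)
    d, _ = tree.query(cloud.points, k=1)
    return d <= cutoff


def balanced_sample(
    cloud: SurfaceCloud,
    antigen: Structure,
    n: int = SAMPLES_PER_CLASS,
    seed: int = 0,
    cutoff: float = BINDING_CUTOFF,
) -> SampledPoints:
    """Draw up to ``n`` positive surface points and as many negatives.

    Positives are points within ``cutoff`` of an antigen heavy atom; when
    fewer than ``n`` exist, all are taken and the negative count is matched
    so classes stay balanced.  Deterministic given ``seed``.
    """
    if len(cloud) == 0:
        raise ValueError("empty surface cloud")
    mask = point_binding_mask(cloud, antigen, cutoff)
    pos_idx = np.flatnonzero(mask)
    neg_idx = np.flatnonzero(~mask)
    if len(pos_idx) == 0:
        logger.warning("no positive surface points: pair is unusable for training")
        return SampledPoints(np.empty(0, int), np.empty(0, int), seed)
    k = min(n, len(pos_idx), len(neg_idx))
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(pos_idx, size=k, replace=False))
    neg = np.sort(rng.choice(neg_idx, size=k, replace=False))
    return SampledPoints(pos, neg, seed)


# ---------------------------------------------------------------------------
# local frames and voxelization
# ---------------------------------------------------------------------------

def local_frame(normal: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame (rows) whose third row is ``normal``.

    The in-plane orientation is fixed by projecting the global x-axis onto
    the tangent plane (y-axis when the normal is nearly parallel to x).
    """
    n = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("zero-norm normal vector")
    n = n / norm
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return np.stack([u, v, n])


@dataclasses.dataclass
class FeatureGrid:
    """One voxelized training/inference sample centred on a surface point."""

    tensor: np.ndarray  # (size, size, size, 22) float32
    center: np.ndarray
    frame: np.ndarray
    label: int = 0
    provenance: tuple = ("", -1)  # (structure id, point index)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def voxelize(
    s: Structure,
    center: np.ndarray,
    frame: np.ndarray,
    features: np.ndarray,
    size: int = GRID_SIZE,
    resolution: float = GRID_RESOLUTION,
    label: int = 0,
    provenance: tuple = ("", -1),
) -> FeatureGrid:
    """Map heavy atoms into a ``size``³ grid of ``resolution``-Å voxels.

    Atom coordinates are expressed in the local frame (rows of ``frame``)
    about ``center``; each atom lands in the voxel containing it (half-open
    intervals, centre voxel spanning [-res/2, res/2) per axis) and
    co-located atoms sum channel-wise.  A 41³ grid at 1 Å covers every atom
    within 20 Å of the centre.
    """
    if size % 2 != 1:
        raise ValueError("grid size must be odd")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    heavy = s.heavy_atoms()
    if features.shape != (len(heavy), N_CHANNELS):
        raise ValueError(
            f"features shape {features.shape} does not match {len(heavy)} heavy atoms"
        )
    center = np.asarray(center, dtype=float)
    frame = np.asarray(frame, dtype=float)
    grid = np.zeros((size, size, size, N_CHANNELS), dtype=np.float32)
    if heavy:
        coords = np.asarray([a.coords for a in heavy])
        local = (coords - center) @ frame.T
        idx = np.floor(local / resolution + 0.5).astype(int) + (size - 1) // 2
        inside = np.all((idx >= 0) & (idx < size), axis=1)
        ii = idx[inside]
        np.add.at(grid, (ii[:, 0], ii[:, 1], ii[:, 2]), features[inside].astype(np.float32))
    return FeatureGrid(tensor=grid, center=center, frame=frame, label=label,
                       provenance=provenance)


_ROT_PLANES = {0: (1, 2), 1: (0, 2), 2: (0, 1)}


def augment_rotate90(grid: FeatureGrid, seed: int = 0) -> FeatureGrid:
    """Rotate the tensor a quarter-turn about one uniformly chosen axis."""
    t = grid.tensor
    if not (t.shape[0] == t.shape[1] == t.shape[2]):
        raise ValueError("rotation augmentation requires a cubic grid")
    rng = np.random.default_rng(seed)
    axis = int(rng.integers(0, 3))
    rotated = np.rot90(t, k=1, axes=_ROT_PLANES[axis]).copy()
    return FeatureGrid(tensor=rotated, center=grid.center.copy(), frame=grid.frame.copy(),
                       label=grid.label, provenance=grid.provenance)


# ---------------------------------------------------------------------------
# grid datasets
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GridDataset:
    """Stack of labeled grids with a reproducibility manifest."""

    X: np.ndarray  # (N, size, size, size, 22) float32
    y: np.ndarray  # (N,) int
    manifest: list[dict]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int64)
        if len(self.X) != len(self.y):
            raise ValueError("X/y length mismatch")

    def __len__(self) -> int:
        return len(self.X)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path, X=self.X, y=self.y, manifest=json.dumps(self.manifest)
        )

    @classmethod
    def load(cls, path: str | Path) -> "GridDataset":
        with np.load(path, allow_pickle=False) as z:
            return cls(X=z["X"], y=z["y"], manifest=json.loads(str(z["manifest"])))


def extract_grids(
    receptor: Structure,
    cloud: SurfaceCloud,
    sampled: SampledPoints,
    features: np.ndarray,
    size: int = GRID_SIZE,
    resolution: float = GRID_RESOLUTION,
    structure_id: str = "",
) -> GridDataset:
    """Build one labeled grid per sampled surface point."""
    indices = sampled.all_indices()
    labels = sampled.labels()
    X = np.zeros((len(indices), size, size, size, N_CHANNELS), dtype=np.float32)
    manifest = []
    for row, (pi, lab) in enumerate(zip(indices, labels)):
        frame = local_frame(cloud.normals[pi])
        fg = voxelize(receptor, cloud.points[pi], frame, features, size=size,
                      resolution=resolution, label=int(lab),
                      provenance=(structure_id, int(pi)))
        X[row] = fg.tensor
        manifest.append({
            "structure": structure_id,
            "point": int(pi),
            "label": int(lab),
            "seed": int(sampled.seed),
        })
    return GridDataset(X=X, y=labels, manifest=manifest)
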