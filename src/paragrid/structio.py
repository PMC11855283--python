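"""Reading, cleaning and indexing of antibody / antigen structures.

Structures are held as flat atom lists keyed by author residue identifiers
(chain, number, insertion code) — no renumbering is ever performed, so
residue keys survive round-trips through PDB files and can be joined
against externally supplied IMGT mapping tables.

Binding labels follow the standard heavy-atom contact definition: a
receptor residue is part of the binding site when any of its heavy
(non-hydrogen) atoms lies within ``cutoff`` (default 4.5 Å) of any antigen
heavy atom.  The comparison is ``<=`` throughout the package.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "ResidueId",
    "Structure",
    "BindingLabels",
    "StructureError",
    "read_pdb",
    "clean_structure",
    "select_chains",
    "label_binding_residues",
    "sanity_check",
    "write_pdb",
    "BINDING_CUTOFF",
]

#: Default heavy-atom contact cutoff in Å.
BINDING_CUTOFF = 4.5

# Residue names treated as water.
_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# Monoatomic ion residue names commonly deposited as HETATM records.
_ION_NAMES = {
    "NA", "K", "CL", "BR", "IOD", "F", "MG", "CA", "ZN", "MN", "FE", "FE2",
    "CU", "CU1", "CO", "NI", "CD", "HG", "SR", "BA", "CS", "LI", "RB", "AL",
    "PB", "PT", "AU", "AG", "YB", "SM", "GD", "NH4", "OH",
}

# The 20 standard amino acids plus modified residues kept as polymer.
_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_MODIFIED_AA = {
    "MSE", "SEC", "PYL", "SEP", "TPO", "PTR", "CSO", "CSS", "HYP", "KCX",
    "MLY", "CME", "OCS", "PCA", "FME",
}
_POLYMER_RESIDUES = _STANDARD_AA | _MODIFIED_AA


class StructureError(ValueError):
    """Raised for unusable or malformed structural input."""


@dataclasses.dataclass(frozen=True)
class ResidueId:
    """Author-numbering residue key: (chain, number, icode) is unique."""

    chain: str
    number: int
    icode: str
    resname: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        ic = self.icode.strip()
        return f"{self.chain}/{self.resname}{self.number}{ic}"


@dataclasses.dataclass
class Atom:
    element: str
    coords: np.ndarray
    name: str
    is_heavy: bool
    bfactor: float
    occupancy: float
    parent: ResidueId
    het: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be 3 finite reals")


@dataclasses.dataclass
class Structure:
    """Ordered atom collection with residue index, for one binding partner."""

    atoms: list[Atom]
    residues: list[ResidueId]
    role: str  # "receptor" | "antigen"
    name: str = ""

    def __post_init__(self) -> None:
        known = set(self.residues)
        for a in self.atoms:
            if a.parent not in known:
                raise StructureError(f"atom {a.name} references unknown residue {a.parent}")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coords for a in self.atoms if a.is_heavy]
        if not coords:
            return np.empty((0, 3))
        return np.asarray(coords)

    def atoms_by_residue(self) -> dict[ResidueId, list[Atom]]:
        out: dict[ResidueId, list[Atom]] = {r: [] for r in self.residues}
        for a in self.atoms:
            out[a.parent].append(a)
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = [dataclasses.replace(a, coords=R @ a.coords + t) for a in self.atoms]
        return Structure(atoms, list(self.residues), self.role, self.name)


@dataclasses.dataclass
class BindingLabels:
    """Per-residue boolean interface labels at a distance cutoff."""

    labels: dict[ResidueId, bool]
    cutoff: float = BINDING_CUTOFF

    def __getitem__(self, rid: ResidueId) -> bool:
        return self.labels[rid]

    def positives(self) -> list[ResidueId]:
        return [r for r, v in self.labels.items() if v]

    def any(self) -> bool:
        return any(self.labels.values())


def _is_hydrogen(element: str) -> bool:
    return element.upper() in ("H", "D", "T")


def _from_gemmi(st: gemmi.Structure, role: str, name: str) -> Structure:
    if len(st) == 0:
        raise StructureError(f"{name}: file contains no model")
    model = st[0]
    atoms: list[Atom] = []
    residues: list[ResidueId] = []
    seen: set[ResidueId] = set()
    for chain in model:
        for res in chain:
            rid = ResidueId(
                chain=chain.name,
                number=res.seqid.num,
                icode=(res.seqid.icode or " ").strip(),
                resname=res.name.strip(),
            )
            het = res.het_flag == "H"
            # altloc rule: keep the highest-occupancy conformer per atom
            # name, first encountered wins ties.
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in res:
                prev = best.get(at.name)
                if prev is None:
                    best[at.name] = at
                    order.append(at.name)
                elif at.occ > prev.occ:
                    best[at.name] = at
            res_atoms = []
            for atom_name in order:
                at = best[atom_name]
                el = at.element.name if at.element else ""
                res_atoms.append(
                    Atom(
                        element=el,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        name=at.name,
                        is_heavy=not _is_hydrogen(el),
                        bfactor=at.b_iso,
                        occupancy=at.occ,
                        parent=rid,
                        het=het,
                    )
                )
            if not res_atoms:
                continue
            if rid not in seen:
                seen.add(rid)
                residues.append(rid)
            atoms.extend(res_atoms)
    if not atoms:
        raise StructureError(f"{name}: no ATOM/HETATM records found")
    return Structure(atoms=atoms, residues=residues, role=role, name=name)


def read_pdb(path: str | Path, role: str = "receptor") -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Hydrogens are retained but flagged non-heavy; alternate locations are
    collapsed to the highest-occupancy conformer.
    """
    path = Path(path)
    if role not in ("receptor", "antigen"):
        raise ValueError(f"role must be 'receptor' or 'antigen', got {role!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"{path.name}: PDB parse failure: {exc}") from exc
    st.setup_entities()
    return _from_gemmi(st, role, path.stem)


def read_pdb_string(text: str, role: str = "receptor", name: str = "inline") -> Structure:
    """Parse PDB-format text (used heavily by the test fixtures)."""
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"{name}: PDB parse failure: {exc}") from exc
    st.setup_entities()
    return _from_gemmi(st, role, name)


def _is_ion(rid: ResidueId, atoms: Sequence[Atom]) -> bool:
    if rid.resname in _ION_NAMES:
        return True
    # Monoatomic HETATM residues are ions regardless of naming.
    return len(atoms) == 1 and atoms[0].het and rid.resname not in _POLYMER_RESIDUES


def clean_structure(s: Structure) -> Structure:
    """Remove waters, monoatomic ions, and HETATM ligand residues.

    Standard and modified polymer residues are retained; atom order is
    otherwise preserved.  Raises :class:`StructureError` if nothing
    polymer-like survives.
    """
    by_res = s.atoms_by_residue()
    keep: list[ResidueId] = []
    for rid in s.residues:
        atoms = by_res[rid]
        if rid.resname in _WATER_NAMES:
            continue
        if _is_ion(rid, atoms):
            continue
        if rid.resname not in _POLYMER_RESIDUES and all(a.het for a in atoms):
            continue  # HETATM ligand
        keep.append(rid)
    keep_set = set(keep)
    atoms = [a for a in s.atoms if a.parent in keep_set]
    if not atoms:
        raise StructureError(f"{s.name or s.role}: structure empty after cleaning")
    return Structure(atoms=atoms, residues=keep, role=s.role, name=s.name)


def select_chains(s: Structure, chains: Iterable[str]) -> Structure:
    """Restrict a structure to the given chain identifiers.

    Supports heavy-chain-only / light-chain-only scenarios; callers should
    re-run :func:`sanity_check` afterwards, since detaching a chain can
    remove the entire interface.
    """
    wanted = set(chains)
    residues = [r for r in s.residues if r.chain in wanted]
    if not residues:
        raise StructureError(f"no residues left after selecting chains {sorted(wanted)}")
    keep = set(residues)
    atoms = [a for a in s.atoms if a.parent in keep]
    return Structure(atoms=atoms, residues=residues, role=s.role, name=s.name)


def label_binding_residues(
    receptor: Structure, antigen: Structure, cutoff: float = BINDING_CUTOFF
) -> BindingLabels:
    """Label receptor residues within ``cutoff`` of any antigen heavy atom.

    Distances are computed between heavy atoms only, via a k-d tree; the
    comparison is ``<= cutoff``.
    """
    ag = antigen.heavy_coords()
    if ag.shape[0] == 0:
        raise StructureError("antigen has no heavy atoms")
    rec_heavy = receptor.heavy_atoms()
    if not rec_heavy:
        raise StructureError("receptor has no heavy atoms")
    tree = cKDTree(ag)
    coords = np.asarray([a.coords for a in rec_heavy])
    dmin, _ = tree.query(coords, k=1)
    labels = {rid: False for rid in receptor.residues}
    for atom, d in zip(rec_heavy, dmin):
        if d <= cutoff:
            labels[atom.parent] = True
    return BindingLabels(labels=labels, cutoff=cutoff)


def sanity_check(
    receptor: Structure, antigen: Structure, cutoff: float = BINDING_CUTOFF
) -> bool:
    """True iff at least one receptor heavy atom is within ``cutoff`` of the antigen.

    Pairs failing this check are excluded from training sets.
    """
    ag = antigen.heavy_coords()
    rec = receptor.heavy_coords()
    if ag.shape[0] == 0 or rec.shape[0] == 0:
        raise StructureError("sanity_check requires heavy atoms on both sides")
    tree = cKDTree(ag)
    dmin, _ = tree.query(rec, k=1)
    return bool(np.min(dmin) <= cutoff)


def _to_gemmi(s: Structure, bfactors: dict[ResidueId, float] | None = None) -> gemmi.Structure:
    # gemmi's add_residue/add_chain copy their arguments, so containers
    # must be assembled bottom-up: atoms -> residue -> chain -> model.
    st = gemmi.Structure()
    st.name = s.name or s.role
    model = gemmi.Model("1")
    by_res = s.atoms_by_residue()
    chain_order: list[str] = []
    chain_map: dict[str, gemmi.Chain] = {}
    for rid in s.residues:
        res = gemmi.Residue()
        res.name = rid.resname
        res.seqid = gemmi.SeqId(rid.number, rid.icode if rid.icode else " ")
        for a in by_res[rid]:
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element if a.element else "X")
            at.pos = gemmi.Position(*a.coords)
            at.occ = a.occupancy
            if bfactors is not None:
                at.b_iso = round(bfactors.get(a.parent, 0.0), 2)
            else:
                at.b_iso = a.bfactor
            res.add_atom(at)
        if rid.chain not in chain_map:
            chain_map[rid.chain] = gemmi.Chain(rid.chain)
            chain_order.append(rid.chain)
        chain_map[rid.chain].add_residue(res)
    for name in chain_order:
        model.add_chain(chain_map[name])
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(
    s: Structure, path: str | Path, bfactors: dict[ResidueId, float] | None = None
) -> None:
    """Write a structure as PDB, optionally overriding per-residue b-factors."""
    st = _to_gemmi(s, bfactors=bfactors)
    st.write_pdb(str(path))
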