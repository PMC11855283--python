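"""Deterministic generators for toy complexes and planted-signal grids.

These generators make every pipeline stage testable without downloads:

* :func:`make_toy_complex` builds a rigid poly-glycine-like receptor on a
  lattice with a controllable interface — chosen residues sit at an exact
  minimum heavy-atom distance from the antigen, all others at a decoy
  separation well beyond the contact cutoff, so the expected binding
  labels are known by construction.
* :func:`make_planted_grids` emits labeled feature grids whose positive
  class carries an additive shift on one channel inside the central
  region, i.e. a signal a one-feature linear read-out can recover.

Both are pure functions of their seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .featurize import GridDataset, N_CHANNELS
from .structio import Atom, BindingLabels, ResidueId, Structure

__all__ = [
    "ToyComplexSpec",
    "PlantedGridSpec",
    "make_toy_complex",
    "make_planted_grids",
]

_RESIDUE_SPACING = 6.0  # Å between receptor residue anchors along x


@dataclasses.dataclass
class ToyComplexSpec:
    n_receptor_residues: int = 10
    n_antigen_residues: int = 4
    interface: tuple[int, ...] = (2, 5)  # receptor residue indices (0-based)
    interface_distance: float = 3.5  # Å, exact min heavy-atom distance
    decoy_separation: float = 20.0  # Å, distance of non-interface residues
    cutoff: float = 4.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_receptor_residues < 1 or self.n_antigen_residues < 1:
            raise ValueError("need at least one residue on each side")
        if self.decoy_separation <= self.cutoff:
            raise ValueError("decoy separation must exceed the binding cutoff")
        if self.interface_distance > self.cutoff:
            raise ValueError("interface distance must lie within the cutoff")
        bad = [i for i in self.interface if not 0 <= i < self.n_receptor_residues]
        if bad:
            raise ValueError(f"interface indices out of range: {bad}")


def _glycine_unit(rid: ResidueId, base: np.ndarray) -> list[Atom]:
    """Rigid 4-atom backbone unit stacked upward from ``base``."""
    offsets = {
        "N": (0.0, 0.0, 0.0),
        "CA": (0.0, 1.5, 0.0),
        "C": (0.0, 3.0, 0.0),
        "O": (0.0, 3.0, 1.4),
    }
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    return [
        Atom(element=elements[name], coords=base + np.asarray(off), name=name,
             is_heavy=True, bfactor=0.0, occupancy=1.0, parent=rid)
        for name, off in offsets.items()
    ]


def make_toy_complex(
    spec: ToyComplexSpec,
) -> tuple[Structure, Structure, BindingLabels]:
    """Build (receptor, antigen, expected labels) per the geometric spec.

    Interface residues have their lowest atom exactly
    ``interface_distance`` above an antigen anchor atom; every other
    receptor atom is at least ``decoy_separation`` from all antigen atoms.
    """
    rec_atoms: list[Atom] = []
    rec_residues: list[ResidueId] = []
    interface = set(spec.interface)
    for i in range(spec.n_receptor_residues):
        rid = ResidueId(chain="A", number=i + 1, icode="", resname="GLY")
        rec_residues.append(rid)
        y = spec.interface_distance if i in interface else spec.decoy_separation
        base = np.array([i * _RESIDUE_SPACING, y, 0.0])
        rec_atoms.extend(_glycine_unit(rid, base))
    receptor = Structure(atoms=rec_atoms, residues=rec_residues, role="receptor",
                         name=f"toy-receptor-{spec.seed}")

    # antigen: a base block of residues at y <= -2, plus one anchor atom at
    # y = 0 directly below each interface residue.
    ag_atoms: list[Atom] = []
    ag_residues: list[ResidueId] = []
    for j in range(spec.n_antigen_residues):
        rid = ResidueId(chain="B", number=j + 1, icode="", resname="GLY")
        ag_residues.append(rid)
        base = np.array([j * _RESIDUE_SPACING, -5.0, 0.0])
        ag_atoms.extend(_glycine_unit(rid, base))
    for k, i in enumerate(sorted(interface)):
        rid = ag_residues[k % len(ag_residues)]
        ag_atoms.append(Atom(element="C", coords=np.array([i * _RESIDUE_SPACING, 0.0, 0.0]),
                             name=f"CX{k % 9 + 1}", is_heavy=True, bfactor=0.0,
                             occupancy=1.0, parent=rid))
    antigen = Structure(atoms=ag_atoms, residues=ag_residues, role="antigen",
                        name=f"toy-antigen-{spec.seed}")

    expected = BindingLabels(
        labels={rid: (i in interface) for i, rid in enumerate(rec_residues)},
        cutoff=spec.cutoff,
    )
    return receptor, antigen, expected


@dataclasses.dataclass
class PlantedGridSpec:
    n: int = 2000
    size: int = 9  # spatial edge length (desk-scale)
    channels: int = N_CHANNELS
    signal_channel: int = 3
    effect_size: float = 5.0  # additive shift in units of noise scale
    noise_scale: float = 1.0
    seed: int = 0
    central_region: int = 3  # edge of the central cube carrying the signal

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two grids")
        if not 0 <= self.signal_channel < self.channels:
            raise ValueError("signal channel out of range")
        if self.central_region > self.size:
            raise ValueError("central region larger than the grid")


def make_planted_grids(spec: PlantedGridSpec) -> GridDataset:
    """Labeled grids with a planted one-channel central-region signal.

    Class balance is exact to ±1; positives receive an additive
    ``effect_size × noise_scale`` shift on the signal channel inside the
    central region, on top of i.i.d. Gaussian noise everywhere.
    """
    rng = np.random.default_rng(spec.seed)
    S, C = spec.size, spec.channels
    X = rng.normal(0.0, spec.noise_scale, size=(spec.n, S, S, S, C)).astype(np.float32)
    y = np.zeros(spec.n, dtype=np.int64)
    y[: spec.n // 2] = 1
    y = rng.permutation(y)
    lo = (S - spec.central_region) // 2
    hi = lo + spec.central_region
    shift = np.float32(spec.effect_size * spec.noise_scale)
    pos = np.flatnonzero(y == 1)
    X[np.ix_(pos, range(lo, hi), range(lo, hi), range(lo, hi), [spec.signal_channel])] += shift
    manifest = [{"index": int(i), "label": int(y[i]), "seed": int(spec.seed)}
                for i in range(spec.n)]
    return GridDataset(X=X, y=y, manifest=manifest)
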