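"""Blind inference on a receptor: point scores, residue aggregation, outputs.

Inference consumes only the receptor structure and its surface — no
antigen coordinates enter this path.  Every surface point is scored by
the network and residue scores are the maximum over each residue's
surface points:

    Res_score = max(Pr(sp_1), Pr(sp_2), ..., Pr(sp_N))

Residues with no surface points (fully buried) carry score 0.0 and are
flagged.  A residue is called binding when its score strictly exceeds the
threshold (default 0.5; 0.734 is the Paragraph-comparable operating point).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .featurize import GRID_RESOLUTION, GRID_SIZE, compute_atom_features, local_frame, voxelize
from .network import ParatopeNet, predict_scores
from .structio import ResidueId, Structure, write_pdb
from .surface import SurfaceCloud

__all__ = [
    "PredictionSet",
    "infer",
    "aggregate_residue_scores",
    "classify_residues",
    "write_bfactor_pdb",
    "write_pocket_pdb",
    "write_score_table",
    "PARAGRAPH_THRESHOLD",
]

#: Operating point used for comparison with the Paragraph model.
PARAGRAPH_THRESHOLD = 0.734


@dataclasses.dataclass
class PredictionSet:
    """Per-point and per-residue binding scores for one receptor."""

    point_scores: np.ndarray
    residue_scores: dict[ResidueId, float]
    no_surface: set[ResidueId]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.point_scores = np.asarray(self.point_scores, dtype=float)


def aggregate_residue_scores(
    cloud: SurfaceCloud,
    point_scores: np.ndarray,
    residues: list[ResidueId],
) -> tuple[dict[ResidueId, float], set[ResidueId]]:
    """Max-aggregate point scores per residue; surfaceless residues score 0."""
    point_scores = np.asarray(point_scores, dtype=float)
    if len(point_scores) != len(cloud):
        raise ValueError("one score per surface point required")
    scores: dict[ResidueId, float] = {}
    for rid, s in zip(cloud.parents, point_scores):
        prev = scores.get(rid)
        if prev is None or s > prev:
            scores[rid] = float(s)
    no_surface = {r for r in residues if r not in scores}
    for r in no_surface:
        scores[r] = 0.0
    return scores, no_surface


def infer(
    model: ParatopeNet,
    receptor: Structure,
    cloud: SurfaceCloud,
    features: np.ndarray | None = None,
    batch_size: int = 64,
    threshold: float = 0.5,
) -> PredictionSet:
    """Score every surface point of a receptor and aggregate per residue."""
    n_heavy = len(receptor.heavy_atoms())
    if len(cloud) == 0:
        raise ValueError("empty surface cloud")
    if cloud.parent_atom.max(initial=-1) >= n_heavy:
        raise ValueError("surface cloud does not match this receptor")
    if not set(cloud.parents) <= set(receptor.residues):
        raise ValueError("surface cloud references residues absent from the receptor")
    if features is None:
        features = compute_atom_features(receptor)
    size = model.cfg.grid_size
    X = np.zeros((len(cloud), size, size, size, features.shape[1]), dtype=np.float32)
    for i in range(len(cloud)):
        frame = local_frame(cloud.normals[i])
        X[i] = voxelize(receptor, cloud.points[i], frame, features,
                        size=size, resolution=GRID_RESOLUTION).tensor
    point_scores = predict_scores(model, X, batch_size=batch_size)
    residue_scores, no_surface = aggregate_residue_scores(cloud, point_scores,
                                                          receptor.residues)
    return PredictionSet(point_scores=point_scores, residue_scores=residue_scores,
                         no_surface=no_surface, threshold=threshold)


def classify_residues(p: PredictionSet, threshold: float = 0.5) -> dict[ResidueId, bool]:
    """Binding iff residue score strictly exceeds the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return {rid: score > threshold for rid, score in p.residue_scores.items()}


def write_bfactor_pdb(receptor: Structure, p: PredictionSet, path: str | Path) -> None:
    """Write the receptor with each atom's b-factor set to its residue score."""
    write_pdb(receptor, path, bfactors={r: p.residue_scores.get(r, 0.0)
                                        for r in receptor.residues})


def write_pocket_pdb(
    cloud: SurfaceCloud, p: PredictionSet, path: str | Path, threshold: float = 0.5
) -> int:
    """Write pseudo-atoms (HETATM) at surface points scoring above threshold.

    Returns the number of points written.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    sel = np.flatnonzero(np.asarray(p.point_scores) > threshold)
    with open(path, "w") as fh:
        for serial, i in enumerate(sel, start=1):
            x, y, z = cloud.points[i]
            s = float(p.point_scores[i])
            fh.write(
                f"HETATM{serial % 100000:5d}  O   PTS P{serial % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{s:6.2f}           O\n"
            )
        fh.write("END\n")
    return int(len(sel))


def write_score_table(
    p: PredictionSet,
    path: str | Path,
    labels: dict[ResidueId, bool] | None = None,
) -> None:
    """Tab-separated residue table: chain, number, icode, resname, score[, label]."""
    with open(path, "w") as fh:
        header = "chain\tnumber\ticode\tresname\tscore\tno_surface"
        if labels is not None:
            header += "\tlabel"
        fh.write(header + "\n")
        for rid, score in p.residue_scores.items():
            row = (f"{rid.chain}\t{rid.number}\t{rid.icode or '.'}\t{rid.resname}"
                   f"\t{score:.6f}\t{int(rid in p.no_surface)}")
            if labels is not None:
                row += f"\t{int(labels.get(rid, False))}"
            fh.write(row + "\n")
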