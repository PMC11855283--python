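"""Shared brute-force oracles and random fixture builders for the tests.

Everything here is deliberately naive (double loops, O(n²) pair counts)
so it stays independent of the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np

from paragrid.structio import Atom, ResidueId, Structure


def random_structure(rng: np.random.Generator, n_residues: int, role: str,
                     chain: str = "A", box: float = 30.0,
                     atoms_per_res: tuple[int, int] = (1, 4)) -> Structure:
    """Random point-cloud structure with 1-4 heavy atoms per residue."""
    atoms: list[Atom] = []
    residues: list[ResidueId] = []
    elements = ["C", "N", "O", "S"]
    for i in range(n_residues):
        rid = ResidueId(chain=chain, number=i + 1, icode="", resname="GLY")
        residues.append(rid)
        for j in range(rng.integers(atoms_per_res[0], atoms_per_res[1] + 1)):
            atoms.append(Atom(
                element=elements[rng.integers(0, len(elements))],
                coords=rng.uniform(0, box, 3),
                name=f"X{j + 1}",
                is_heavy=True,
                bfactor=0.0,
                occupancy=1.0,
                parent=rid,
            ))
    return Structure(atoms=atoms, residues=residues, role=role)


def brute_force_labels(receptor: Structure, antigen: Structure, cutoff: float) -> dict:
    """All-pairs heavy-atom distance labeling (the independent oracle)."""
    ag = [a.coords for a in antigen.atoms if a.is_heavy]
    out = {}
    for rid in receptor.residues:
        hit = False
        for a in receptor.atoms:
            if a.parent != rid or not a.is_heavy:
                continue
            for c in ag:
                if np.linalg.norm(a.coords - c) <= cutoff:
                    hit = True
                    break
            if hit:
                break
        out[rid] = hit
    return out


def auroc_oracle(y: np.ndarray, s: np.ndarray) -> float:
    """Pairwise concordance AUROC with half-credit for score ties."""
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def average_precision_oracle(y: np.ndarray, s: np.ndarray) -> float:
    """AP = Σ (R_k − R_{k−1}) · P_k over descending unique score thresholds."""
    order = np.argsort(-s, kind="stable")
    y = np.asarray(y)[order]
    s = np.asarray(s)[order]
    n_pos = int(y.sum())
    ap, tp, fp, prev_recall = 0.0, 0, 0, 0.0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:  # group ties at one threshold
            j += 1
        tp += int(y[i:j].sum())
        fp += (j - i) - int(y[i:j].sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def group_max_oracle(parents: list, scores: np.ndarray) -> dict:
    """Naive per-residue max aggregation."""
    out: dict = {}
    for rid, sc in zip(parents, scores):
        out.setdefault(rid, []).append(float(sc))
    return {rid: max(v) for rid, v in out.items()}
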