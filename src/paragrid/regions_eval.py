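"""IMGT region masks, scoped evaluation metrics, and the positional baseline.

IMGT variable-domain numbering assigns fixed position ranges to framework
and CDR segments: FR1 1-26, CDR1 27-38, FR2 39-55, CDR2 56-65, FR3 66-104,
CDR3 105-117, FR4 118-128; positions beyond 128 belong to the constant
domain.  Evaluation scopes nest: CDR ⊆ CDR±2 ⊆ Fv ⊆ Fab.

IMGT positions are supplied as an input mapping table (this package does
not renumber antibodies).  CDR±2 flanks are taken along the ordered chain
sequence, so insertion-code gaps in author numbering cannot skew them.

Metrics: threshold-free AUROC / AUPR (average precision), threshold
metrics (F1, MCC, accuracy, precision, recall, NPV, specificity, FPR),
and CAUROC — the median of per-complex AUROCs, robust to outliers.
Complexes with a single label class have no defined AUROC and are
excluded from the CAUROC median (pooled metrics still include them).
"""

from __future__ import annotations

import dataclasses
import json
import math
import statistics
import warnings
from pathlib import Path

import numpy as np
from sklearn import metrics as skm

from .structio import BindingLabels, ResidueId

__all__ = [
    "REGIONS",
    "RegionMask",
    "MetricsReport",
    "region_of",
    "cdr_pm2_mask",
    "scope_residues",
    "evaluate",
    "evaluate_complexes",
    "positional_baseline",
    "PositionalBaseline",
    "read_imgt_map",
]

# (region, first, last) in IMGT numbering; order defines chain order.
REGIONS = [
    ("FR1", 1, 26),
    ("CDR1", 27, 38),
    ("FR2", 39, 55),
    ("CDR2", 56, 65),
    ("FR3", 66, 104),
    ("CDR3", 105, 117),
    ("FR4", 118, 128),
]
_CDR_NAMES = ("CDR1", "CDR2", "CDR3")
FV_LAST_POSITION = 128


def region_of(imgt_position: int) -> str:
    """Region label for an IMGT position; > 128 is the constant domain."""
    if imgt_position < 1:
        raise ValueError("IMGT positions start at 1")
    for name, lo, hi in REGIONS:
        if lo <= imgt_position <= hi:
            return name
    return "constant"


@dataclasses.dataclass
class RegionMask:
    """Ordered per-residue IMGT assignment for one chain.

    ``entries`` follow chain order; each is (residue, imgt_position,
    region).  ``chain_type`` is "heavy" or "light".
    """

    entries: list[tuple[ResidueId, int, str]]
    chain_type: str

    def __post_init__(self) -> None:
        if self.chain_type not in ("heavy", "light"):
            raise ValueError("chain_type must be 'heavy' or 'light'")
        last = 0
        for rid, pos, region in self.entries:
            if pos < 1:
                raise ValueError(f"{rid}: IMGT position must be >= 1")
            if pos < last:
                raise ValueError(f"{rid}: IMGT positions must be non-decreasing")
            if region_of(pos) != region:
                raise ValueError(f"{rid}: position {pos} is {region_of(pos)}, not {region}")
            last = pos

    def residues(self) -> list[ResidueId]:
        return [rid for rid, _, _ in self.entries]

    def region_residues(self, region: str) -> list[ResidueId]:
        return [rid for rid, _, r in self.entries if r == region]

    def fv_residues(self) -> list[ResidueId]:
        return [rid for rid, pos, _ in self.entries if pos <= FV_LAST_POSITION]

    @classmethod
    def from_positions(cls, residues: list[ResidueId], positions: list[int],
                       chain_type: str) -> "RegionMask":
        entries = [(rid, pos, region_of(pos)) for rid, pos in zip(residues, positions)]
        return cls(entries=entries, chain_type=chain_type)


def cdr_pm2_mask(mask: RegionMask) -> set[ResidueId]:
    """CDR residues plus the two sequence-adjacent flanks of each loop.

    Flanking is by ordered index within the chain, truncated at chain ends.
    """
    out: set[ResidueId] = set()
    n = len(mask.entries)
    i = 0
    while i < n:
        region = mask.entries[i][2]
        if region in _CDR_NAMES:
            j = i
            while j + 1 < n and mask.entries[j + 1][2] == region:
                j += 1
            lo = max(0, i - 2)
            hi = min(n - 1, j + 2)
            out.update(mask.entries[k][0] for k in range(lo, hi + 1))
            i = j + 1
        else:
            i += 1
    return out


def scope_residues(masks: list[RegionMask], scope: str) -> list[ResidueId]:
    """Residues belonging to an evaluation scope across the chain pair.

    Scopes: "CDR", "CDR+-2", "Fv", "Fab", or a single region name
    ("CDR3", "FR1", ...).
    """
    scope_norm = scope.replace("±", "+-")
    out: list[ResidueId] = []
    for mask in masks:
        if scope_norm == "Fab":
            out.extend(mask.residues())
        elif scope_norm == "Fv":
            out.extend(mask.fv_residues())
        elif scope_norm == "CDR+-2":
            sel = cdr_pm2_mask(mask)
            out.extend(r for r in mask.residues() if r in sel)
        elif scope_norm == "CDR":
            for name in _CDR_NAMES:
                out.extend(mask.region_residues(name))
        else:
            out.extend(mask.region_residues(scope_norm))
    return out


@dataclasses.dataclass
class MetricsReport:
    scope: str
    threshold: float
    n_complexes: int
    n_residues: int
    auc_roc: float | None
    auc_pr: float | None
    cauroc: float | None
    f1: float
    mcc: float
    accuracy: float
    precision: float
    recall: float
    npv: float
    spc: float
    fpr: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def _threshold_metrics(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    tp = int(np.sum((y == 1) & yhat))
    tn = int(np.sum((y == 0) & ~yhat))
    fp = int(np.sum((y == 0) & yhat))
    fn = int(np.sum((y == 1) & ~yhat))

    def ratio(a, b):
        return a / b if b else 0.0

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "precision": precision,
        "recall": recall,
        "f1": ratio(2 * precision * recall, precision + recall) if precision + recall else 0.0,
        "mcc": mcc,
        "npv": ratio(tn, tn + fn),
        "spc": ratio(tn, tn + fp),
        "fpr": ratio(fp, fp + tn),
    }


def evaluate(
    scores: dict[ResidueId, float],
    labels: BindingLabels | dict[ResidueId, bool],
    masks: list[RegionMask],
    scope: str = "Fv",
    threshold: float = 0.5,
) -> MetricsReport:
    """Metrics for one complex, restricted to a region scope."""
    return evaluate_complexes([(scores, labels, masks)], scope=scope,
                              threshold=threshold)


def evaluate_complexes(
    complexes: list[tuple],
    scope: str = "Fv",
    threshold: float = 0.5,
    average: str = "micro",
) -> MetricsReport:
    """Pooled (micro) or per-complex-averaged (macro) scoped metrics.

    Each entry of ``complexes`` is (scores dict, labels, region masks).
    CAUROC is always the median of per-complex AUROCs; complexes whose
    scoped labels are single-class are excluded from that median with a
    warning.
    """
    if average not in ("micro", "macro"):
        raise ValueError("average must be 'micro' or 'macro'")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    pooled_y, pooled_s = [], []
    per_auroc, per_aupr, per_thr = [], [], []
    n_res = 0
    for scores, labels, masks in complexes:
        lab = labels.labels if isinstance(labels, BindingLabels) else labels
        resids = [r for r in scope_residues(masks, scope) if r in scores and r in lab]
        if not resids:
            continue
        y = np.array([int(lab[r]) for r in resids])
        s = np.array([scores[r] for r in resids])
        n_res += len(y)
        pooled_y.append(y)
        pooled_s.append(s)
        if len(np.unique(y)) == 2:
            per_auroc.append(float(skm.roc_auc_score(y, s)))
            per_aupr.append(float(skm.average_precision_score(y, s)))
        else:
            warnings.warn("complex with single-class labels in scope: "
                          "excluded from CAUROC", stacklevel=2)
        per_thr.append(_threshold_metrics(y, s > threshold))
    if not pooled_y:
        raise ValueError(f"no residues with both score and label in scope {scope!r}")
    y = np.concatenate(pooled_y)
    s = np.concatenate(pooled_s)
    if average == "micro":
        thr = _threshold_metrics(y, s > threshold)
    else:
        thr = {k: float(np.mean([t[k] for t in per_thr])) for k in per_thr[0]}
    two_class = len(np.unique(y)) == 2
    if not two_class:
        warnings.warn("pooled labels are single-class: AUROC/AUPR undefined",
                      stacklevel=2)
    return MetricsReport(
        scope=scope,
        threshold=threshold,
        n_complexes=len(complexes),
        n_residues=int(n_res),
        auc_roc=float(skm.roc_auc_score(y, s)) if two_class else None,
        auc_pr=float(skm.average_precision_score(y, s)) if two_class else None,
        cauroc=float(statistics.median(per_auroc)) if per_auroc else None,
        **thr,
    )


@dataclasses.dataclass
class PositionalBaseline:
    """Per-position binding proportions learned from a training cohort."""

    proportions: dict[tuple[str, int], float]  # (chain_type, imgt position) -> prop

    def score(self, chain_type: str, imgt_position: int) -> float:
        return self.proportions.get((chain_type, imgt_position), 0.0)

    def predict(self, mask: RegionMask) -> dict[ResidueId, float]:
        return {rid: self.score(mask.chain_type, pos) for rid, pos, _ in mask.entries}


def positional_baseline(
    train: list[tuple[RegionMask, BindingLabels]]
) -> PositionalBaseline:
    """Binding proportion at each (chain type, IMGT position) in training.

    Positions never seen in training score 0 at prediction time.
    """
    if not train:
        raise ValueError("positional baseline requires at least one training complex")
    counts: dict[tuple[str, int], int] = {}
    bound: dict[tuple[str, int], int] = {}
    for mask, labels in train:
        lab = labels.labels if isinstance(labels, BindingLabels) else labels
        for rid, pos, _ in mask.entries:
            if rid not in lab:
                continue
            key = (mask.chain_type, pos)
            counts[key] = counts.get(key, 0) + 1
            bound[key] = bound.get(key, 0) + int(lab[rid])
    props = {k: bound[k] / counts[k] for k in counts}
    return PositionalBaseline(proportions=props)


def read_imgt_map(path: str | Path, residues: list[ResidueId]) -> list[RegionMask]:
    """Read a residue→IMGT mapping table and build per-chain masks.

    Tab-separated columns: chain, chain_type (heavy|light), author number
    (with optional icode suffix), imgt position.  Rows must appear in
    chain order.
    """
    by_key = {(r.chain, r.number, r.icode): r for r in residues}
    per_chain: dict[str, tuple[str, list, list]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chain\t"):
                continue
            tok = line.split("\t")
            if len(tok) < 4:
                raise ValueError(f"{Path(path).name}:{lineno}: need 4 columns")
            chain, ctype, author, imgt = tok[0], tok[1], tok[2], int(tok[3])
            icode = ""
            num_part = author
            if author and author[-1].isalpha():
                num_part, icode = author[:-1], author[-1]
            rid = by_key.get((chain, int(num_part), icode))
            if rid is None:
                raise ValueError(
                    f"{Path(path).name}:{lineno}: residue {chain}/{author} not in structure")
            slot = per_chain.setdefault(chain, (ctype, [], []))
            slot[1].append(rid)
            slot[2].append(imgt)
    return [RegionMask.from_positions(rids, pos, ctype)
            for ctype, rids, pos in per_chain.values()]
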