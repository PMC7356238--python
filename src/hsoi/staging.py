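"""Diabetic-retinopathy staging from PCA scores of mean vessel spectra.

The mean reflectance spectrum of the segmented arteries (or veins) is
projected onto the first two principal components of a reference spectrum
collection; the resulting (FPC, SPC) score pair falls into per-stage
rectangular regions of score space. The shipped default regions are the
published artery and vein score ranges for Normal, background (BDR),
pre-proliferative (PPDR) and proliferative (PDR) retinopathy; regions
overlap in places ("fuzzy zone"), and classification there is resolved by
the nearest box center and explicitly flagged as ambiguous.

Diagnostic quality is summarized by a 4-class confusion matrix and
one-vs-rest sensitivity, precision, F1 and accuracy per stage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "StageLabel",
    "Box",
    "StageRegionSet",
    "DEFAULT_REGIONS",
    "ScoreBasis",
    "mean_reflectance",
    "fit_score_space",
    "pca_scores",
    "classify_stage",
    "build_confusion_matrix",
    "class_metrics",
    "truncate2",
]


class StageLabel(str, Enum):
    """The four stages, ordered by severity."""

    NORMAL = "Normal"
    BDR = "BDR"
    PPDR = "PPDR"
    PDR = "PDR"

    @classmethod
    def ordered(cls) -> list["StageLabel"]:
        return [cls.NORMAL, cls.BDR, cls.PPDR, cls.PDR]


@dataclass(frozen=True)
class Box:
    """Open axis-aligned region (fpc_lo, fpc_hi) x (spc_lo, spc_hi)."""

    fpc_lo: float
    fpc_hi: float
    spc_lo: float
    spc_hi: float

    def __post_init__(self) -> None:
        if not (self.fpc_lo < self.fpc_hi and self.spc_lo < self.spc_hi):
            raise ValueError("box bounds must satisfy lo < hi on both axes")

    def contains(self, fpc: float, spc: float) -> bool:
        # strict inequalities: the published ranges use "<" throughout
        return self.fpc_lo < fpc < self.fpc_hi and self.spc_lo < spc < self.spc_hi

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.fpc_lo + self.fpc_hi), 0.5 * (self.spc_lo + self.spc_hi))

    def boundary_distance(self, fpc: float, spc: float) -> float:
        """Euclidean distance from a point to the (closed) box."""
        dx = max(self.fpc_lo - fpc, 0.0, fpc - self.fpc_hi)
        dy = max(self.spc_lo - spc, 0.0, spc - self.spc_hi)
        return math.hypot(dx, dy)


#: Published per-stage score regions for artery and vein spectra.
DEFAULT_REGIONS: dict[str, dict[StageLabel, Box]] = {
    "artery": {
        StageLabel.NORMAL: Box(-2.00, 2.50, -0.50, 0.00),
        StageLabel.BDR: Box(-2.00, 2.50, -0.30, 0.10),
        StageLabel.PPDR: Box(-1.50, 2.00, -0.10, 0.30),
        StageLabel.PDR: Box(-2.00, 2.00, -0.10, 0.40),
    },
    "vein": {
        StageLabel.NORMAL: Box(-1.50, 2.50, 0.00, 0.40),
        StageLabel.BDR: Box(-2.00, 2.25, -0.10, 0.20),
        StageLabel.PPDR: Box(-1.25, 1.00, -0.15, 0.75),
        StageLabel.PDR: Box(-0.75, 2.75, -0.25, -0.05),
    },
}


@dataclass(frozen=True)
class StageRegionSet:
    """Score-space boxes per vessel type and stage."""

    regions: dict[str, dict[StageLabel, Box]]

    @classmethod
    def default(cls) -> "StageRegionSet":
        return cls(DEFAULT_REGIONS)

    def boxes(self, vessel_type: str) -> dict[StageLabel, Box]:
        if vessel_type not in self.regions:
            raise KeyError(f"unknown vessel type {vessel_type!r}")
        return self.regions[vessel_type]

    def to_json(self) -> str:
        doc = {
            vt: {
                stage.value: [b.fpc_lo, b.fpc_hi, b.spc_lo, b.spc_hi]
                for stage, b in boxes.items()
            }
            for vt, boxes in self.regions.items()
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StageRegionSet":
        doc = json.loads(text)
        return cls(
            {
                vt: {StageLabel(s): Box(*vals) for s, vals in boxes.items()}
                for vt, boxes in doc.items()
            }
        )


def mean_reflectance(
    cube: np.ndarray, mask: np.ndarray, labels: np.ndarray | None = None,
    label: int | None = None,
) -> np.ndarray:
    """Mean spectrum over the selected vessel pixels.

    With ``labels``/``label`` given, restricts to that artery (1) / vein (2)
    label; otherwise averages over the whole mask.
    """
    sel = np.asarray(mask, dtype=bool)
    if labels is not None and label is not None:
        sel = sel & (np.asarray(labels) == label)
    if not sel.any():
        raise ValueError("no pixels selected for the mean spectrum")
    return np.asarray(cube[sel], dtype=float).mean(axis=0)


@dataclass(frozen=True)
class ScoreBasis:
    """Mean-centered 2-component PCA basis for score computation."""

    center: np.ndarray       # 401
    components: np.ndarray   # 2 x 401, orthonormal rows

    def __post_init__(self) -> None:
        if self.components.shape[0] != 2:
            raise ValueError("score basis needs exactly two components")


def fit_score_space(spectra: np.ndarray) -> ScoreBasis:
    """Fit the two-component score space from a collection of spectra.

    ``spectra`` is n x 401 with n >= 3. Components are ordered by explained
    variance; the largest-magnitude loading of each component is made
    positive so the sign convention is deterministic.
    """
    x = np.asarray(spectra, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need at least 3 spectra to fit the score space")
    center = x.mean(axis=0)
    _, _, vt = np.linalg.svd(x - center, full_matrices=False)
    comps = vt[:2]
    signs = np.sign(comps[np.arange(2), np.argmax(np.abs(comps), axis=1)])
    signs[signs == 0] = 1.0
    return ScoreBasis(center=center, components=comps * signs[:, None])


def pca_scores(spectrum: np.ndarray, basis: ScoreBasis) -> tuple[float, float]:
    """(FPC, SPC) projection of one spectrum onto the fitted score space."""
    s = np.asarray(spectrum, dtype=float) - basis.center
    fpc, spc = basis.components @ s
    return float(fpc), float(spc)


def classify_stage(
    point: tuple[float, float],
    regions: StageRegionSet | None = None,
    vessel_type: str = "artery",
) -> tuple[StageLabel, str]:
    """Assign a stage to a score point.

    Returns ``(stage, flag)`` with flag one of ``"unambiguous"`` (exactly
    one region contains the point), ``"ambiguous"`` (several do — the fuzzy
    zone; nearest box center wins) or ``"out-of-range"`` (none does; the
    nearest box by boundary distance wins).
    """
    if regions is None:
        regions = StageRegionSet.default()
    fpc, spc = point
    boxes = regions.boxes(vessel_type)
    hits = [stage for stage, box in boxes.items() if box.contains(fpc, spc)]
    if len(hits) == 1:
        return hits[0], "unambiguous"
    if len(hits) > 1:
        best = min(
            hits,
            key=lambda st: (
                math.hypot(fpc - boxes[st].center[0], spc - boxes[st].center[1]),
                StageLabel.ordered().index(st),
            ),
        )
        return best, "ambiguous"
    best = min(
        boxes,
        key=lambda st: (
            boxes[st].boundary_distance(fpc, spc),
            StageLabel.ordered().index(st),
        ),
    )
    return best, "out-of-range"


def build_confusion_matrix(
    gold: list[StageLabel | str], predicted: list[StageLabel | str]
) -> np.ndarray:
    """4x4 count matrix, rows = gold standard, columns = predicted."""
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted label lists differ in length")
    order = StageLabel.ordered()
    idx = {stage: i for i, stage in enumerate(order)}
    cm = np.zeros((4, 4), dtype=int)
    for g, p in zip(gold, predicted):
        cm[idx[StageLabel(g)], idx[StageLabel(p)]] += 1
    return cm


def truncate2(value: float) -> float:
    """Truncate toward zero at two decimals (the table-rendering convention)."""
    return math.trunc(value * 100.0) / 100.0


def class_metrics(cm: np.ndarray, cls: StageLabel | str) -> dict[str, float]:
    """One-vs-rest sensitivity, precision, F1 and accuracy, in percent.

    Values are full precision; use :func:`truncate2` for table rendering.
    A zero row or column makes the affected metric NaN.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    i = StageLabel.ordered().index(StageLabel(cls))
    tp = cm[i, i]
    row = cm[i, :].sum()
    col = cm[:, i].sum()
    sens = 100.0 * tp / row if row > 0 else float("nan")
    prec = 100.0 * tp / col if col > 0 else float("nan")
    if math.isnan(sens) or math.isnan(prec) or (sens + prec) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * sens * prec / (sens + prec)
    tn = total - row - col + tp
    acc = 100.0 * (tp + tn) / total
    return {"sensitivity": sens, "precision": prec, "f1": f1, "accuracy": acc}
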