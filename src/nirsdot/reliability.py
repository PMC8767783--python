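"""Cross-session agreement of activation maps and t-images.

Each recording date classifies every voxel into one of three categories
(L>R, L<R, none); dates are treated as raters and voxels as subjects.
Chance-corrected multi-rater agreement is scored with Fleiss's kappa and
Gwet's AC1 (robust to category imbalance), spatial overlap with the Dice
coefficient over date pairs, detection constancy with the mean fraction
of significant voxels, and ROI-level reproducibility with the one-way
random-effects intraclass correlation ICC(1,1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_CATEGORIES = (-1, 0, 1)


@dataclass
class ReliabilityReport:
    fleiss_kappa: float
    gwet_ac1: float
    dice_mean: float
    detection_rate: float
    icc11: float | None = None
    hb_image_correlation: float | None = None
    core_overlap_rate: float | None = None

    def to_json(self, path: str) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {k: (None if v is None else float(v)) for k, v in self.__dict__.items()},
                fh,
                indent=2,
            )


def classify_by_date(maps: list) -> np.ndarray:
    """Stack per-date activation classes into an N x D category table."""
    cols = [m.classes if hasattr(m, "classes") else np.asarray(m) for m in maps]
    n = len(cols[0])
    if any(len(c) != n for c in cols):
        raise ValueError("activation maps do not share a voxel set")
    return np.column_stack(cols)


def _category_counts(table: np.ndarray, categories=DEFAULT_CATEGORIES) -> np.ndarray:
    """(N, Q) counts of ratings per subject and category."""
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("need an N x D table with D >= 2 raters")
    return np.stack([(table == c).sum(axis=1) for c in categories], axis=1)


def _observed_agreement(counts: np.ndarray) -> float:
    D = counts.sum(axis=1)
    if np.any(D < 2):
        raise ValueError("every subject needs at least 2 ratings")
    pa = ((counts * (counts - 1)).sum(axis=1) / (D * (D - 1))).mean()
    return float(pa)


def fleiss_kappa(table: np.ndarray, categories=DEFAULT_CATEGORIES) -> float:
    """Multi-rater Fleiss kappa over the given categories."""
    counts = _category_counts(table, categories)
    pa = _observed_agreement(counts)
    pi = counts.sum(axis=0) / counts.sum()
    pe = float((pi**2).sum())
    if pe >= 1.0:
        raise ValueError("chance agreement is 1 (single category); kappa undefined")
    return (pa - pe) / (1.0 - pe)


def gwet_ac1(table: np.ndarray, categories=DEFAULT_CATEGORIES) -> float:
    """Gwet's AC1: chance agreement sum_q pi_q (1 - pi_q) / (Q - 1)."""
    counts = _category_counts(table, categories)
    pa = _observed_agreement(counts)
    pi = counts.sum(axis=0) / counts.sum()
    Q = len(categories)
    pe = float((pi * (1.0 - pi)).sum() / (Q - 1))
    if pe >= 1.0:
        raise ValueError("degenerate chance agreement; AC1 undefined")
    return (pa - pe) / (1.0 - pe)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """2|A&B| / (|A| + |B|)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return np.nan
    return 2.0 * float((a & b).sum()) / float(denom)


def dice_pairs(table: np.ndarray, labels=(1, -1)) -> float:
    """Mean Dice over all unordered date pairs and both activation labels.

    Pairs where both masks are empty are skipped (0/0 convention) with a
    log record rather than scored as 0.
    """
    table = np.asarray(table)
    D = table.shape[1]
    if D < 2:
        raise ValueError("need at least 2 dates")
    vals, skipped = [], 0
    for lab in labels:
        for i in range(D):
            for j in range(i + 1, D):
                d = dice(table[:, i] == lab, table[:, j] == lab)
                if np.isnan(d):
                    skipped += 1
                else:
                    vals.append(d)
    if skipped:
        logger.info("dice_pairs: skipped %d empty-mask pairs", skipped)
    return float(np.mean(vals)) if vals else np.nan


def detection_rate(table: np.ndarray) -> float:
    """Mean over dates of the fraction of voxels with any significant class."""
    table = np.asarray(table)
    return float((table != 0).mean(axis=0).mean())


def icc_1_1(roi_t_table: np.ndarray) -> float:
    """One-way random-effects ICC(1,1): (BMS - WMS)/(BMS + (D-1) WMS).

    Rows are ROIs (targets), columns dates (raters).  Negative values
    (between-ROI variance below the noise floor) are reported as-is.
    """
    X = np.asarray(roi_t_table, dtype=float)
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 ROIs and 2 dates")
    row_means = X.mean(axis=1)
    grand = X.mean()
    bss = k * ((row_means - grand) ** 2).sum()
    wss = ((X - row_means[:, None]) ** 2).sum()
    bms = bss / (n - 1)
    wms = wss / (n * (k - 1))
    return float((bms - wms) / (bms + (k - 1) * wms))


def image_correlation(t_a: np.ndarray, t_b: np.ndarray) -> float:
    """Pearson correlation between two t-images (e.g. HbO vs HbR)."""
    return float(np.corrcoef(np.asarray(t_a), np.asarray(t_b))[0, 1])


def core_overlap_rate(core_hbo: np.ndarray, core_hbr: np.ndarray) -> float:
    """Overlap between HbO and HbR core maps, averaged over tasks.

    HbO and HbR respond with opposite signs, so the L>R HbO core is
    compared with the L<R HbR core and vice versa; each side's overlap
    is the intersection over the core size, averaged.
    """
    rates = []
    for side in (1, -1):
        a = np.asarray(core_hbo) == side
        b = np.asarray(core_hbr) == -side
        if a.sum() == 0:
            continue
        rates.append((a & b).sum() / a.sum())
    return float(np.mean(rates)) if rates else np.nan


def evaluate_reliability(
    maps_by_date: list,
    roi_t_table: np.ndarray | None = None,
    t_hbo: np.ndarray | None = None,
    t_hbr: np.ndarray | None = None,
    core_hbo: np.ndarray | None = None,
    core_hbr: np.ndarray | None = None,
) -> ReliabilityReport:
    """Assemble the full per-method reliability report."""
    table = classify_by_date(maps_by_date)
    return ReliabilityReport(
        fleiss_kappa=fleiss_kappa(table),
        gwet_ac1=gwet_ac1(table),
        dice_mean=dice_pairs(table),
        detection_rate=detection_rate(table),
        icc11=None if roi_t_table is None else icc_1_1(roi_t_table),
        hb_image_correlation=None
        if t_hbo is None or t_hbr is None
        else image_correlation(t_hbo, t_hbr),
        core_overlap_rate=None
        if core_hbo is None or core_hbr is None
        else core_overlap_rate(core_hbo, core_hbr),
    )
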