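"""ROI-level HIF-1a scoring from immunohistochemistry cell tables.

A cell carries a staining-intensity category 0 (negative) to 3
(strongly positive).  The ROI score multiplies the percent of positive
cells (0-100) by the mean intensity category among positive cells
(0-3), giving a 0-300 scale; a score above 150 marks a region of high
HIF-1a expression.  A score of exactly 150 is assigned to the low
class, which keeps the published > / < rule a partition.

An H-score variant (sum over categories of category x percent-in-
category) is provided as an explicitly flagged alternative; it is not
the headline score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

HIGH_CUT_DEFAULT = 150.0
MAX_SCORE = 300.0


@dataclass(frozen=True)
class HifScore:
    """Score for one ROI's cell population."""

    n_cells: int
    percent_positive: float  # 0-100
    intensity: float         # mean category of positive cells, 0-3
    score: float             # percent_positive * intensity, 0-300
    label: str               # "high" | "low"


def classify_cell_intensity(optical_density, thresholds) -> np.ndarray:
    """Map continuous stain densities to categories 0-3.

    ``thresholds`` are the three strictly increasing category cut
    points; the category is the number of thresholds at or below the
    density (ties resolve upward).
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.size != 3 or np.any(np.diff(thr) <= 0):
        raise ValueError("thresholds must be three strictly increasing values")
    od = np.asarray(optical_density, dtype=float)
    return np.searchsorted(thr, od, side="right").astype(np.int8)


def score_roi(categories, high_cut: float = HIGH_CUT_DEFAULT) -> HifScore:
    """Score one ROI from its cells' intensity categories.

    Raises
    ------
    ValueError
        For an empty cell set (the caller must exclude such ROIs).
    """
    cat = np.asarray(categories, dtype=int)
    if cat.size == 0:
        raise ValueError("ROI contains no cells; exclude it upstream")
    if cat.min() < 0 or cat.max() > 3:
        raise ValueError("categories must lie in {0, 1, 2, 3}")
    positive = cat > 0
    pct = 100.0 * positive.sum() / cat.size
    intensity = float(cat[positive].mean()) if positive.any() else 0.0
    score = pct * intensity
    return HifScore(
        n_cells=int(cat.size), percent_positive=float(pct),
        intensity=intensity, score=float(score),
        label=label_expression(score, high_cut),
    )


def label_expression(score: float, high_cut: float = HIGH_CUT_DEFAULT) -> str:
    """Dichotomize a 0-300 score: > cut is "high", otherwise "low"."""
    if not 0.0 <= score <= MAX_SCORE:
        raise ValueError("score must lie in [0, 300]")
    return "high" if score > high_cut else "low"


def h_score(categories) -> float:
    """Alternative histopathology H-score: sum of category x percent.

    Range 0-300 like the headline score but computed from the full
    category histogram; reported only as a flagged alternative.
    """
    cat = np.asarray(categories, dtype=int)
    if cat.size == 0:
        raise ValueError("ROI contains no cells")
    pct = np.bincount(cat, minlength=4) / cat.size * 100.0
    return float((np.arange(4) * pct).sum())
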