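"""TIRFM single-molecule stoichiometry by photobleaching step counting.

Pipeline over a single-channel image stack of sparse, fixed fluorescent
spots:

1. :func:`detect_spots` — local maxima of the (lightly smoothed) mean of
   the first frames above a robust background threshold; candidate pairs
   closer than 5 px are both discarded so every accepted spot is an
   isolated diffraction-limited molecule.
2. :func:`extract_trace` — per-frame 5×5 summed intensity minus the local
   background (median of a surrounding annulus), giving a
   background-corrected trace.
3. :func:`fit_steps` (see :mod:`smolbind.stepfit`) and
   :func:`classify_stoichiometry` — accepted traces bleaching in 1/2/3
   steps are monomers/dimers/trimers.
4. :func:`tally_stoichiometry` — per-condition counts and percentages of
   counted spots; the two-step percentage is the dimer percentage.
5. :func:`compare_dimer_fractions` — one-way ANOVA plus Tukey HSD across
   conditions on per-cell dimer percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from ._errors import BoundsError, DetectionError, InputError, StatisticsError
from ._util import MAD_SCALE, round_half_up
from .simulate import IntensityTrace
from .stepfit import StepFitResult, StepModel, fit_steps  # noqa: F401  (re-export)

__all__ = [
    "SpotLocation",
    "DetectionParams",
    "StoichiometryCounts",
    "DimerComparisonResult",
    "detect_spots",
    "extract_trace",
    "fit_steps",
    "classify_stoichiometry",
    "tally_stoichiometry",
    "dimer_confidence_interval",
    "compare_dimer_fractions",
]

REGION_HALF = 2  # 5x5 analysis region
ANNULUS_INNER = 3  # exclude the inner 7x7
ANNULUS_OUTER = 5  # annulus out to 11x11


@dataclass(frozen=True)
class SpotLocation:
    """A detected spot: 0-based center and its half-open 5×5 region."""

    row: float
    col: float

    @property
    def region(self) -> tuple[int, int, int, int]:
        """(r0, r1, c0, c1) half-open bounds of the 5×5 region."""
        r, c = int(round(self.row)), int(round(self.col))
        return r - REGION_HALF, r + REGION_HALF + 1, c - REGION_HALF, c + REGION_HALF + 1


@dataclass
class DetectionParams:
    """Spot-detection settings.

    The detection image is the mean of the first ``k_frames`` frames,
    Gaussian-smoothed by ``smooth_sigma`` px (a matched-filter aid for
    dim spots); the threshold is the image median plus ``threshold_sd``
    robust SDs (MAD·1.4826) of the smoothed image.
    """

    k_frames: int = 10
    threshold_sd: float = 5.0
    smooth_sigma: float = 1.0
    min_separation: float = 5.0  # px; closer pairs are all discarded


def detect_spots(
    stack: np.ndarray, params: Optional[DetectionParams] = None
) -> list[SpotLocation]:
    """Detect isolated diffraction-limited spots.

    Returns accepted spots in row-major (deterministic) order. Candidates
    whose 5×5 region would leave the image and *all* members of pairs
    closer than ``min_separation`` px are discarded.
    """
    params = params or DetectionParams()
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.size == 0:
        raise DetectionError("stack must be a non-empty (frames, rows, cols) array")
    mean_img = stack[: params.k_frames].mean(axis=0)
    if np.ptp(mean_img) == 0:
        raise DetectionError("zero-variance stack; nothing to detect")
    img = (
        ndimage.gaussian_filter(mean_img, params.smooth_sigma)
        if params.smooth_sigma > 0
        else mean_img
    )
    med = np.median(img)
    rsd = MAD_SCALE * np.median(np.abs(img - med))
    threshold = med + params.threshold_sd * rsd

    local_max = img == ndimage.maximum_filter(img, size=3, mode="nearest")
    rows, cols = np.nonzero(local_max & (img > threshold))
    h, w = img.shape
    inside = (
        (rows >= REGION_HALF) & (rows < h - REGION_HALF)
        & (cols >= REGION_HALF) & (cols < w - REGION_HALF)
    )
    rows, cols = rows[inside], cols[inside]

    pts = np.column_stack([rows, cols]).astype(float)
    keep = np.ones(len(pts), dtype=bool)
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if np.hypot(*(pts[i] - pts[j])) < params.min_separation:
                keep[i] = keep[j] = False
    pts = pts[keep]
    order = np.lexsort((pts[:, 1], pts[:, 0]))  # row-major
    return [SpotLocation(float(r), float(c)) for r, c in pts[order]]


def extract_trace(
    stack: np.ndarray, spot: SpotLocation, frame_interval: float = 0.1
) -> IntensityTrace:
    """Background-corrected intensity trace of one spot.

    Per frame: sum over the 5×5 region minus 25 × the median of a
    surrounding annulus (inner 7×7 excluded, outer 11×11, clipped at the
    image border).
    """
    stack = np.asarray(stack, dtype=float)
    n_frames, h, w = stack.shape
    r0, r1, c0, c1 = spot.region
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise BoundsError("5x5 spot region lies outside the image")
    signal = stack[:, r0:r1, c0:c1].sum(axis=(1, 2))

    r, c = int(round(spot.row)), int(round(spot.col))
    rr0, rr1 = max(r - ANNULUS_OUTER, 0), min(r + ANNULUS_OUTER + 1, h)
    cc0, cc1 = max(c - ANNULUS_OUTER, 0), min(c + ANNULUS_OUTER + 1, w)
    patch = stack[:, rr0:rr1, cc0:cc1]
    pr, pc = np.meshgrid(np.arange(rr0, rr1), np.arange(cc0, cc1), indexing="ij")
    annulus = (np.abs(pr - r) > ANNULUS_INNER) | (np.abs(pc - c) > ANNULUS_INNER)
    if not annulus.any():
        raise BoundsError("annulus is empty; spot too close to the border")
    background = np.median(patch[:, annulus], axis=1)
    return IntensityTrace(signal - 25.0 * background, frame_interval)


def classify_stoichiometry(fit: StepFitResult) -> Union[int, str]:
    """Map an accepted 1/2/3-step fit to its subunit count, else 'rejected'."""
    if fit.accepted and fit.n_steps in (1, 2, 3):
        return fit.n_steps
    return "rejected"


@dataclass
class StoichiometryCounts:
    """Per-condition tally of photobleaching step classes."""

    n_one: int
    n_two: int
    n_three: int
    n_rejected: int
    condition: str = ""

    @property
    def n_counted(self) -> int:
        return self.n_one + self.n_two + self.n_three

    @property
    def pct_one(self) -> float:
        return round_half_up(100.0 * self.n_one / self.n_counted)

    @property
    def pct_two(self) -> float:
        """The dimer percentage."""
        return round_half_up(100.0 * self.n_two / self.n_counted)

    @property
    def pct_three(self) -> float:
        return round_half_up(100.0 * self.n_three / self.n_counted)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "condition": self.condition,
                    "n_one": self.n_one, "n_two": self.n_two,
                    "n_three": self.n_three, "n_rejected": self.n_rejected,
                    "n_counted": self.n_counted,
                    "pct_one": self.pct_one, "pct_two": self.pct_two,
                    "pct_three": self.pct_three,
                }
            ]
        )

    def summary(self) -> str:
        return (
            f"{self.condition or 'condition'}: {self.n_counted} counted spots "
            f"({self.n_rejected} rejected) -> "
            f"{self.pct_one}% monomer, {self.pct_two}% dimer, "
            f"{self.pct_three}% trimer"
        )


def tally_stoichiometry(
    classifications: Sequence[Union[int, str]], condition: str = ""
) -> StoichiometryCounts:
    """Tally classifications into counts and printed-style percentages.

    Percentages are of counted (non-rejected) spots, one decimal, rounded
    half away from zero.
    """
    if len(classifications) == 0:
        raise InputError("no classifications to tally")
    n1 = sum(1 for c in classifications if c == 1)
    n2 = sum(1 for c in classifications if c == 2)
    n3 = sum(1 for c in classifications if c == 3)
    nrej = len(classifications) - n1 - n2 - n3
    if n1 + n2 + n3 == 0:
        raise InputError("all spots rejected; nothing to tally")
    return StoichiometryCounts(n1, n2, n3, nrej, condition)


def dimer_confidence_interval(
    counts: StoichiometryCounts, level: float = 0.95
) -> tuple[float, float]:
    """Exact (Clopper–Pearson) CI, in percent, for the dimer fraction."""
    k, n = counts.n_two, counts.n_counted
    alpha = 1.0 - level
    lo = sps.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = sps.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return 100.0 * float(lo), 100.0 * float(hi)


@dataclass
class DimerComparisonResult:
    """One-way ANOVA + Tukey HSD on per-cell dimer percentages."""

    f_statistic: float
    pvalue: float
    comparisons: pd.DataFrame  # pairwise Tukey-adjusted p-values
    group_labels: tuple
    group_sizes: tuple

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA on per-cell dimer percentages: "
            f"F = {self.f_statistic:.4f}, p = {self.pvalue:.6g}",
            f"groups: {dict(zip(self.group_labels, self.group_sizes))}",
            "Tukey HSD pairwise comparisons:",
            self.comparisons.to_string(index=False),
        ]
        return "\n".join(lines)


def compare_dimer_fractions(
    per_cell: Union[Mapping[str, Sequence[float]], Sequence[StoichiometryCounts]],
) -> DimerComparisonResult:
    """Compare conditions by their per-cell dimer percentages.

    ``per_cell`` is either a mapping {condition: per-cell dimer
    percentages} or a flat sequence of per-cell :class:`StoichiometryCounts`
    (grouped by their ``condition`` labels). Statistics run on cells as
    replicates, not on pooled spots.
    """
    if not isinstance(per_cell, Mapping):
        grouped: dict[str, list[float]] = {}
        for tally in per_cell:
            grouped.setdefault(tally.condition, []).append(tally.pct_two)
        per_cell = grouped
    labels = list(per_cell.keys())
    groups = [np.asarray(list(v), dtype=float) for v in per_cell.values()]
    if len(groups) < 2:
        raise StatisticsError("need >= 2 conditions to compare")
    if any(g.size < 2 for g in groups):
        raise StatisticsError("need >= 2 replicate cells per condition")

    degenerate = np.ptp(np.concatenate(groups)) == 0
    if degenerate:
        f_stat, pvalue = 0.0, 1.0
    else:
        f_stat, pvalue = sps.f_oneway(*groups)
        tukey = sps.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                    "p_adjusted": 1.0 if degenerate else float(tukey.pvalue[i, j]),
                }
            )
    return DimerComparisonResult(
        float(f_stat), float(pvalue), pd.DataFrame(rows),
        tuple(labels), tuple(g.size for g in groups),
    )
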