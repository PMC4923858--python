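"""AFM single-molecule force spectroscopy analysis.

From force–distance cycles measured with a ligand-functionalized
cantilever on live cells:

* :func:`read_force_curves` / :func:`write_force_curve` — plain-text
  dialect, one file per curve (header lines ``#id``,
  ``#spring_constant_N_per_m``, ``#loading_rate_pN_per_s``,
  ``#segment approach|retract``; data rows
  ``separation_nm<TAB>deflection_nm``). Deflection is converted to force
  at parse time: F[pN] = k[N/m] · d[nm] · 1000.
* :func:`correct_baseline` — linear baseline from the far quarter of the
  retract subtracted from both segments; contact point from the zero
  crossing of the corrected approach.
* :func:`detect_ruptures` — discontinuous force relaxations on the
  retract found by gap-differencing the median-filtered trace against a
  robust noise estimate. Events within ``d_min`` of contact are
  nonspecific adhesion; among the rest the one at largest separation is
  the specific event (last-rupture rule).
* :class:`ForceHistogramModel` — single-Gaussian least-squares fit to the
  Freedman–Diaconis rupture-force histogram; the peak is the binding
  force.
* :func:`binding_probability` — per-experiment fraction of curves with a
  specific event, mean ± SEM across experiments, with a single-molecule
  regime flag (< 30%).
* :func:`compare_forces` — exact Mann–Whitney comparison (see
  :mod:`smolbind.stats`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit

from ._errors import (
    CorrectionError,
    FitError,
    InputError,
    ParseError,
    StateError,
)
from ._util import MAD_SCALE
from .simulate import ForceCurve
from .stats import MannWhitneyResult, mannwhitney_exact

__all__ = [
    "RuptureEvent",
    "RuptureParams",
    "ForceHistogramModel",
    "ForceHistogramFit",
    "BindingProbability",
    "read_force_curves",
    "write_force_curve",
    "correct_baseline",
    "detect_ruptures",
    "fit_force_histogram",
    "binding_probability",
    "compare_forces",
]

logger = logging.getLogger(__name__)

PN_PER_NM_PER_NPM = 1000.0  # (N/m)·nm -> pN


# --------------------------------------------------------------------------
# file dialect
# --------------------------------------------------------------------------

def write_force_curve(path, curve: ForceCurve) -> None:
    """Write one curve in the plain-text dialect (deflection in nm)."""
    k = float(curve.spring_constant)
    with open(path, "w") as fh:
        fh.write(f"#id {curve.curve_id}\n")
        fh.write(f"#spring_constant_N_per_m {k!r}\n")
        fh.write(f"#loading_rate_pN_per_s {float(curve.loading_rate)!r}\n")
        for name, sep, force in (
            ("approach", curve.approach_separation, curve.approach_force),
            ("retract", curve.retract_separation, curve.retract_force),
        ):
            fh.write(f"#segment {name}\n")
            for s, f in zip(sep, force):
                fh.write(f"{float(s)!r}\t{float(f) / (k * PN_PER_NM_PER_NPM)!r}\n")


def _parse_curve_file(path: Path, spring_constant: Optional[float]) -> ForceCurve:
    curve_id = path.stem
    k: Optional[float] = None
    loading_rate = float("nan")
    segments: dict[str, list[tuple[float, float]]] = {}
    current: Optional[str] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                fields = line[1:].split(None, 1)
                key = fields[0]
                val = fields[1] if len(fields) > 1 else ""
                if key == "id":
                    curve_id = val
                elif key == "spring_constant_N_per_m":
                    k = float(val)
                elif key == "loading_rate_pN_per_s":
                    loading_rate = float(val)
                elif key == "segment":
                    if val not in ("approach", "retract"):
                        raise ParseError(
                            f"{path}:{lineno}: unknown segment tag {val!r}"
                        )
                    current = val
                    segments[current] = []
                else:
                    raise ParseError(f"{path}:{lineno}: unknown header {key!r}")
                continue
            if current is None:
                raise ParseError(f"{path}:{lineno}: data row before any #segment")
            parts = line.split("\t")
            try:
                s, d = float(parts[0]), float(parts[1])
            except (IndexError, ValueError):
                logger.warning("%s:%d: malformed data row rejected: %r",
                               path, lineno, line)
                continue
            segments[current].append((s, d))

    if spring_constant is not None:
        k = float(spring_constant)
    if k is None:
        raise ParseError(f"{path}: missing #spring_constant_N_per_m header")
    for name in ("approach", "retract"):
        if name not in segments or not segments[name]:
            raise ParseError(f"{path}: missing or empty {name} segment")
    arrays = {}
    for name, rows in segments.items():
        a = np.asarray(rows, dtype=float)
        sep, defl = a[:, 0], a[:, 1]
        d = np.diff(sep)
        if not (np.all(d >= 0) or np.all(d <= 0)):
            raise ParseError(f"{path}: non-monotone separation in {name} segment")
        arrays[name] = (sep, defl * k * PN_PER_NM_PER_NPM)
    return ForceCurve(
        approach_separation=arrays["approach"][0],
        approach_force=arrays["approach"][1],
        retract_separation=arrays["retract"][0],
        retract_force=arrays["retract"][1],
        spring_constant=k,
        loading_rate=loading_rate,
        curve_id=curve_id,
    )


def read_force_curves(
    path, spring_constant: Optional[float] = None
) -> list[ForceCurve]:
    """Read one curve file or a directory of ``*.txt`` curve files.

    ``spring_constant`` (N/m), when given, overrides the file headers.
    """
    p = Path(path)
    files = sorted(p.glob("*.txt")) if p.is_dir() else [p]
    if not files:
        raise ParseError(f"no curve files found under {p}")
    return [_parse_curve_file(f, spring_constant) for f in files]


# --------------------------------------------------------------------------
# baseline and contact point
# --------------------------------------------------------------------------

def correct_baseline(curve: ForceCurve, noise_sd_mult: float = 5.0) -> ForceCurve:
    """Subtract a linear baseline and locate the contact point.

    The baseline is fitted to the final 25% of the retract (largest
    separations, far from the surface) and subtracted from both segments.
    The contact point is the zero crossing of the corrected approach on
    the way into the repulsive contact regime: the largest separation at
    which the approach force has decayed back to zero after exceeding the
    noise floor.
    """
    n = curve.retract_separation.size
    if n < 50:
        raise InputError("retract segment needs >= 50 points for baseline fitting")
    order = np.argsort(curve.retract_separation)
    sep_r = curve.retract_separation[order]
    force_r = curve.retract_force[order]
    tail = slice(int(np.ceil(0.75 * n)), n)
    s_tail, f_tail = sep_r[tail], force_r[tail]
    if s_tail.size < 2 or np.ptp(s_tail) == 0:
        raise CorrectionError("degenerate baseline region")
    slope, intercept = np.polyfit(s_tail, f_tail, 1)

    def debase(sep: np.ndarray, force: np.ndarray) -> np.ndarray:
        return force - (intercept + slope * sep)

    app_f = debase(curve.approach_separation, curve.approach_force)
    ret_f = debase(curve.retract_separation, curve.retract_force)

    # contact point from the corrected approach
    o = np.argsort(curve.approach_separation)
    s_a, f_a = curve.approach_separation[o], app_f[o]
    noise = MAD_SCALE * np.median(np.abs(f_a[s_a > np.median(s_a)]))
    lift = noise_sd_mult * max(noise, 1e-12)
    above = np.nonzero(f_a > lift)[0]
    if above.size:
        i = int(above.max())  # last (largest-separation) strongly repulsive point
        j = np.nonzero(f_a[i:] <= 0)[0]
        contact = float(s_a[i + j.min()]) if j.size else float(s_a[i])
    else:
        contact = 0.0

    out = replace(
        curve,
        approach_force=app_f,
        retract_force=ret_f,
        baseline_corrected=True,
        contact_nm=contact,
    )
    return out


# --------------------------------------------------------------------------
# rupture detection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RuptureEvent:
    """A discontinuous force relaxation on the retract."""

    force: float  # pN, magnitude of the drop
    separation: float  # nm (absolute, same axis as the curve)
    distance_from_contact: float  # nm
    specific: bool


@dataclass
class RuptureParams:
    """Rupture-detection settings."""

    n_sigma: float = 4.0  # jump threshold in noise SDs
    d_min: float = 10.0  # nm from contact; closer events are nonspecific
    median_kernel: int = 5  # samples, trace pre-smoothing
    gap: int = 3  # samples spanned by the jump difference


def detect_ruptures(
    curve: ForceCurve, params: Optional[RuptureParams] = None
) -> list[RuptureEvent]:
    """Detect rupture events on a baseline-corrected retract.

    The retract force is median-filtered; upward jumps (bond release
    toward baseline) over ``gap`` samples exceeding ``n_sigma`` robust
    noise SDs are events. Events nearer than ``d_min`` to the contact
    point are flagged nonspecific; of the remaining events only the one
    at largest separation keeps the specific flag (last-rupture rule).
    """
    params = params or RuptureParams()
    if not curve.baseline_corrected or curve.contact_nm is None:
        raise StateError("detect_ruptures requires a baseline-corrected curve")
    order = np.argsort(curve.retract_separation)
    sep = curve.retract_separation[order]
    force = curve.retract_force[order]
    smoothed = ndimage.median_filter(force, size=params.median_kernel, mode="nearest")
    d = np.diff(force)
    noise = MAD_SCALE * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
    noise = max(noise, 1e-12)

    g = params.gap
    jump = smoothed[g:] - smoothed[:-g]
    hits = np.nonzero(jump > params.n_sigma * noise)[0]
    events: list[RuptureEvent] = []
    if hits.size:
        # cluster contiguous hit runs into single events
        breaks = np.nonzero(np.diff(hits) > g + params.median_kernel)[0]
        clusters = np.split(hits, breaks + 1)
        raw_diff = np.diff(force)
        for cl in clusters:
            i = int(cl[np.argmax(jump[cl])])
            # localize the drop on the raw trace; the rupture force is the
            # force at the last loaded sample (single-sample read noise is
            # part of the measurement, unbiased for the histogram peak)
            lo = max(i - 1, 0)
            hi = min(i + g + 1, raw_diff.size)
            j = lo + int(np.argmax(raw_diff[lo:hi]))
            pre = float(force[j])
            post = float(
                np.median(force[j + 1: min(j + 1 + params.median_kernel, force.size)])
            )
            magnitude = post - pre
            if magnitude <= 0:
                continue
            s_evt = float(sep[j])
            events.append(
                RuptureEvent(
                    force=magnitude,
                    separation=s_evt,
                    distance_from_contact=s_evt - curve.contact_nm,
                    specific=False,
                )
            )
    # specific flag: beyond d_min, largest separation wins
    candidates = [
        e for e in events if e.distance_from_contact >= params.d_min
    ]
    if candidates:
        last = max(candidates, key=lambda e: e.separation)
        events = [
            replace(e, specific=(e is last)) for e in events
        ]
    return events


# --------------------------------------------------------------------------
# force histogram fit
# --------------------------------------------------------------------------

@dataclass
class ForceHistogramFit:
    """Single-Gaussian fit of a rupture-force histogram."""

    peak: float  # pN, fitted mean
    sd: float  # pN
    amplitude: float  # counts at the peak
    bin_width: float  # pN
    n_forces: int
    goodness: float  # R^2 of the Gaussian against bin counts
    good_fit: bool  # goodness above threshold (single maximum adequate)
    bin_centers: np.ndarray
    bin_counts: np.ndarray

    def summary(self) -> str:
        lines = [
            "Rupture-force histogram fit (single Gaussian)",
            "-" * 45,
            f"n forces:    {self.n_forces}",
            f"peak:        {self.peak:.2f} pN",
            f"SD:          {self.sd:.2f} pN",
            f"bin width:   {self.bin_width:.2f} pN (Freedman-Diaconis)",
            f"R^2:         {self.goodness:.4f}",
            f"single-peak fit adequate: {self.good_fit}",
        ]
        return "\n".join(lines)


class ForceHistogramModel:
    """Least-squares Gaussian model of the binned rupture forces.

    Freedman–Diaconis binning; the fit is initialized at the sample mean
    and SD. ``goodness_threshold`` flags distributions a single maximum
    does not describe (e.g. bimodal force populations).
    """

    def __init__(self, forces, goodness_threshold: float = 0.8) -> None:
        self.forces = np.asarray(list(forces), dtype=float)
        if self.forces.size < 30:
            raise InputError(
                f"need >= 30 rupture forces to fit a histogram "
                f"(got {self.forces.size})"
            )
        if np.ptp(self.forces) == 0:
            raise FitError("all forces identical; histogram fit is degenerate")
        self.goodness_threshold = float(goodness_threshold)

    def fit(self) -> ForceHistogramFit:
        counts, edges = np.histogram(self.forces, bins="fd")
        centers = 0.5 * (edges[:-1] + edges[1:])
        width = float(edges[1] - edges[0])

        def gauss(x, a, mu, s):
            return a * np.exp(-((x - mu) ** 2) / (2.0 * s**2))

        p0 = [counts.max(), self.forces.mean(), max(self.forces.std(), width)]
        lo, hi = self.forces.min(), self.forces.max()
        # the mean is constrained to the observed range; a distribution a
        # single maximum cannot describe then simply fits poorly (low R^2)
        bounds = ([0.0, lo, width / 10.0], [np.inf, hi, hi - lo + width])
        try:
            popt, _ = curve_fit(
                gauss, centers, counts, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError as exc:
            raise FitError(f"Gaussian histogram fit did not converge: {exc}") from exc
        a, mu, s = float(popt[0]), float(popt[1]), abs(float(popt[2]))
        resid = counts - gauss(centers, *popt)
        sst = float(np.sum((counts - counts.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
        return ForceHistogramFit(
            peak=mu, sd=s, amplitude=a, bin_width=width,
            n_forces=self.forces.size, goodness=r2,
            good_fit=r2 >= self.goodness_threshold,
            bin_centers=centers, bin_counts=counts,
        )


def fit_force_histogram(forces, goodness_threshold: float = 0.8) -> ForceHistogramFit:
    """Functional wrapper over :class:`ForceHistogramModel`."""
    return ForceHistogramModel(forces, goodness_threshold).fit()


# --------------------------------------------------------------------------
# binding probability
# --------------------------------------------------------------------------

@dataclass
class BindingProbability:
    """Binding probability of a condition across independent experiments."""

    n_with_event: int
    n_total: int
    probability: float  # %, mean of per-experiment percentages
    sem: float  # % across experiments (0 for a single experiment)
    per_experiment: pd.DataFrame
    single_molecule_regime: bool  # probability < 30%
    condition: str = ""

    def summary(self) -> str:
        return (
            f"{self.condition or 'condition'}: binding probability "
            f"{self.probability:.1f} +/- {self.sem:.1f}% "
            f"({self.n_with_event}/{self.n_total} curves, "
            f"{len(self.per_experiment)} experiments; "
            f"single-molecule regime: {self.single_molecule_regime})"
        )


def binding_probability(
    flags_by_experiment: Mapping[str, Sequence[bool]],
    condition: str = "",
    min_curves: int = 50,
) -> BindingProbability:
    """Fraction of curves with >= 1 specific rupture, per experiment.

    ``flags_by_experiment`` maps experiment id to one boolean per curve
    (specific event present). The condition value is the mean of the
    per-experiment percentages, with SEM across experiments; fewer than
    ``min_curves`` curves in any experiment is an error.
    """
    if not flags_by_experiment:
        raise InputError("no experiments given")
    rows = []
    for exp, flags in flags_by_experiment.items():
        flags = np.asarray(list(flags), dtype=bool)
        if flags.size == 0:
            raise InputError(f"experiment {exp!r} has no curves")
        if flags.size < min_curves:
            raise InputError(
                f"experiment {exp!r} has {flags.size} curves; "
                f"need >= {min_curves}"
            )
        rows.append(
            {"experiment": exp, "n_with_event": int(flags.sum()),
             "n_total": int(flags.size),
             "probability_pct": 100.0 * flags.mean()}
        )
    per_exp = pd.DataFrame(rows)
    probs = per_exp["probability_pct"].to_numpy()
    mean = float(probs.mean())
    sem = float(probs.std(ddof=1) / np.sqrt(probs.size)) if probs.size > 1 else 0.0
    return BindingProbability(
        n_with_event=int(per_exp["n_with_event"].sum()),
        n_total=int(per_exp["n_total"].sum()),
        probability=mean,
        sem=sem,
        per_experiment=per_exp,
        single_molecule_regime=mean < 30.0,
        condition=condition,
    )


def compare_forces(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "two-sided",
) -> MannWhitneyResult:
    """Exact Mann–Whitney comparison of forces or probability replicates."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("both samples need >= 2 observations")
    return mannwhitney_exact(a, b, alternative=alternative)
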