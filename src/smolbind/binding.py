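"""Equilibrium binding fits.

Two one-parameter-family models cover the binding assays:

* :class:`SingleSiteBindingModel` — steady-state 1:1 Langmuir isotherm
  ``R(C) = Rmax·C/(KD + C)`` fitted to plateau responses vs analyte
  concentration (μM); yields the equilibrium dissociation constant KD.
* :class:`CompetitionBindingModel` — one-site competition
  ``B(c) = 100/(1 + 10^(log10 c − logIC50))`` (unit slope, asymptotes
  fixed at 100%/0%) fitted to % specific binding vs molar competitor
  concentration; yields log10 IC50. A free-Hill-slope variant is
  available behind a flag and is also used internally to warn when the
  data show no dose dependence.

Both follow the Model → ``fit()`` → Results pattern: results carry
estimates, standard errors from the Jacobian, residual sum of squares and
a ``summary()`` table, and expose ``predict``.

:func:`compute_specific_binding` performs the radioligand normalization:
specific = total − mean(nonspecific), expressed as % of the specific
binding at zero competitor dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._errors import FitError, InputError
from .simulate import BindingSeries, langmuir_response

__all__ = [
    "SingleSiteBindingModel",
    "SingleSiteFitResults",
    "CompetitionBindingModel",
    "CompetitionFitResults",
    "SpecificBindingTable",
    "compute_specific_binding",
]

_FIT_KW = dict(maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14)


def _validate_series(conc: np.ndarray, resp: np.ndarray) -> None:
    if conc.shape != resp.shape or conc.ndim != 1:
        raise InputError("concentrations and responses must be equal-length 1-D")
    if np.any(conc <= 0):
        raise InputError("concentrations must be strictly positive")
    if np.unique(conc).size < 4:
        raise InputError("need >= 4 distinct concentrations to fit")


# --------------------------------------------------------------------------
# steady-state single-site
# --------------------------------------------------------------------------

@dataclass
class SingleSiteFitResults:
    """Results of a 1:1 steady-state affinity fit."""

    kd: float  # μM
    rmax: float  # response units
    kd_se: float
    rmax_se: float
    rss: float
    nobs: int
    converged: bool
    saturated: bool  # KD collapsed far below the tested range
    model: "SingleSiteBindingModel" = field(repr=False)

    def predict(self, concentrations) -> np.ndarray:
        return langmuir_response(np.asarray(concentrations, float), self.rmax, self.kd)

    def summary(self) -> str:
        lines = [
            "Single-site steady-state binding fit",
            "-" * 36,
            f"n obs:       {self.nobs}",
            f"KD:          {self.kd:.4g} uM  (SE {self.kd_se:.3g})",
            f"Rmax:        {self.rmax:.4g}  (SE {self.rmax_se:.3g})",
            f"RSS:         {self.rss:.4g}",
            f"converged:   {self.converged}",
        ]
        if self.saturated:
            lines.append("warning:     responses saturated; KD poorly determined")
        return "\n".join(lines)


class SingleSiteBindingModel:
    """1:1 Langmuir isotherm fitted to steady-state responses.

    Initialization follows the shape of the isotherm: Rmax starts at the
    maximum observed response and KD at the concentration where the
    response first crosses half of it (linear interpolation).
    """

    def __init__(self, concentrations, responses) -> None:
        self.concentrations = np.asarray(concentrations, dtype=float)
        self.responses = np.asarray(responses, dtype=float)
        _validate_series(self.concentrations, self.responses)

    @classmethod
    def from_series(cls, series: BindingSeries) -> "SingleSiteBindingModel":
        return cls(series.concentrations, series.responses)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, conc: str = "concentration", resp: str = "response"
    ) -> "SingleSiteBindingModel":
        return cls(df[conc].to_numpy(), df[resp].to_numpy())

    def _initial(self) -> tuple[float, float]:
        order = np.argsort(self.concentrations)
        c, r = self.concentrations[order], self.responses[order]
        rmax0 = float(r.max())
        half = rmax0 / 2.0
        above = np.nonzero(r >= half)[0]
        if above.size and above[0] > 0:
            i = above[0]
            frac = (half - r[i - 1]) / (r[i] - r[i - 1]) if r[i] != r[i - 1] else 0.5
            kd0 = float(c[i - 1] + frac * (c[i] - c[i - 1]))
        else:
            kd0 = float(np.median(c))
        return max(rmax0, 1e-12), max(kd0, 1e-12)

    def fit(self) -> SingleSiteFitResults:
        if np.ptp(self.responses) == 0:
            raise FitError("responses are all equal; no binding signal to fit")
        rmax0, kd0 = self._initial()

        def f(C, rmax, kd):
            return langmuir_response(C, rmax, kd)

        def jac(C, rmax, kd):
            d_rmax = C / (kd + C)
            d_kd = -rmax * C / (kd + C) ** 2
            return np.column_stack([d_rmax, d_kd])

        try:
            popt, pcov = curve_fit(
                f, self.concentrations, self.responses, p0=[rmax0, kd0],
                jac=jac, bounds=([0.0, 0.0], [np.inf, np.inf]), **_FIT_KW,
            )
            converged = True
        except RuntimeError as exc:
            raise FitError(f"single-site fit did not converge: {exc}") from exc
        rmax, kd = map(float, popt)
        se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
        resid = self.responses - f(self.concentrations, rmax, kd)
        saturated = kd < self.concentrations.min() / 100.0
        if saturated:
            warnings.warn(
                "fitted KD far below the tested concentration range; "
                "responses look saturated", stacklevel=2,
            )
        return SingleSiteFitResults(
            kd=kd, rmax=rmax, kd_se=float(se[1]), rmax_se=float(se[0]),
            rss=float(resid @ resid), nobs=self.concentrations.size,
            converged=converged, saturated=saturated, model=self,
        )


# --------------------------------------------------------------------------
# one-site competition
# --------------------------------------------------------------------------

@dataclass
class CompetitionFitResults:
    """Results of a one-site competition fit (% specific binding)."""

    log_ic50: float  # log10 molar
    log_ic50_se: float
    hill_slope: float  # 1.0 when fixed
    hill_slope_se: float
    free_slope: bool
    rss: float
    nobs: int
    converged: bool
    out_of_range: bool  # logIC50 outside tested range ± 1 log unit
    no_dose_dependence: bool  # free-slope check: slope CI spans 0
    model: "CompetitionBindingModel" = field(repr=False)

    @property
    def ic50(self) -> float:
        """IC50 in molar units."""
        return 10.0**self.log_ic50

    def predict(self, concentrations) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        return 100.0 / (
            1.0 + 10.0 ** (self.hill_slope * (np.log10(c) - self.log_ic50))
        )

    def summary(self) -> str:
        lines = [
            "One-site competition binding fit",
            "-" * 32,
            f"n obs:       {self.nobs}",
            f"logIC50:     {self.log_ic50:.4g}  (SE {self.log_ic50_se:.3g})",
            f"IC50:        {self.ic50:.4g} M",
            f"Hill slope:  {self.hill_slope:.4g}"
            + ("" if not self.free_slope else f"  (SE {self.hill_slope_se:.3g})"),
            f"RSS:         {self.rss:.4g}",
            f"converged:   {self.converged}",
        ]
        if self.out_of_range:
            lines.append("warning:     logIC50 outside tested range +/- 1 log unit")
        if self.no_dose_dependence:
            lines.append("warning:     no detectable dose dependence (slope CI spans 0)")
        return "\n".join(lines)


class CompetitionBindingModel:
    """One-site competition curve fitted to % specific binding.

    Concentrations are molar; the fit runs on the log10 scale. Asymptotes
    are fixed at 100%/0% and the slope at 1 unless ``free_slope``.
    """

    def __init__(self, concentrations, pct_specific, free_slope: bool = False) -> None:
        self.concentrations = np.asarray(concentrations, dtype=float)
        self.pct_specific = np.asarray(pct_specific, dtype=float)
        self.free_slope = bool(free_slope)
        _validate_series(self.concentrations, self.pct_specific)

    @classmethod
    def from_series(cls, series: BindingSeries, **kw) -> "CompetitionBindingModel":
        return cls(series.concentrations, series.responses, **kw)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, conc: str = "concentration",
        resp: str = "pct_specific", **kw,
    ) -> "CompetitionBindingModel":
        return cls(df[conc].to_numpy(), df[resp].to_numpy(), **kw)

    def _fit_params(self, free_slope: bool) -> tuple[np.ndarray, np.ndarray]:
        logc = np.log10(self.concentrations)
        log_ic50_0 = float(logc[np.argmin(np.abs(self.pct_specific - 50.0))])

        if free_slope:
            def f(lc, log_ic50, slope):
                return 100.0 / (1.0 + 10.0 ** (slope * (lc - log_ic50)))
            p0 = [log_ic50_0, 1.0]
        else:
            def f(lc, log_ic50):
                return 100.0 / (1.0 + 10.0 ** (lc - log_ic50))
            p0 = [log_ic50_0]
        try:
            popt, pcov = curve_fit(f, logc, self.pct_specific, p0=p0, **_FIT_KW)
        except RuntimeError as exc:
            raise FitError(f"competition fit did not converge: {exc}") from exc
        return popt, np.sqrt(np.maximum(np.diag(pcov), 0.0))

    def fit(self) -> CompetitionFitResults:
        popt, se = self._fit_params(self.free_slope)
        if self.free_slope:
            log_ic50, slope = map(float, popt)
            log_ic50_se, slope_se = map(float, se)
        else:
            log_ic50, log_ic50_se = float(popt[0]), float(se[0])
            slope, slope_se = 1.0, 0.0
        # dose-dependence check always runs on the free-slope variant
        try:
            popt_f, se_f = self._fit_params(True)
            no_dose = abs(popt_f[1]) < 1.96 * se_f[1]
        except FitError:
            no_dose = True
        logc = np.log10(self.concentrations)
        out_of_range = not (logc.min() - 1.0 <= log_ic50 <= logc.max() + 1.0)
        if out_of_range:
            warnings.warn(
                "fitted logIC50 lies outside the tested concentration range "
                "+/- 1 log unit", stacklevel=2,
            )
        pred = 100.0 / (1.0 + 10.0 ** (slope * (logc - log_ic50)))
        resid = self.pct_specific - pred
        return CompetitionFitResults(
            log_ic50=log_ic50, log_ic50_se=log_ic50_se, hill_slope=slope,
            hill_slope_se=slope_se, free_slope=self.free_slope,
            rss=float(resid @ resid), nobs=logc.size, converged=True,
            out_of_range=out_of_range, no_dose_dependence=bool(no_dose), model=self,
        )


# --------------------------------------------------------------------------
# radioligand specific-binding normalization
# --------------------------------------------------------------------------

@dataclass
class SpecificBindingTable:
    """Per-well specific binding, normalized to the zero-dose reference."""

    table: pd.DataFrame  # columns: dose, counts, specific, pct_specific
    nonspecific_mean: float
    reference_specific: float  # mean specific counts at dose == 0
    n_floored: int  # wells whose specific counts were floored at 0

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def compute_specific_binding(
    df: pd.DataFrame,
    dose: str = "dose",
    counts: str = "counts",
    kind: str = "kind",
    total_label: str = "total",
    nonspecific_label: str = "nonspecific",
) -> SpecificBindingTable:
    """Specific = total − mean(nonspecific), as % of zero-dose specific binding.

    ``df`` holds one row per well with a dose column, raw counts, and a
    kind column distinguishing total-binding wells from nonspecific wells
    (measured with excess unlabeled ligand). Negative specific counts are
    floored at zero with a warning.
    """
    for col in (dose, counts, kind):
        if col not in df.columns:
            raise InputError(f"missing column {col!r}")
    ns = df.loc[df[kind] == nonspecific_label, counts]
    if ns.empty:
        raise InputError("no nonspecific wells in input")
    totals = df.loc[df[kind] == total_label, [dose, counts]].copy()
    if totals.empty:
        raise InputError("no total-binding wells in input")
    if not np.any(np.isclose(totals[dose].to_numpy(dtype=float), 0.0)):
        raise InputError("no zero-dose reference wells in input")

    ns_mean = float(ns.mean())
    specific = totals[counts].to_numpy(dtype=float) - ns_mean
    n_floored = int(np.sum(specific < 0))
    if n_floored:
        warnings.warn(
            f"{n_floored} wells had specific counts below zero; floored at 0",
            stacklevel=2,
        )
    specific = np.maximum(specific, 0.0)
    zero_mask = np.isclose(totals[dose].to_numpy(dtype=float), 0.0)
    reference = float(specific[zero_mask].mean())
    if reference <= 0:
        if np.all(specific == 0):
            # total equals nonspecific everywhere: no specific binding at all
            warnings.warn("no specific binding anywhere; all percentages are 0",
                          stacklevel=2)
            pct = np.zeros_like(specific)
        else:
            raise InputError("zero-dose specific binding is not positive")
    else:
        pct = 100.0 * specific / reference
    out = pd.DataFrame(
        {
            dose: totals[dose].to_numpy(),
            counts: totals[counts].to_numpy(),
            "specific": specific,
            "pct_specific": pct,
        }
    )
    return SpecificBindingTable(out, ns_mean, reference, n_floored)
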