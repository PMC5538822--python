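"""Equilibrium nucleic-acid binding quantification (EMSA / filter binding).

Band or filter intensities are reduced to fraction bound, titrations over a
protein dilution series are fit to the Hill isotherm

    f([P]) = Bmax * [P]**n / (Kd**n + [P]**n),

and mutants are classified by their Kd fold change relative to wild type.
The probe is assumed to be present far below Kd, so free protein is taken
equal to total protein (no depletion correction). Fitting is done in
log-Kd space for numerical stability across nM-to-uM ranges.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections.abc import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TitrationSeries",
    "BindingFitResult",
    "MutantCall",
    "CompetitionSeries",
    "hill_model",
    "fraction_bound",
    "dilution_series",
    "fit_binding",
    "classify_mutant",
    "competition_percent_bound",
]


@dataclasses.dataclass(frozen=True)
class TitrationSeries:
    """Protein concentrations and the corresponding fraction bound."""

    conc: np.ndarray
    fraction: np.ndarray
    unit: str = "uM"
    probe: str | None = None
    probe_conc: float | None = None
    replicate: int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc, dtype=float)
        frac = np.asarray(self.fraction, dtype=float)
        if conc.shape != frac.shape or conc.ndim != 1:
            raise ValueError("conc and fraction must be 1-D arrays of equal length")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(frac < 0):
            raise ValueError("fraction bound cannot be negative")
        if np.any(frac > 1):
            warnings.warn("fraction bound above 1 clipped to 1 (band-quantification noise)",
                          stacklevel=3)
            frac = np.clip(frac, 0.0, 1.0)
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "fraction", frac)

    @classmethod
    def from_intensities(cls, conc, bound, free, **kwargs) -> "TitrationSeries":
        """Build a series from raw (bound, free) band intensities."""
        bound = np.asarray(bound, dtype=float)
        free = np.asarray(free, dtype=float)
        frac = np.array([fraction_bound(b, f) for b, f in zip(bound, free)])
        return cls(conc=conc, fraction=frac, **kwargs)


@dataclasses.dataclass(frozen=True)
class BindingFitResult:
    """Hill-model fit: Kd (input units), Hill slope n, amplitude Bmax."""

    kd: float
    hill: float
    bmax: float
    kd_se: float           # from the fit covariance (delta method on log Kd)
    rss: float
    unit: str
    converged: bool


@dataclasses.dataclass(frozen=True)
class MutantCall:
    """Affinity classification of a mutant relative to wild type."""

    label: str
    kd_ratio: float        # Kd(mutant) / Kd(WT); >1 means weaker binding
    category: str          # decreased_binding | increased_binding | unchanged


@dataclasses.dataclass(frozen=True)
class CompetitionSeries:
    """Unlabeled-competitor concentrations and percent labeled probe bound."""

    competitor_conc: np.ndarray
    percent_bound: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.competitor_conc, dtype=float)
        pct = np.asarray(self.percent_bound, dtype=float)
        if conc.shape != pct.shape or conc.ndim != 1:
            raise ValueError("competitor_conc and percent_bound must match in length")
        if np.any((pct < 0) | (pct > 100)):
            raise ValueError("percent bound must be within [0, 100]")
        object.__setattr__(self, "competitor_conc", conc)
        object.__setattr__(self, "percent_bound", pct)


def hill_model(conc: np.ndarray, kd: float, n: float, bmax: float = 1.0) -> np.ndarray:
    """Hill binding isotherm ``Bmax * c**n / (Kd**n + c**n)``."""
    conc = np.asarray(conc, dtype=float)
    cn = conc ** n
    return bmax * cn / (kd ** n + cn)


def fraction_bound(bound_intensity: float, free_intensity: float) -> float:
    """Fraction bound from band intensities: bound / (bound + free)."""
    if bound_intensity < 0 or free_intensity < 0:
        raise ValueError("band intensities must be non-negative")
    total = bound_intensity + free_intensity
    if total == 0:
        raise ValueError("bound and free intensities cannot both be zero")
    return bound_intensity / total


def dilution_series(start: float, factor: float, count: int) -> np.ndarray:
    """Geometric dilution series ``start, start/factor, ...`` of length count."""
    if start <= 0:
        raise ValueError("start concentration must be > 0")
    if factor <= 1:
        raise ValueError("dilution factor must be > 1")
    if count < 1:
        raise ValueError("count must be >= 1")
    return start / factor ** np.arange(count, dtype=float)


def fit_binding(
    series: TitrationSeries,
    hill_free: bool = True,
    bmax_free: bool = False,
) -> BindingFitResult:
    """Nonlinear least-squares fit of the Hill isotherm.

    By default the Hill slope n is fitted and Bmax is fixed at 1; either can
    be toggled. Kd is parameterized as log Kd internally so it stays
    positive; its standard error is propagated back to the concentration
    scale. The result is flagged non-converged when the optimizer fails or
    the fitted Kd falls outside [min(conc)/100, max(conc)*100] — a Kd that
    far outside the sampled range is not constrained by the data.
    """
    conc = series.conc
    frac = series.fraction
    if np.unique(conc).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if series.probe_conc is not None and conc.min() < 10 * series.probe_conc:
        warnings.warn(
            "lowest protein concentration is within 10x of the probe concentration; "
            "probe depletion may bias the fit", stacklevel=2,
        )

    log_kd0 = math.log(np.median(conc))

    # only the free parameters enter the optimizer; fixed ones are closed over
    def model(c, log_kd, *rest):
        rest = list(rest)
        n = rest.pop(0) if hill_free else 1.0
        bmax = rest.pop(0) if bmax_free else 1.0
        return hill_model(c, math.exp(log_kd), n, bmax)

    p0 = [log_kd0]
    lo = [math.log(conc.min()) - math.log(100)]
    hi = [math.log(conc.max()) + math.log(100)]
    if hill_free:
        p0.append(1.0), lo.append(0.1), hi.append(10.0)
    if bmax_free:
        p0.append(1.0), lo.append(0.0), hi.append(1.5)

    try:
        popt, pcov = curve_fit(model, conc, frac, p0=p0, bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError):
        return BindingFitResult(kd=math.nan, hill=math.nan, bmax=math.nan,
                                kd_se=math.nan, rss=math.nan,
                                unit=series.unit, converged=False)
    params = list(float(v) for v in popt)
    log_kd = params.pop(0)
    n = params.pop(0) if hill_free else 1.0
    bmax = params.pop(0) if bmax_free else 1.0
    kd = math.exp(log_kd)
    se_log = math.sqrt(pcov[0, 0]) if np.isfinite(pcov[0, 0]) else math.nan
    kd_se = kd * se_log if math.isfinite(se_log) else math.nan
    resid = frac - model(conc, *popt)
    rss = float(resid @ resid)
    in_range = conc.min() / 100 <= kd <= conc.max() * 100
    return BindingFitResult(kd=kd, hill=n, bmax=bmax, kd_se=kd_se, rss=rss,
                            unit=series.unit, converged=bool(in_range))


def classify_mutant(
    kd_mutant: float,
    kd_wt: float,
    label: str = "",
    threshold: float = 10.0,
) -> MutantCall:
    """Classify a mutant by its Kd fold change relative to WT.

    A ratio above ``threshold`` (default 10-fold) means decreased binding
    affinity; below ``1/threshold``, increased; otherwise unchanged.
    """
    if kd_mutant <= 0 or kd_wt <= 0:
        raise ValueError("Kd values must be positive")
    ratio = kd_mutant / kd_wt
    if ratio > threshold:
        category = "decreased_binding"
    elif ratio < 1.0 / threshold:
        category = "increased_binding"
    else:
        category = "unchanged"
    return MutantCall(label=label, kd_ratio=ratio, category=category)


def competition_percent_bound(series: CompetitionSeries) -> dict:
    """Tabulate percent probe bound vs competitor and flag competition.

    Competition behavior means the percent bound does not increase with
    competitor concentration and shows a net decrease from the lowest to
    the highest competitor concentration.
    """
    if series.competitor_conc.size < 2:
        raise ValueError("need at least 2 competitor concentrations")
    order = np.argsort(series.competitor_conc)
    conc = series.competitor_conc[order]
    pct = series.percent_bound[order]
    diffs = np.diff(pct)
    competition = bool(np.all(diffs <= 0) and pct[-1] < pct[0])
    return {
        "competitor_conc": conc,
        "percent_bound": pct,
        "competition": competition,
    }
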