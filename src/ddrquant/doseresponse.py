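"""Concentration-response statistics: fold change, loess fitting, the
point-of-departure (PoD) statistic and absolute IC50.

The PoD of a reporter is the lowest concentration at which the loess-smoothed
concentration-response curve (local linear regression with tricube weights,
span 0.5, fitted against log10 concentration) leaves the solvent-control band
``control_mean ± 2·control_SD`` — in either direction.  The absolute IC50 of a
viability curve (expressed as % of solvent control) is the concentration where
a four-parameter log-logistic fit with the top plateau fixed at 100 % crosses
the 50 % line.  Both statistics are reported as *undefined* rather than
extrapolated when the curve never crosses inside the tested range.

The two estimators follow the statsmodels idiom: build a model object from a
:class:`ResponseCurve` (or a tidy measurement table), call ``fit()``, and read
estimates and diagnostics off the returned results object, whose ``summary()``
prints a compact table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import DegenerateControlError, FitError, InsufficientDataError

__all__ = [
    "ResponseCurve",
    "LoessConfig",
    "PoDResult",
    "IC50Result",
    "fold_change",
    "min_max_normalize",
    "fit_loess",
    "compute_pod",
    "compute_ic50",
    "PointOfDepartureModel",
    "PointOfDepartureResults",
    "AbsoluteIC50Model",
    "AbsoluteIC50Results",
]


@dataclass
class ResponseCurve:
    """Replicate responses over a concentration series plus solvent controls.

    ``responses[i]`` holds the replicate values measured at
    ``concentrations[i]``; ``control_values`` are the solvent-control wells
    (concentration 0, excluded from any fit, used for the ±2·SD band).
    """

    concentrations: np.ndarray
    responses: Sequence[np.ndarray]
    control_values: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.ndim != 1 or len(self.concentrations) < 1:
            raise ValueError("concentrations must be a nonempty 1D array")
        if np.any(self.concentrations <= 0) or np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        self.responses = [np.atleast_1d(np.asarray(r, dtype=float)) for r in self.responses]
        if len(self.responses) != len(self.concentrations):
            raise ValueError("one replicate vector per concentration is required")
        if any(len(r) < 1 for r in self.responses):
            raise ValueError("every concentration needs at least one replicate")
        self.control_values = np.atleast_1d(np.asarray(self.control_values, dtype=float))
        if len(self.control_values) < 1:
            raise ValueError("the solvent-control set must be nonempty")

    @property
    def control_mean(self) -> float:
        return float(np.mean(self.control_values))

    @property
    def control_sd(self) -> float:
        """Sample SD of the solvent-control wells (0 for a single control)."""
        if len(self.control_values) < 2:
            return 0.0
        return float(np.std(self.control_values, ddof=1))

    def flat_xy(self) -> Tuple[np.ndarray, np.ndarray]:
        """All (log10 concentration, response) observations, replicates expanded."""
        x = np.concatenate(
            [np.full(len(r), np.log10(c)) for c, r in zip(self.concentrations, self.responses)]
        )
        y = np.concatenate(self.responses)
        return x, y

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        value_col: str = "value",
        concentration_col: str = "concentration_uM",
        well_type_col: str = "well_type",
    ) -> "ResponseCurve":
        """Build a curve from a tidy table with treated and solvent rows."""
        treated = df[df[well_type_col] == "treated"]
        controls = df[df[well_type_col] == "solvent"][value_col].to_numpy()
        concs = np.sort(treated[concentration_col].unique())
        reps = [
            treated.loc[treated[concentration_col] == c, value_col].to_numpy() for c in concs
        ]
        return cls(concs, reps, controls)


@dataclass
class LoessConfig:
    """Loess settings: ``span`` is the fraction of points in each local fit
    (0.5, read from the protocol's "2/4"); degree is fixed at 1 (local
    linear); ``grid_points`` log-spaced evaluation points are used for the
    band-crossing search."""

    span: float = 0.5
    degree: int = 1
    grid_points: int = 512

    def __post_init__(self) -> None:
        if not (0 < self.span <= 1):
            raise ValueError("span must be in (0, 1]")
        if self.degree != 1:
            raise ValueError("only degree-1 (local linear) loess is supported")
        if self.grid_points < 8:
            raise ValueError("grid_points must be >= 8")


@dataclass
class PoDResult:
    """Point of departure: concentration (µM) of the first band exit, its
    direction, the band edges, and whether the PoD was censored at the lowest
    tested concentration (curve already outside the band there)."""

    pod: Optional[float]
    direction: str  # "positive" | "negative" | "none"
    threshold_upper: float
    threshold_lower: float
    censored: bool = False

    @property
    def defined(self) -> bool:
        return self.pod is not None


@dataclass
class IC50Result:
    """Absolute IC50 (µM), undefined (None) when the fitted viability curve
    never crosses 50 % of control inside the tested range."""

    ic50: Optional[float]
    params: Optional[dict] = None

    @property
    def defined(self) -> bool:
        return self.ic50 is not None


# ---------------------------------------------------------------------------
# normalisations


def fold_change(curve: ResponseCurve) -> ResponseCurve:
    """Divide responses and controls by the solvent-control mean.

    After the transform the control mean is exactly 1.  Scale-invariant:
    multiplying all inputs by a constant leaves the output unchanged.
    """
    m = curve.control_mean
    if m <= 0:
        raise DegenerateControlError(f"control mean must be positive, got {m}")
    return ResponseCurve(
        curve.concentrations.copy(),
        [r / m for r in curve.responses],
        curve.control_values / m,
    )


def min_max_normalize(values: np.ndarray) -> Tuple[np.ndarray, bool]:
    """Rescale one model's value collection linearly onto [0, 1].

    Returns ``(normalized, degenerate)``; a constant collection maps to all
    zeros with ``degenerate=True`` instead of raising.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot normalise an empty collection")
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        return np.zeros_like(values), True
    return (values - lo) / (hi - lo), False


# ---------------------------------------------------------------------------
# loess


def fit_loess(curve: ResponseCurve, config: Optional[LoessConfig] = None) -> Callable[[np.ndarray], np.ndarray]:
    """Fit loess (tricube-weighted local linear regression) of the replicate
    responses against log10 concentration.

    Returns an evaluator over log10 concentration, valid on the tested range.
    Solvent controls are not part of the fit (their concentration is 0).
    """
    config = config or LoessConfig()
    if len(np.unique(curve.concentrations)) < 4:
        raise InsufficientDataError("loess needs at least 4 distinct concentrations")
    x, y = curve.flat_xy()

    def evaluate(xq: np.ndarray) -> np.ndarray:
        xq = np.atleast_1d(np.asarray(xq, dtype=float))
        fitted = lowess(y, x, frac=config.span, it=0, xvals=xq)
        return fitted

    return evaluate


# ---------------------------------------------------------------------------
# point of departure


class PointOfDepartureModel:
    """PoD estimator for one condition's concentration-response curve.

    Parameters
    ----------
    curve : ResponseCurve
        Replicate responses (any scale — the statistic is invariant to affine
        rescaling applied jointly to responses and controls).
    config : LoessConfig, optional
    use_fold_change : bool
        Divide by the control mean before fitting (default True; the band is
        then 1 ± 2·SD of control fold changes).
    band_from_fit_residuals : bool
        Alternative band width: residual SD of the loess fit instead of the
        solvent-control SD (default False).
    """

    def __init__(
        self,
        curve: ResponseCurve,
        config: Optional[LoessConfig] = None,
        use_fold_change: bool = True,
        band_from_fit_residuals: bool = False,
    ) -> None:
        self.config = config or LoessConfig()
        self.curve = fold_change(curve) if use_fold_change else curve
        self.band_from_fit_residuals = band_from_fit_residuals

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "PointOfDepartureModel":
        return cls(ResponseCurve.from_dataframe(df), **kwargs)

    def fit(self) -> "PointOfDepartureResults":
        curve, config = self.curve, self.config
        evaluator = fit_loess(curve, config)
        c = curve.concentrations
        grid = np.logspace(np.log10(c[0]), np.log10(c[-1]), config.grid_points)
        log_grid = np.log10(grid)
        fitted = evaluator(log_grid)

        mean = curve.control_mean
        if self.band_from_fit_residuals:
            x, y = curve.flat_xy()
            sd = float(np.std(y - evaluator(x), ddof=1)) if len(y) > 1 else 0.0
        else:
            sd = curve.control_sd
        upper, lower = mean + 2.0 * sd, mean - 2.0 * sd

        pod, direction, censored = self._first_crossing(log_grid, fitted, upper, lower)
        result = PoDResult(pod, direction, upper, lower, censored)
        return PointOfDepartureResults(self, result, grid, fitted, evaluator)

    @staticmethod
    def _first_crossing(
        log_grid: np.ndarray, fitted: np.ndarray, upper: float, lower: float
    ) -> Tuple[Optional[float], str, bool]:
        above = fitted > upper
        below = fitted < lower
        if above[0]:
            return float(10 ** log_grid[0]), "positive", True
        if below[0]:
            return float(10 ** log_grid[0]), "negative", True
        first_above = int(np.argmax(above)) if above.any() else None
        first_below = int(np.argmax(below)) if below.any() else None
        candidates = []
        if first_above is not None:
            candidates.append((first_above, "positive", upper))
        if first_below is not None:
            candidates.append((first_below, "negative", lower))
        if not candidates:
            return None, "none", False
        i, direction, thr = min(candidates)
        # linear-in-log10 interpolation between the bracketing grid points
        x0, x1 = log_grid[i - 1], log_grid[i]
        y0, y1 = fitted[i - 1], fitted[i]
        t = (thr - y0) / (y1 - y0) if y1 != y0 else 0.0
        return float(10 ** (x0 + t * (x1 - x0))), direction, False


@dataclass
class PointOfDepartureResults:
    """Fitted PoD results: the statistic, the loess curve on the search grid,
    and the evaluator for plotting or further queries."""

    model: PointOfDepartureModel
    result: PoDResult
    grid: np.ndarray
    fitted: np.ndarray
    evaluator: Callable[[np.ndarray], np.ndarray]

    @property
    def pod(self) -> Optional[float]:
        return self.result.pod

    @property
    def direction(self) -> str:
        return self.result.direction

    @property
    def censored(self) -> bool:
        return self.result.censored

    def summary(self) -> str:
        r = self.result
        lines = [
            "Point of departure (loess vs solvent band)",
            "-" * 44,
            f"tested range (uM) : {self.grid[0]:.4g} - {self.grid[-1]:.4g}",
            f"control band      : [{r.threshold_lower:.4g}, {r.threshold_upper:.4g}]",
            f"PoD (uM)          : {r.pod:.4g}" if r.defined else "PoD (uM)          : undefined",
            f"direction         : {r.direction}",
            f"censored at lowest: {r.censored}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Responses, loess fit and control band on a log concentration axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.model.curve
        for c, reps in zip(curve.concentrations, curve.responses):
            ax.plot([c] * len(reps), reps, "o", color="0.6", ms=4)
        ax.plot(self.grid, self.fitted, "-", color="C0", label="loess fit")
        r = self.result
        ax.axhspan(r.threshold_lower, r.threshold_upper, color="C2", alpha=0.15, label="control ±2 SD")
        if r.defined:
            ax.axvline(r.pod, color="C3", ls="--", label=f"PoD = {r.pod:.3g} µM")
        ax.set_xscale("log")
        ax.set_xlabel("concentration (µM)")
        ax.set_ylabel("response")
        ax.legend(fontsize=8)
        return ax


def compute_pod(
    curve: ResponseCurve, config: Optional[LoessConfig] = None, **kwargs
) -> PoDResult:
    """Functional wrapper: fit :class:`PointOfDepartureModel` and return its
    :class:`PoDResult`."""
    return PointOfDepartureModel(curve, config, **kwargs).fit().result


# ---------------------------------------------------------------------------
# absolute IC50


def _log_logistic(c: np.ndarray, bottom: float, ec50: float, slope: float, top: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + (c / ec50) ** slope)


class AbsoluteIC50Model:
    """Absolute IC50 from a viability curve expressed as % of solvent control.

    A four-parameter log-logistic curve with the top plateau fixed at ``top``
    (default 100 %) is fitted by least squares; the IC50 is where the fit
    crosses 50 % of control — the *absolute* definition, not the fitted
    curve's own midpoint.
    """

    def __init__(self, curve: ResponseCurve, top: float = 100.0) -> None:
        self.curve = curve
        self.top = float(top)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "AbsoluteIC50Model":
        return cls(ResponseCurve.from_dataframe(df), **kwargs)

    def fit(self) -> "AbsoluteIC50Results":
        curve = self.curve
        x = curve.concentrations
        y = np.array([np.mean(r) for r in curve.responses])
        top = self.top
        half = top / 2.0
        # flat data, or data never reaching 50 %, cannot define an absolute IC50
        if np.min(y) > half or float(np.ptp(y)) < 1e-9:
            return AbsoluteIC50Results(self, IC50Result(None), None)
        p0 = [max(np.min(y), 0.0), float(np.sqrt(x[0] * x[-1])), 1.0]
        bounds = ([0.0, x[0] / 100.0, 0.05], [top, x[-1] * 100.0, 20.0])
        xfit, yfit = curve.flat_xy()
        cfit = 10.0 ** xfit
        try:
            popt, _ = curve_fit(
                lambda c, b, e, s: _log_logistic(c, b, e, s, top),
                cfit, yfit, p0=p0, bounds=bounds, maxfev=20000,
            )
        except RuntimeError as exc:  # pragma: no cover - rare optimiser failure
            raise FitError(f"log-logistic fit did not converge: {exc}") from exc
        bottom, ec50, slope = (float(v) for v in popt)
        params = {"bottom": bottom, "ec50": ec50, "slope": slope, "top": top}
        ic50: Optional[float] = None
        if bottom < half < top:
            cand = ec50 * ((top - half) / (half - bottom)) ** (1.0 / slope)
            if x[0] <= cand <= x[-1]:
                ic50 = float(cand)
        return AbsoluteIC50Results(self, IC50Result(ic50, params), params)


@dataclass
class AbsoluteIC50Results:
    model: AbsoluteIC50Model
    result: IC50Result
    params: Optional[dict]

    @property
    def ic50(self) -> Optional[float]:
        return self.result.ic50

    def summary(self) -> str:
        lines = ["Absolute IC50 (log-logistic, top fixed)", "-" * 40]
        if self.params:
            lines.append(
                "fit: bottom={bottom:.4g}  ec50={ec50:.4g}  slope={slope:.4g}  top={top:.4g}".format(
                    **self.params
                )
            )
        lines.append(
            f"IC50 (uM): {self.result.ic50:.4g}" if self.result.defined else "IC50 (uM): undefined"
        )
        return "\n".join(lines)


def compute_ic50(curve: ResponseCurve, top: float = 100.0) -> IC50Result:
    """Functional wrapper around :class:`AbsoluteIC50Model`."""
    return AbsoluteIC50Model(curve, top=top).fit().result
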