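"""Polynomial regression of segmentation error against complexity measures.

A dataset's mean overlap error E after downsampling is modelled as a
polynomial in one complexity measure, fitted by ordinary least squares on
the monomial basis.  Each fit is scored with six goodness metrics:

* R^2 = 1 - RSS/TSS and adjusted R^2 = 1 - (1-R^2)(n-1)/(n-k-1),
* RMSE = sqrt(RSS/n) and MAE,
* AIC = n ln(RSS/n) + 2k and AICc = AIC + (2k^2+2k)/(n-k-1),

where k is the polynomial degree (the number of independent variables, the
"degrees of freedom" of the model) and n the number of data points.  AICc
is the decision rule when sweeping degrees, being the small-sample
corrected criterion.  Natural log is used in AIC; note this is the
residual-variance form, which differs from a log-likelihood AIC by an
additive constant only, so model ranking is unaffected.

The module follows the model/results idiom: :func:`fit_polynomial` returns
a :class:`RegressionFit` results object with a ``summary()`` table.
A packaged reference table ships the published ten-dataset complexity and
degradation values (:func:`load_reference_table`) so rankings can be
reproduced without downloading any imaging data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "RegressionFit",
    "fit_polynomial",
    "aic",
    "aicc",
    "dof_sweep",
    "rank_measures",
    "load_reference_table",
    "MEASURES",
]

#: Measure columns of a measure/error table, in canonical order.
MEASURES = ("de", "mnf", "mdf", "pc")


@dataclass(frozen=True)
class RegressionFit:
    """One polynomial model's coefficients and goodness-of-fit metrics.

    ``coefficients`` are in ascending-power order (c0 + c1 x + ... + ck x^k).
    ``aic``/``aicc`` are ``nan`` when undefined (RSS = 0, or n <= k+1 for
    AICc).
    """

    dof: int
    coefficients: np.ndarray
    n: int
    r2: float
    ar2: float
    rmse: float
    mae: float
    aic: float
    aicc: float
    rss: float
    tss: float

    def predict(self, x: Sequence[float]) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, float), self.coefficients)

    def summary(self) -> str:
        lines = [
            f"Polynomial OLS fit (degree {self.dof}, n = {self.n})",
            "coefficients (ascending power): "
            + ", ".join(f"{c:.6g}" for c in self.coefficients),
            f"R2   = {self.r2:.6f}    adj. R2 = {self.ar2:.6f}",
            f"RMSE = {self.rmse:.6g}    MAE = {self.mae:.6g}",
            f"AIC  = {self.aic:.6g}    AICc = {self.aicc:.6g}",
        ]
        return "\n".join(lines)


def aic(rss: float, n: int, k: int) -> float:
    """Akaike information criterion, residual-variance form (natural log).

    Returns ``nan`` (with a warning) for RSS = 0, where the criterion
    diverges to -infinity.
    """
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    if rss < 0:
        raise ValidationError(f"RSS must be non-negative, got {rss}")
    if rss == 0.0:
        warnings.warn("AIC undefined for a perfect fit (RSS = 0)", stacklevel=2)
        return math.nan
    return n * math.log(rss / n) + 2 * k


def aicc(aic_value: float, n: int, k: int) -> float:
    """Small-sample corrected AIC; ``nan`` when n <= k+1."""
    if n <= k + 1:
        return math.nan
    return aic_value + (2 * k * k + 2 * k) / (n - k - 1)


def fit_polynomial(x: Sequence[float], y: Sequence[float], dof: int) -> RegressionFit:
    """OLS fit of y on the monomial basis of x up to degree *dof*.

    Requires at least dof+1 points; x must not be constant for dof >= 1.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValidationError(f"x and y lengths differ: {x.size} vs {y.size}")
    n, k = x.size, int(dof)
    if k < 0:
        raise ValidationError(f"degree must be >= 0, got {dof}")
    if n < k + 1:
        raise ValidationError(f"need at least {k + 1} points for degree {k}, got {n}")
    if k >= 1 and np.ptp(x) == 0:
        raise ValidationError("x is constant; polynomial fit underdetermined")
    design = np.vander(x, k + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    ar2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n > k + 1 else math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = aic(rss, n, k)
    return RegressionFit(
        dof=k,
        coefficients=coef,
        n=n,
        r2=r2,
        ar2=ar2,
        rmse=math.sqrt(rss / n),
        mae=float(np.abs(resid).mean()),
        aic=a,
        aicc=aicc(a, n, k),
        rss=rss,
        tss=tss,
    )


# --------------------------------------------------------------------------
# measure/error tables

_TABLE_COLUMNS = {"dataset", "factor", "error", *MEASURES}


def load_reference_table() -> pd.DataFrame:
    """Published ten-dataset degradation table packaged with the library.

    One row per dataset x downsampling factor, with the four complexity
    measures of the original images (de, mnf, mdf, pc) and the seven mean
    reconstruction metrics at that factor.
    """
    with resources.files("segcomplexity.data").joinpath(
        "reference_degradation_table.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = _TABLE_COLUMNS - set(table.columns)
    if missing:
        raise ValidationError(f"measure/error table missing columns: {sorted(missing)}")
    if table.empty:
        raise ValidationError("measure/error table is empty")
    return table


def _xy(table: pd.DataFrame, measure: str, factor: int, response: str):
    table = _check_table(table)
    measure = measure.lower()
    if measure not in MEASURES:
        raise ValidationError(f"unknown measure {measure!r}; choose from {MEASURES}")
    sub = table[table["factor"] == factor]
    if sub.empty:
        raise ValidationError(f"no rows for downsampling factor {factor}")
    return sub[measure].to_numpy(), sub[response].to_numpy()


@dataclass(frozen=True)
class DofSweep:
    """Fits across polynomial degrees, with the AICc-selected degree."""

    measure: str
    factor: int
    fits: tuple[RegressionFit, ...]
    selected_dof: int = field(init=False)

    def __post_init__(self) -> None:
        finite = [f for f in self.fits if not math.isnan(f.aicc)]
        pool = finite or list(self.fits)
        object.__setattr__(
            self, "selected_dof", min(pool, key=lambda f: f.aicc).dof
            if finite else pool[0].dof
        )

    def best(self) -> RegressionFit:
        return next(f for f in self.fits if f.dof == self.selected_dof)


def dof_sweep(
    table: pd.DataFrame,
    measure: str,
    factor: int,
    dofs: Sequence[int] = (1, 2, 3, 4, 5),
    response: str = "error",
) -> DofSweep:
    """Fit one polynomial per degree and flag the AICc-minimizing one."""
    x, y = _xy(table, measure, factor, response)
    fits = tuple(fit_polynomial(x, y, d) for d in dofs)
    return DofSweep(measure=measure, factor=factor, fits=fits)


def rank_measures(
    table: pd.DataFrame,
    factor: int,
    dof: int = 1,
    response: str = "error",
) -> list[tuple[str, float]]:
    """Rank the four measures by descending R^2 of a degree-*dof* fit.

    Ties are broken alphabetically by measure name.
    """
    scored = []
    for m in MEASURES:
        x, y = _xy(table, m, factor, response)
        scored.append((m, fit_polynomial(x, y, dof).r2))
    return sorted(scored, key=lambda t: (-t[1], t[0]))
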