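"""Geostatistics for soil-nutrient mapping: empirical semivariogram,
variogram model fitting, ordinary kriging, and map classification.

The workflow is the standard one for a regional nutrient survey: compute
the empirical semivariogram of the georeferenced samples, fit a bounded
variogram model (Gaussian, spherical, exponential, circular or linear) by
pair-count-weighted least squares, interpolate to a grid with ordinary
kriging, and summarize the surface as class-area percentages.  The
nugget/sill ratio of the fitted model measures how much of the variance is
spatially unstructured: ratios near 1 indicate weak spatial autocorrelation
(management-driven variability), near 0 strong autocorrelation
(structurally driven).

Range convention: all families use the *effective* range — the lag at which
the model reaches ≈95% of its sill — matching how GIS packages report the
parameter.  For families that attain the sill exactly (spherical, circular,
linear) the effective range is the true range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "VariogramModel",
    "EmpiricalVariogram",
    "KrigingSurface",
    "empirical_semivariogram",
    "model_gamma",
    "fit_variogram",
    "nugget_sill_ratio",
    "OrdinaryKriging",
    "ordinary_kriging",
    "cross_validate",
    "classify_surface",
    "make_grid",
]

FAMILIES = ("gaussian", "spherical", "exponential", "circular", "linear")


@dataclass(frozen=True)
class VariogramModel:
    """Bounded variogram model γ(h) = nugget·1{h>0} + partial_sill·g(h/range).

    total sill = nugget + partial_sill; γ(0) = 0 by definition.
    """

    family: str
    nugget: float
    partial_sill: float
    range_: float

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be >= 0")
        if self.range_ <= 0:
            raise ValueError("range must be > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def gamma(self, h):
        return model_gamma(self, h)

    def covariance(self, h):
        """C(h) = sill − γ(h); the nugget contributes only at h = 0."""
        return self.sill - model_gamma(self, h)

    def to_dict(self) -> dict:
        return {
            "schema": "nitracolor.variogram/1",
            "family": self.family,
            "nugget": self.nugget,
            "partial_sill": self.partial_sill,
            "range": self.range_,
        }

    @classmethod
    def from_dict(cls, d) -> "VariogramModel":
        return cls(d["family"], d["nugget"], d["partial_sill"], d["range"])


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned method-of-moments semivariogram.

    ``gamma`` is NaN for empty bins (``pair_counts`` 0).
    """

    lag_centers: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray
    max_lag: float
    n_lags: int


def _structural(family: str, h: np.ndarray, a: float) -> np.ndarray:
    """Normalized structural component g(h) in [0, 1] with effective range a."""
    h = np.asarray(h, dtype=np.float64)
    if family == "gaussian":
        return 1.0 - np.exp(-3.0 * (h / a) ** 2)
    if family == "exponential":
        return 1.0 - np.exp(-3.0 * h / a)
    if family == "spherical":
        t = np.minimum(h / a, 1.0)
        return 1.5 * t - 0.5 * t**3
    if family == "circular":
        t = np.minimum(h / a, 1.0)
        return (2.0 / np.pi) * (t * np.sqrt(1.0 - t**2) + np.arcsin(t))
    if family == "linear":
        return np.minimum(h / a, 1.0)
    raise ValueError(f"unknown family {family!r}")


def model_gamma(model: VariogramModel, h) -> np.ndarray | float:
    """Evaluate γ(h).  γ(0) = 0 exactly; the nugget enters for h > 0."""
    h_arr = np.asarray(h, dtype=np.float64)
    if np.any(h_arr < 0):
        raise ValueError("lag distance must be >= 0")
    g = model.nugget * (h_arr > 0) + model.partial_sill * _structural(
        model.family, h_arr, model.range_
    )
    return float(g) if np.isscalar(h) else g


def empirical_semivariogram(
    coords: np.ndarray,
    values: np.ndarray,
    n_lags: int = 12,
    max_lag: float | None = None,
) -> EmpiricalVariogram:
    """Method-of-moments semivariogram on equal-width lag bins.

    γ(h) = (1/2N(h)) Σ (zᵢ − zⱼ)² over pairs whose separation falls in the
    bin.  ``max_lag`` defaults to half the maximum pairwise distance.
    """
    coords = np.asarray(coords, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64).ravel()
    if coords.shape[0] < 5:
        raise ValueError("need >= 5 samples")
    d = pdist(coords)
    if max_lag is None:
        max_lag = float(d.max()) / 2.0
    if max_lag <= 0:
        raise ValueError("max_lag must be > 0")
    dz2 = pdist(values[:, None], metric="sqeuclidean")
    within = d <= max_lag
    if not within.any():
        raise ValueError("all pairs beyond max_lag: empty variogram")
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    idx = np.clip(np.searchsorted(edges, d[within], side="right") - 1, 0, n_lags - 1)
    counts = np.bincount(idx, minlength=n_lags)
    sums = np.bincount(idx, weights=dz2[within], minlength=n_lags)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(centers, gamma, counts, float(max_lag), n_lags)


def fit_variogram(emp: EmpiricalVariogram, family: str = "gaussian") -> VariogramModel:
    """Fit (nugget, partial sill, range) by pair-count-weighted least
    squares with non-negativity bounds.

    Minimizes Σ N(h)·(γ_emp(h) − γ_model(h))².  A multi-start over a coarse
    grid of candidate ranges guards against local minima; the result is
    deterministic given the input.
    """
    ok = emp.pair_counts > 0
    if ok.sum() < 4:
        raise ValueError("need >= 4 non-empty lags to fit")
    h = emp.lag_centers[ok]
    g = emp.gamma[ok]
    w = np.sqrt(emp.pair_counts[ok].astype(np.float64))
    gmax = float(g.max())
    if gmax == 0.0:
        return VariogramModel(family, 0.0, 0.0, float(h.max()))

    def resid(theta):
        nug, psill, rng = theta
        m = nug * (h > 0) + psill * _structural(family, h, rng)
        return w * (g - m)

    hmax = float(h.max())
    best = None
    for r0 in (hmax * f for f in (0.1, 0.25, 0.5, 0.75, 1.0, 1.5)):
        for frac in (0.1, 0.5, 0.9):
            x0 = np.array([gmax * (1 - frac), gmax * frac, r0])
            try:
                sol = least_squares(
                    resid,
                    x0,
                    bounds=([0.0, 0.0, 1e-12], [np.inf, np.inf, 10.0 * hmax]),
                    method="trf",
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost - 1e-12:
                best = sol
    if best is None or not best.success and best.cost > 1e6:
        raise RuntimeError(f"variogram fit failed for family {family!r}")
    nug, psill, rng = best.x
    return VariogramModel(family, float(nug), float(psill), float(rng))


def nugget_sill_ratio(model: VariogramModel) -> float:
    """nugget / (nugget + partial sill), the unstructured variance fraction."""
    total = model.nugget + model.partial_sill
    if total <= 0:
        raise ValueError("zero total sill: ratio undefined")
    return model.nugget / total


class OrdinaryKriging(BaseEstimator, RegressorMixin):
    """Ordinary kriging: best linear unbiased prediction with weights
    constrained to sum to one.

    For each target location the system

        [ Γ  1 ] [ w ]   [ γ₀ ]
        [ 1ᵀ 0 ] [ μ ] = [ 1  ]

    is solved, where Γ is the sample–sample semivariance matrix and γ₀ the
    sample–target semivariances.  The prediction is Σ wᵢ zᵢ and the kriging
    variance Σ wᵢ γ(hᵢ₀) + μ.  The neighborhood is global (all samples).

    Parameters
    ----------
    variogram : VariogramModel or None
        Fixed variogram model.  If None, one is fitted to the training data
        at ``fit`` time.
    family : str
        Variogram family to fit when ``variogram`` is None.
    n_lags, max_lag : empirical-variogram binning used for the internal fit.

    Attributes
    ----------
    variogram_ : VariogramModel — the model used for prediction.
    X_ : (n, 2) training coordinates (duplicates averaged).
    y_ : (n,) training values.
    """

    def __init__(
        self,
        variogram: VariogramModel | None = None,
        family: str = "gaussian",
        n_lags: int = 12,
        max_lag: float | None = None,
    ):
        self.variogram = variogram
        self.family = family
        self.n_lags = n_lags
        self.max_lag = max_lag

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2) planar coordinates")
        if X.shape[0] != y.size:
            raise ValueError("X and y lengths differ")
        if X.shape[0] < 2:
            raise ValueError("need >= 2 samples")
        if not np.all(np.isfinite(X)):
            raise ValueError("coordinates must be finite")
        X, y = _dedupe(X, y)
        self.X_, self.y_ = X, y
        if self.variogram is not None:
            self.variogram_ = self.variogram
        else:
            emp = empirical_semivariogram(X, y, self.n_lags, self.max_lag)
            self.variogram_ = fit_variogram(emp, self.family)
        n = X.shape[0]
        gamma_mat = squareform(
            model_gamma(self.variogram_, pdist(X))
        )  # zero diagonal: γ(0) = 0
        a = np.empty((n + 1, n + 1))
        a[:n, :n] = gamma_mat
        a[n, :] = 1.0
        a[:, n] = 1.0
        a[n, n] = 0.0
        try:
            self._lu = _LUSolver(a)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular kriging system — deduplicate sample locations"
            ) from exc
        self.n_features_in_ = 2
        return self

    def predict(self, X, return_std: bool = False, return_weights: bool = False):
        check_is_fitted(self, "variogram_")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        n = self.X_.shape[0]
        vg = self.variogram_
        # RHS uses the h→0⁺ limit: the target is a new realization, so the
        # nugget applies even at zero distance.  With nugget = 0 this makes
        # kriging an exact interpolator at data points; with nugget > 0 it
        # smooths there (prediction need not honor the observation).
        h0 = cdist(self.X_, X)
        g0 = vg.nugget + vg.partial_sill * _structural(vg.family, h0, vg.range_)
        rhs = np.vstack([g0, np.ones((1, X.shape[0]))])
        sol = self._lu.solve(rhs)  # (n+1, m)
        w, mu = sol[:n], sol[n]
        pred = w.T @ self.y_
        if not (return_std or return_weights):
            return pred
        out = [pred]
        if return_std:
            var = np.maximum(np.sum(w * g0, axis=0) + mu, 0.0)
            out.append(np.sqrt(var))
        if return_weights:
            out.append(w.T)
        return tuple(out)

    def predict_variance(self, X):
        """Kriging prediction and variance (not SD) at the targets."""
        pred, sd = self.predict(X, return_std=True)
        return pred, sd**2

    def cross_validate(self) -> "CrossValidation":
        """Leave-one-out kriging over the training samples.

        Returns RMSE of the residuals and the OLS regression of observed on
        predicted (the form map-accuracy tables report).
        """
        check_is_fitted(self, "variogram_")
        X, y = self.X_, self.y_
        n = X.shape[0]
        if n < 5:
            raise ValueError("need >= 5 samples for cross-validation")
        preds = np.empty(n)
        for i in range(n):
            mask = np.arange(n) != i
            ok = OrdinaryKriging(variogram=self.variogram_)
            ok.fit(X[mask], y[mask])
            preds[i] = ok.predict(X[i : i + 1])[0]
        resid = y - preds
        rmse = float(np.sqrt(np.mean(resid**2)))
        # observed = slope * predicted + intercept
        A = np.vstack([preds, np.ones_like(preds)]).T
        slope, intercept = np.linalg.lstsq(A, y, rcond=None)[0]
        return CrossValidation(rmse, float(slope), float(intercept), preds)


class _LUSolver:
    """Cached LU factorization of the kriging matrix."""

    def __init__(self, a: np.ndarray):
        from scipy.linalg import lu_factor

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            try:
                self._fac = lu_factor(a)
            except Warning as w:  # scipy warns on exactly singular input
                raise np.linalg.LinAlgError(str(w)) from None
        diag = np.abs(np.diag(self._fac[0]))
        if np.any(diag < 1e-300) or not np.all(np.isfinite(self._fac[0])):
            raise np.linalg.LinAlgError("singular matrix")

    def solve(self, b: np.ndarray) -> np.ndarray:
        from scipy.linalg import lu_solve

        return lu_solve(self._fac, b)


@dataclass(frozen=True)
class CrossValidation:
    rmse: float
    slope: float
    intercept: float
    predictions: np.ndarray


@dataclass(frozen=True)
class KrigingSurface:
    """Regular-grid kriging output: predictions and kriging variance per
    cell, row 0 at the grid origin (lower-left), row-major."""

    origin: tuple[float, float]
    cell_size: float
    n_cols: int
    n_rows: int
    predictions: np.ndarray  # (n_rows, n_cols)
    variance: np.ndarray  # (n_rows, n_cols)

    def cell_centers(self) -> np.ndarray:
        x = self.origin[0] + (np.arange(self.n_cols) + 0.5) * self.cell_size
        y = self.origin[1] + (np.arange(self.n_rows) + 0.5) * self.cell_size
        xx, yy = np.meshgrid(x, y)
        return np.column_stack([xx.ravel(), yy.ravel()])


def _dedupe(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average values at duplicated coordinates, warning once."""
    uniq, inv, counts = np.unique(X, axis=0, return_inverse=True, return_counts=True)
    if uniq.shape[0] == X.shape[0]:
        return X, y
    warnings.warn(
        f"{X.shape[0] - uniq.shape[0]} duplicate sample location(s) averaged",
        stacklevel=3,
    )
    sums = np.zeros(uniq.shape[0])
    np.add.at(sums, inv, y)
    return uniq, sums / counts


def make_grid(
    coords: np.ndarray, cell_size: float, padding: float = 0.0
) -> tuple[tuple[float, float], int, int]:
    """Grid origin and dimensions covering the sample bounding box."""
    coords = np.asarray(coords, dtype=np.float64)
    x0, y0 = coords.min(axis=0) - padding
    x1, y1 = coords.max(axis=0) + padding
    n_cols = max(1, int(np.ceil((x1 - x0) / cell_size)))
    n_rows = max(1, int(np.ceil((y1 - y0) / cell_size)))
    return (float(x0), float(y0)), n_cols, n_rows


def ordinary_kriging(
    coords: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    targets: np.ndarray | None = None,
    cell_size: float | None = None,
) -> KrigingSurface | tuple[np.ndarray, np.ndarray]:
    """Krige to explicit target points (returns (pred, variance)) or to a
    regular grid of the given cell size (returns a :class:`KrigingSurface`)."""
    ok = OrdinaryKriging(variogram=model).fit(coords, values)
    if targets is not None:
        return ok.predict_variance(np.asarray(targets, dtype=np.float64))
    if cell_size is None:
        raise ValueError("give either targets or cell_size")
    origin, n_cols, n_rows = make_grid(np.asarray(coords), cell_size)
    surf = KrigingSurface(
        origin, cell_size, n_cols, n_rows, np.empty((n_rows, n_cols)),
        np.empty((n_rows, n_cols)),
    )
    pred, var = ok.predict_variance(surf.cell_centers())
    return KrigingSurface(
        origin,
        cell_size,
        n_cols,
        n_rows,
        pred.reshape(n_rows, n_cols),
        var.reshape(n_rows, n_cols),
    )


def cross_validate(
    coords: np.ndarray, values: np.ndarray, model: VariogramModel
) -> CrossValidation:
    """Leave-one-out kriging cross-validation with a fixed variogram."""
    return OrdinaryKriging(variogram=model).fit(coords, values).cross_validate()


def classify_surface(
    surface: KrigingSurface | np.ndarray, breaks
) -> pd.DataFrame:
    """Tabulate the percentage of cells in each concentration class.

    Classes are half-open intervals [low, high) over strictly ascending
    break edges; cells outside the envelope fall in an overflow class with
    a warning.  Percentages sum to 100 within rounding.
    """
    breaks = np.asarray(breaks, dtype=np.float64)
    if breaks.size < 2 or np.any(np.diff(breaks) <= 0):
        raise ValueError("breaks must be >= 2 strictly ascending edges")
    vals = (
        surface.predictions if isinstance(surface, KrigingSurface) else surface
    )
    vals = np.asarray(vals, dtype=np.float64).ravel()
    n = vals.size
    rows = []
    inside = np.zeros(n, dtype=bool)
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        sel = (vals >= lo) & (vals < hi)
        inside |= sel
        rows.append({"low": lo, "high": hi, "percent": 100.0 * sel.sum() / n})
    n_out = int((~inside).sum())
    if n_out:
        warnings.warn(f"{n_out} cell(s) outside the break envelope", stacklevel=2)
        rows.append(
            {"low": float("nan"), "high": float("nan"), "percent": 100.0 * n_out / n}
        )
    return pd.DataFrame(rows)
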