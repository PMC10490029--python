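"""Linear V → NO3⁻ calibration and device characterization metrics.

The device's calibration law is affine, ``NO3⁻ = intercept + slope · V``,
with V the mean HSV Value of the cuvette image on the 0–100 percent scale.
The reagent complex darkens with concentration, so the slope is negative.
Device quality is summarized by the sensitivity (|slope|), the limit of
detection LOD = 3.3·SD/σ, the relative standard deviation (%RSD) and the
relative bias (%bias) over quality-control replicate sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LinearCalibration",
    "Prediction",
    "DeviceMetrics",
    "fit_calibration",
    "sensitivity",
    "lod",
    "rsd_percent",
    "bias_percent",
    "characterize_device",
]


@dataclass(frozen=True)
class Prediction:
    """A single concentration prediction with range flags.

    ``concentration`` is clamped to ≥ 0; ``raw`` keeps the unclamped affine
    value.  ``below_range``/``extrapolated`` flag values outside the fitted
    concentration range.
    """

    concentration: float
    raw: float
    below_range: bool
    extrapolated: bool


class LinearCalibration(BaseEstimator, RegressorMixin):
    """Ordinary-least-squares calibration of concentration on mean V.

    The regression direction matches the printed form of the device law
    (concentration = a + b·V), i.e. classical calibration with V as the
    regressor, not inverse calibration.

    Parameters
    ----------
    v_scale : {"percent", "unit"}
        Scale of the V values the model is expressed in.  The printed
        coefficients are coherent on the percent (0–100) scale.
    clip_negative : bool
        Clamp negative predictions to zero in :meth:`predict` (raw values
        remain available through :meth:`predict_one`).

    Attributes
    ----------
    intercept_ : float
        mg L⁻¹ at V = 0.
    slope_ : float
        mg L⁻¹ per V-unit (signed; negative for this chemistry).
    r_squared_ : float
        Coefficient of determination on the training standards.
    valid_range_ : tuple of float
        (min, max) of the training concentrations.
    """

    def __init__(self, v_scale: str = "percent", clip_negative: bool = True):
        self.v_scale = v_scale
        self.clip_negative = clip_negative

    # -- sklearn API ---------------------------------------------------

    def fit(self, X, y):
        """Fit on standards: X is (n, 1) mean-V values, y concentrations."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must be a single mean-V column")
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        v = X[:, 0]
        if np.unique(v).size < 3:
            raise ValueError("need >= 3 distinct mean-V values to calibrate")
        # closed-form OLS on the centered design
        vbar, ybar = v.mean(), y.mean()
        sxx = float(((v - vbar) ** 2).sum())
        if sxx == 0.0:
            raise ValueError("zero variance in mean-V: degenerate design")
        sxy = float(((v - vbar) * (y - ybar)).sum())
        self.slope_ = sxy / sxx
        self.intercept_ = ybar - self.slope_ * vbar
        resid = y - (self.intercept_ + self.slope_ * v)
        sst = float(((y - ybar) ** 2).sum())
        self.r_squared_ = 1.0 if sst == 0.0 else 1.0 - float((resid**2).sum()) / sst
        self.valid_range_ = (float(y.min()), float(y.max()))
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        raw = self.intercept_ + self.slope_ * X[:, 0]
        return np.maximum(raw, 0.0) if self.clip_negative else raw

    # -- domain API ----------------------------------------------------

    def predict_one(self, mean_v: float) -> Prediction:
        """Predict a single concentration with below-range and
        extrapolation flags."""
        check_is_fitted(self, "slope_")
        raw = float(self.intercept_ + self.slope_ * mean_v)
        lo, hi = self.valid_range_
        below = raw < lo
        conc = max(raw, 0.0) if self.clip_negative else raw
        return Prediction(
            concentration=conc,
            raw=raw,
            below_range=below,
            extrapolated=raw > hi,
        )

    @property
    def sensitivity_(self) -> float:
        """|slope|: change in output concentration per unit change in V."""
        check_is_fitted(self, "slope_")
        return abs(self.slope_)

    def inverse_v(self, concentration: float) -> float:
        """V value that the fitted law maps to the given concentration."""
        check_is_fitted(self, "slope_")
        if self.slope_ == 0:
            raise ValueError("zero slope: inverse undefined")
        return (concentration - self.intercept_) / self.slope_

    # -- persistence ---------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "slope_")
        return {
            "schema": "nitracolor.calibration/1",
            "intercept": self.intercept_,
            "slope": self.slope_,
            "r_squared": self.r_squared_,
            "v_scale": self.v_scale,
            "valid_range": list(self.valid_range_),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinearCalibration":
        m = cls(v_scale=d.get("v_scale", "percent"))
        m.intercept_ = float(d["intercept"])
        m.slope_ = float(d["slope"])
        m.r_squared_ = float(d.get("r_squared", float("nan")))
        vr = d.get("valid_range", [0.0, 10.0])
        m.valid_range_ = (float(vr[0]), float(vr[1]))
        m.n_features_in_ = 1
        return m

    @classmethod
    def from_coefficients(
        cls,
        intercept: float,
        slope: float,
        valid_range: tuple[float, float] = (0.0, 10.0),
        v_scale: str = "percent",
    ) -> "LinearCalibration":
        """Construct directly from published coefficients."""
        return cls.from_dict(
            {
                "intercept": intercept,
                "slope": slope,
                "valid_range": list(valid_range),
                "v_scale": v_scale,
            }
        )


def fit_calibration(standards: pd.DataFrame) -> LinearCalibration:
    """Fit the calibration from a standards table with columns
    ``concentration_mg_per_L`` and ``mean_v`` (optionally ``replicate``)."""
    conc = standards["concentration_mg_per_L"].to_numpy(dtype=np.float64)
    v = standards["mean_v"].to_numpy(dtype=np.float64)
    return LinearCalibration().fit(v[:, None], conc)


def sensitivity(model: LinearCalibration) -> float:
    """Device sensitivity: |slope| in mg L⁻¹ per V-unit."""
    return model.sensitivity_


def lod(sd: float, sigma: float) -> float:
    """Limit of detection, 3.3 · SD / σ, assuming normally distributed
    noise.  SD is the standard deviation of device results (mg L⁻¹) and σ
    the sensitivity."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sigma <= 0:
        raise ValueError("sensitivity must be > 0")
    return 3.3 * sd / sigma


def rsd_percent(values: Sequence[float]) -> float:
    """Relative standard deviation: sample SD (n−1) over mean, ×100."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need >= 2 values")
    m = x.mean()
    if m == 0:
        raise ValueError("mean is zero: RSD undefined")
    return float(x.std(ddof=1) / m * 100.0)


def bias_percent(known: float, measured: Sequence[float]) -> float:
    """Relative bias: (known − mean(measured)) / known × 100.

    Positive values mean the device underestimates; negative, overestimates.
    """
    if known <= 0:
        raise ValueError("known concentration must be > 0")
    m = float(np.mean(np.asarray(measured, dtype=np.float64)))
    return (known - m) / known * 100.0


@dataclass(frozen=True)
class DeviceMetrics:
    """Characterization summary of a calibrated device."""

    lod: float
    sensitivity: float
    rsd_percent: float
    bias_percent: float
    sd: float
    interday_rsd_percent: float | None = None

    def to_dict(self) -> dict:
        return {
            "lod_mg_per_L": self.lod,
            "sensitivity_mg_per_L_per_V": self.sensitivity,
            "rsd_percent": self.rsd_percent,
            "bias_percent": self.bias_percent,
            "sd_mg_per_L": self.sd,
            "interday_rsd_percent": self.interday_rsd_percent,
        }


def characterize_device(
    qc_sets: Mapping[float, Sequence[float]],
    model: LinearCalibration,
    day_means: Iterable[float] | None = None,
) -> DeviceMetrics:
    """Compute device metrics from quality-control replicate sets.

    ``qc_sets`` maps each known concentration (mg L⁻¹) to its replicate
    measured concentrations.  The SD is pooled across sets as the
    root-mean-square of per-set sample SDs (appropriate for equal replicate
    counts under homoscedasticity); %RSD and %bias are averaged over sets;
    LOD combines the pooled SD with the model sensitivity.  If per-day mean
    concentrations are supplied, inter-day precision is their RSD.
    """
    if not qc_sets:
        raise ValueError("qc_sets is empty")
    sds, rsds, biases = [], [], []
    for known, reps in qc_sets.items():
        reps = np.asarray(reps, dtype=np.float64)
        if reps.size < 2:
            raise ValueError(f"set at {known} mg/L needs >= 2 replicates")
        sds.append(reps.std(ddof=1))
        rsds.append(rsd_percent(reps))
        biases.append(bias_percent(known, reps))
    pooled_sd = float(np.sqrt(np.mean(np.square(sds))))
    sigma = model.sensitivity_
    interday = None
    if day_means is not None:
        interday = rsd_percent(list(day_means))
    return DeviceMetrics(
        lod=lod(pooled_sd, sigma),
        sensitivity=sigma,
        rsd_percent=float(np.mean(rsds)),
        bias_percent=float(np.mean(biases)),
        sd=pooled_sd,
        interday_rsd_percent=interday,
    )
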