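"""Synthetic fixtures: cuvette images, calibration tables, replicate sets,
and spatial fields with known variogram structure.

Everything downstream can be exercised without any field data.  Cuvette
image fixtures are flat color patches — the quantification pipeline only
consumes the mean V, so photorealism adds nothing to test power.  Spatial
fields are drawn from the exact multivariate normal implied by a variogram
model, so parameter-recovery tests compare against a known truth.

All generators are pure functions of their spec, including the seed.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import LinearCalibration
from .geostats import VariogramModel, _structural
from .imaging import PixelGrid

__all__ = [
    "ImageFixtureSpec",
    "FieldFixtureSpec",
    "render_cuvette_image",
    "gen_calibration_table",
    "gen_replicate_table",
    "gen_gaussian_random_field",
    "STANDARD_CONCENTRATIONS",
    "QC_CONCENTRATIONS",
]

#: The 12-point standard dilution series (mg L⁻¹) used for calibration.
STANDARD_CONCENTRATIONS = (0.0, 0.5, 1.5, 2.5, 3.5, 4.5, 5.5, 6.5, 7.5, 8.5, 9.5, 10.0)

#: Quality-control concentrations spanning the calibration range.
QC_CONCENTRATIONS = (0.25, 1.25, 2.75, 3.75, 5.75, 8.75)


@dataclass(frozen=True)
class ImageFixtureSpec:
    """Recipe for one synthetic cuvette photograph.

    The target mean V (percent) is the calibration law inverted at
    ``concentration``; ``noise_sd`` is per-pixel Gaussian noise in V
    percent units.  Hue defaults to the yellow of the nitrate–chromotropic
    acid complex; saturation rises with concentration, emulating the color
    deepening as the complex forms.
    """

    concentration: float
    calibration: LinearCalibration
    noise_sd: float = 0.0
    size: int = 64
    hue_base: float = 55.0
    seed: int = 0


@dataclass(frozen=True)
class FieldFixtureSpec:
    """Recipe for a georeferenced sample set with known spatial structure."""

    n_points: int
    variogram: VariogramModel
    domain: tuple[float, float, float, float] = (0.0, 0.0, 100.0, 100.0)
    mean: float = 30.0
    seed: int = 0


def render_cuvette_image(spec: ImageFixtureSpec) -> PixelGrid:
    """Render a flat color patch whose mean V encodes the concentration.

    The V target (percent) is ``(intercept − c)/|slope|`` for the usual
    negative-slope law; pixels get seeded Gaussian V noise of ``noise_sd``
    and are converted from HSV (fixed hue, concentration-scaled saturation)
    to 8-bit RGB.
    """
    model = spec.calibration
    if model.slope_ == 0:
        raise ValueError("calibration slope must be nonzero")
    v_target = model.inverse_v(spec.concentration)  # percent scale
    if not 0.0 <= v_target <= 100.0:
        raise ValueError(
            f"target V {v_target:.2f}% outside [0, 100] for "
            f"{spec.concentration} mg/L"
        )
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    v = v_target / 100.0 + rng.normal(0.0, spec.noise_sd / 100.0, size=(n, n))
    v = np.clip(v, 0.0, 1.0)
    lo, hi = model.valid_range_
    span = max(hi - lo, 1e-12)
    sat = 0.15 + 0.6 * (spec.concentration - lo) / span
    sat = float(np.clip(sat, 0.0, 1.0))
    hue = (spec.hue_base % 360.0) / 360.0
    # HSV → RGB with V per pixel, constant hue and saturation
    r0, g0, b0 = colorsys.hsv_to_rgb(hue, sat, 1.0)
    rgb = np.stack([v * r0, v * g0, v * b0], axis=-1)
    return PixelGrid(np.round(rgb * 255.0).astype(np.uint8))


def gen_calibration_table(
    concentrations=STANDARD_CONCENTRATIONS,
    model: LinearCalibration | None = None,
    noise_sd: float = 0.0,
    n_reps: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Standards table: mean V from the inverted calibration law plus
    seeded Gaussian noise per replicate.

    Columns: concentration_mg_per_L, mean_v, replicate.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if model is None:
        model = LinearCalibration.from_coefficients(24.82, -0.26)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_reps + 1):
        for c in concentrations:
            v = model.inverse_v(c) + rng.normal(0.0, noise_sd)
            rows.append(
                {"concentration_mg_per_L": c, "mean_v": v, "replicate": rep}
            )
    return pd.DataFrame(rows)


def gen_replicate_table(
    n_samples: int = 30,
    k: int = 5,
    mean: float = 5.0,
    between_sd: float = 2.0,
    within_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate measurements: per-sample true values N(mean, between_sd²)
    observed ``k`` times with N(0, within_sd²) device noise.

    Columns: sample_id, rep_1 .. rep_k.
    """
    rng = np.random.default_rng(seed)
    truth = rng.normal(mean, between_sd, size=n_samples)
    reps = truth[:, None] + rng.normal(0.0, within_sd, size=(n_samples, k))
    df = pd.DataFrame(reps, columns=[f"rep_{i + 1}" for i in range(k)])
    df.insert(0, "sample_id", [f"S{i + 1:03d}" for i in range(n_samples)])
    return df


def gen_gaussian_random_field(spec: FieldFixtureSpec) -> pd.DataFrame:
    """Sample a Gaussian random field at random locations.

    Locations are uniform over the domain box; values are jointly Gaussian
    with covariance C(h) = partial_sill · (1 − g(h/range)) from the
    structural part of the variogram, plus independent nugget noise, so the
    realized semivariogram matches γ(h) = nugget + partial_sill·g(h/range)
    in expectation.  The covariance matrix is factorized by Cholesky with a
    small jitter retry.

    Columns: sample_id, x, y, value.
    """
    if spec.n_points > 2000:
        raise ValueError("n_points > 2000: dense factorization not supported")
    rng = np.random.default_rng(spec.seed)
    x0, y0, x1, y1 = spec.domain
    xy = np.column_stack(
        [
            rng.uniform(x0, x1, size=spec.n_points),
            rng.uniform(y0, y1, size=spec.n_points),
        ]
    )
    vg = spec.variogram
    from scipy.spatial.distance import squareform, pdist

    if vg.partial_sill > 0:
        h = squareform(pdist(xy))
        cov = vg.partial_sill * (1.0 - _structural(vg.family, h, vg.range_))
        z = None
        for jitter in (0.0, 1e-10, 1e-8, 1e-6):
            try:
                L = np.linalg.cholesky(
                    cov + jitter * vg.partial_sill * np.eye(spec.n_points)
                )
            except np.linalg.LinAlgError:
                continue
            z = L @ rng.standard_normal(spec.n_points)
            break
        if z is None:
            raise RuntimeError("covariance not positive definite after jitter")
    else:
        z = np.zeros(spec.n_points)
        rng.standard_normal(spec.n_points)  # keep the stream layout stable
    values = spec.mean + z
    if vg.nugget > 0:
        values = values + rng.normal(0.0, np.sqrt(vg.nugget), size=spec.n_points)
    df = pd.DataFrame(
        {
            "sample_id": [f"P{i + 1:04d}" for i in range(spec.n_points)],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "value": values,
        }
    )
    return df
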