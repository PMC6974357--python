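"""Ratiometric O2-optode image calibration.

A sensor paint of O2-quenched red-emitting indicator nanoparticles with a
constant green reference dye is imaged with an RGB camera. The pixelwise
ratio R = red/green falls exponentially with O2, so the dark-anoxic
referenced quantity ΔR = R_dark − R follows a saturating single exponential

    ΔR(C) = a · (1 − e^(−b·C)),        C in % air saturation,

with ΔR(0) = 0 by construction. ΔR referencing also cancels additive
red-channel backgrounds that are constant in time (e.g. chlorophyll-a
autofluorescence excited by the measuring light). The calibration is fitted
on ROI-mean ΔR at known bulk O2 levels and inverted per pixel,

    C = −ln(1 − ΔR/a) / b,

with ΔR clamped into [0, a(1 − eps)] so the inversion stays bounded near the
asymptote; clamped pixels are flagged. Conversion from % air saturation to
µmol O2 L⁻¹ uses the combined-fit seawater O2 solubility of Garcia & Gordon
(1992) with EOS-80 surface density.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import curve_fit

from .types import (
    CalibrationModel,
    DeltaRatioImage,
    DimensionError,
    O2Image,
    RatioImage,
    RGBFrame,
)

__all__ = [
    "ratio_image",
    "delta_ratio",
    "dark_reference",
    "fit_calibration",
    "invert_calibration",
    "o2_solubility_umol_kg",
    "seawater_density",
    "airsat_to_concentration",
    "CalibrationError",
]


class CalibrationError(RuntimeError):
    """Calibration fit failed or produced a non-physical model."""


# ---------------------------------------------------------------------------
# ratio and delta-ratio images
# ---------------------------------------------------------------------------

def ratio_image(frame: RGBFrame, green_floor: float | None = None) -> RatioImage:
    """Pixelwise R = red/green; the blue channel is unused by the sensor.

    Pixels whose green reference signal falls below ``green_floor`` are
    masked (divide-by-near-zero noise). The default floor is 1% of the green
    channel's dynamic range, taken as its maximum for float data.
    """
    if green_floor is None:
        green_floor = 0.01 * float(np.nanmax(frame.green, initial=0.0))
    mask = ~(frame.green > green_floor) | ~np.isfinite(frame.red) | ~np.isfinite(frame.green)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = frame.red / frame.green
    r[mask] = np.nan
    return RatioImage(r, mask=mask, t=frame.t, light=frame.light)


def delta_ratio(r: RatioImage, r_dark: RatioImage) -> DeltaRatioImage:
    """ΔR = R_dark − R, referencing to the dark-anoxic state; masks union."""
    if r.data.shape != r_dark.data.shape:
        raise DimensionError("ratio images are not co-registered")
    mask = r.mask | r_dark.mask
    dr = r_dark.data - r.data
    dr[mask] = np.nan
    return DeltaRatioImage(dr, mask=mask, reference_t=r_dark.t, t=r.t, light=r.light)


def dark_reference(
    ratios: list[RatioImage],
    min_dark_minutes: float = 45.0,
    before_t: float | None = None,
) -> RatioImage:
    """Dark-anoxic reference ratio image.

    Mean of all frames recorded in darkness at t ≥ ``min_dark_minutes``
    (steady-state anoxia after the initial dark incubation). Pass
    ``before_t`` (typically the first light-on time) to exclude dark frames
    recorded after illumination, when O2 may still be decaying.
    """
    sel = [r for r in ratios if r.light == "dark" and r.t is not None and r.t >= min_dark_minutes]
    if before_t is not None:
        sel = [r for r in sel if r.t <= before_t]
    if not sel:
        raise ValueError(
            f"no dark frames with t ≥ {min_dark_minutes} min to build the anoxic reference"
        )
    stack = np.stack([r.data for r in sel])
    mask = np.any([r.mask for r in sel], axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    mean[mask] = np.nan
    return RatioImage(mean, mask=mask, t=sel[-1].t, light="dark")


# ---------------------------------------------------------------------------
# calibration fit and inversion
# ---------------------------------------------------------------------------

def _model(c, a, b):
    return a * (1.0 - np.exp(-b * c))


def fit_calibration(pairs) -> CalibrationModel:
    """Nonlinear least-squares fit of ΔR = a·(1 − e^(−b·C)).

    ``pairs`` is a sequence of ``(delta_r, o2_percent_airsat)`` ROI means.
    Requires ≥ 3 points spanning ≥ 2 distinct O2 levels, with the lowest
    level at or near anoxia (≤ 5% air saturation) so the reference state is
    constrained. Initialization: a₀ = max ΔR (scaled just above, so the log
    is defined), b₀ from inverting the model at the largest sub-asymptotic
    point.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be (delta_r, o2_percent_airsat) rows")
    dr, c = pairs[:, 0], pairs[:, 1]
    if len(dr) < 3:
        raise ValueError("need at least 3 calibration points")
    if len(np.unique(c)) < 2:
        raise ValueError("need at least 2 distinct O2 levels")
    if c.min() > 5.0:
        raise ValueError("calibration must include an (near-)anoxic level (C ≤ 5% air sat)")
    if c.min() < 0:
        raise ValueError("O2 levels must be nonnegative")

    a0 = float(dr.max()) * 1.05
    if a0 <= 0:
        raise CalibrationError("all ΔR values nonpositive; nothing to fit")
    # invert the model at the highest-C point for a rate-constant guess
    i = int(np.argmax(c))
    frac = min(max(dr[i] / a0, 1e-6), 1 - 1e-6)
    b0 = -np.log(1.0 - frac) / c[i] if c[i] > 0 else 0.01
    try:
        popt, _ = curve_fit(
            _model, c, dr, p0=[a0, max(b0, 1e-8)],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise CalibrationError(f"calibration fit did not converge: {exc}") from exc
    a, b = float(popt[0]), float(popt[1])
    if not (a > 0 and b > 0) or not np.isfinite(a * b):
        raise CalibrationError(f"non-physical calibration parameters a={a}, b={b}")
    rss = float(np.sum((_model(c, a, b) - dr) ** 2))
    return CalibrationModel(a=a, b=b, rss=rss, n=len(dr))


def invert_calibration(
    model: CalibrationModel,
    dr: DeltaRatioImage,
    eps: float = 1e-6,
    max_airsat: float = 150.0,
) -> O2Image:
    """Invert the calibration per pixel: C = −ln(1 − ΔR/a)/b.

    ΔR is clamped into [0, a·(1 − eps)] before inversion (pixels at or above
    the asymptote are flagged), and the result is capped at ``max_airsat``
    % air saturation.
    """
    data = dr.data
    clamped = (~dr.mask) & ((data < 0) | (data >= model.a * (1 - eps)))
    clipped = np.clip(data, 0.0, model.a * (1.0 - eps))
    with np.errstate(divide="ignore", invalid="ignore"):
        c = -np.log(1.0 - clipped / model.a) / model.b
    c = np.minimum(c, max_airsat)
    c[dr.mask] = np.nan
    return O2Image(c, mask=dr.mask.copy(), t=dr.t, light=dr.light, clamped=clamped)


# ---------------------------------------------------------------------------
# O2 solubility: % air saturation → µmol L⁻¹
# ---------------------------------------------------------------------------

# Garcia & Gordon (1992), combined fit to the Benson & Krause data, µmol/kg.
_GG_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_GG_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_GG_C0 = -2.75915e-7


def o2_solubility_umol_kg(temp_c: float, salinity: float) -> float:
    """Air-saturated O2 concentration in µmol per kg of seawater."""
    ts = np.log((298.15 - temp_c) / (273.15 + temp_c))  # scaled temperature
    lnc = sum(a * ts**i for i, a in enumerate(_GG_A))
    lnc += salinity * sum(b * ts**i for i, b in enumerate(_GG_B))
    lnc += _GG_C0 * salinity**2
    return float(np.exp(lnc))


def seawater_density(temp_c: float, salinity: float) -> float:
    """Density of seawater at atmospheric pressure (EOS-80), kg m⁻³."""
    t, s = temp_c, salinity
    rho_w = (999.842594 + 6.793952e-2 * t - 9.095290e-3 * t**2
             + 1.001685e-4 * t**3 - 1.120083e-6 * t**4 + 6.536332e-9 * t**5)
    a = (0.824493 - 4.0899e-3 * t + 7.6438e-5 * t**2
         - 8.2467e-7 * t**3 + 5.3875e-9 * t**4)
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return rho_w + a * s + b * s**1.5 + c * s**2


def airsat_to_concentration(c_airsat, temp_c: float = 23.0, salinity: float = 35.0):
    """Convert % air saturation to µmol O2 L⁻¹ at given temperature/salinity.

    concentration = (C/100) × C_sat(T, S), with C_sat from the Garcia–Gordon
    combined-fit solubility (µmol/kg) times the EOS-80 density (kg/L).
    Scalar or array input; defaults are the experimental conditions
    (23 °C, salinity 35).
    """
    if not (-2.0 <= temp_c <= 40.0):
        raise ValueError(f"temperature {temp_c} °C outside supported range [-2, 40]")
    if not (0.0 <= salinity <= 42.0):
        raise ValueError(f"salinity {salinity} outside supported range [0, 42]")
    csat_umol_l = o2_solubility_umol_kg(temp_c, salinity) * seawater_density(temp_c, salinity) / 1000.0
    return np.asarray(c_airsat, dtype=float) / 100.0 * csat_umol_l if np.ndim(c_airsat) \
        else float(c_airsat) / 100.0 * csat_umol_l
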