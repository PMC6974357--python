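"""Synthetic hyperspectral scenes and optode time series with known truth.

Every stage of the analysis has a closed-form forward model here, so the
pipeline can be validated end-to-end without any measured data:

* Hyperspectral scenes: each pixel's reflectance is a smooth baseline
  (degree ≤ 3 polynomial, optionally plus a broad Gaussian) multiplied by
  Gaussian absorption dips, ``R(λ,x,y) = B(λ)·∏ᵢ(1 − Aᵢ(x,y)·Gᵢ(λ))`` —
  a chlorophyll-a dip near 675 nm in a surface layer and chlorophyll-f dips
  near 720 nm in deeper hotspots, mimicking an endolithic biofilm
  cross-section. Raw counts are reconstructed through the acquisition model
  (reflectance standard spectrum, dark offset, additive Gaussian noise), so
  the calibration stage is exercised too.

* Optode series: O2 relaxes pixel-locally and exponentially toward a
  steady-state field after light-on and back toward anoxia after light-off
  (time constant τ; no lateral diffusion, so analytic truth exists), and the
  camera model is ``red = G₀·(a·e^(−b·C) + r_inf) + noise`` over a constant
  green reference — exactly the single-exponential calibration family the
  analysis fits.

All generators are bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .optode import airsat_to_concentration
from .types import LightEvent, RGBFrame, ScalarImage, SpectralCube

__all__ = [
    "LayerLayout",
    "HotspotLayout",
    "PigmentSpec",
    "SceneParams",
    "SceneData",
    "synth_hyperspectral_scene",
    "OptodeParams",
    "OptodeData",
    "synth_optode_timeseries",
    "synth_calibration_series",
    "linked_beachrock_pair",
]


# ---------------------------------------------------------------------------
# hyperspectral scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerLayout:
    """A horizontal band (surface biofilm layer) of uniform abundance.

    ``row_frac`` bounds are fractions of image height; amplitude is the
    relative abundance (0–1) inside the band.
    """

    row_frac: tuple[float, float] = (0.0, 0.25)
    amplitude: float = 1.0


@dataclass(frozen=True)
class HotspotLayout:
    """Gaussian abundance hotspots scattered in a depth band.

    ``radius_px`` is the Gaussian σ of each blob in pixels; centers are drawn
    uniformly at random inside the ``row_frac`` depth band.
    """

    count: int = 3
    radius_px: float = 5.0
    amplitude: float = 1.0
    row_frac: tuple[float, float] = (0.4, 0.8)


@dataclass(frozen=True)
class PigmentSpec:
    """One pigment: a Gaussian absorption dip over a spatial abundance map."""

    name: str
    center_nm: float
    sigma_nm: float
    max_depth: float
    layout: LayerLayout | HotspotLayout | np.ndarray = field(default_factory=HotspotLayout)

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_depth < 1.0):
            raise ValueError(f"dip depth fraction must be in [0, 1), got {self.max_depth}")


@dataclass
class SceneParams:
    """Configuration of a synthetic hyperspectral beachrock cross-section.

    Defaults reproduce the qualitative structure of the study scenes: a
    chl-a-rich surface layer and deeper chl-f hotspots, imaged at 2 nm steps
    against a 20% reflectance standard. ``noise_sigma_pct`` is additive
    Gaussian noise expressed in % reflectance units.
    """

    shape: tuple[int, int] = (64, 64)
    wl_start: float = 400.0
    wl_stop: float = 850.0
    wl_step: float = 2.0
    baseline_coeffs: tuple[float, ...] = (25.0, 20.0, -10.0, 3.0)  # % reflectance, in u = (λ-λ0)/(λ1-λ0)
    baseline_gauss: tuple[float, float, float] | None = None  # (center nm, sigma nm, amplitude %)
    pigments: tuple[PigmentSpec, ...] = (
        PigmentSpec("chla", 675.0, 8.0, 0.6, LayerLayout((0.0, 0.25), 1.0)),
        PigmentSpec("chlf", 720.0, 8.0, 0.4, HotspotLayout(3, 5.0, 1.0, (0.4, 0.8))),
    )
    standard_pct: float = 20.0
    standard_level: float = 1000.0  # counts of the reference spectrum
    dark_level: float = 50.0  # counts
    noise_sigma_pct: float = 0.0
    seed: int = 0

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.wl_stop - self.wl_start) / self.wl_step)) + 1
        return self.wl_start + self.wl_step * np.arange(n)

    def __post_init__(self) -> None:
        if len(self.baseline_coeffs) > 4:
            raise ValueError("baseline polynomial must have degree ≤ 3")
        wl = self.wavelengths
        for p in self.pigments:
            if not (wl[0] <= p.center_nm <= wl[-1]):
                raise ValueError(f"dip center {p.center_nm} nm outside wavelength grid")


@dataclass
class SceneData:
    """A synthetic scene plus its ground truth."""

    raw: SpectralCube
    dark: SpectralCube
    standard: SpectralCube
    standard_dark: SpectralCube
    reflectance_true: SpectralCube
    truth: dict[str, ScalarImage]  # per-pigment true abundance·depth maps
    params: SceneParams


def _layout_map(layout, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    if isinstance(layout, np.ndarray):
        m = np.asarray(layout, dtype=float)
        if m.shape != shape:
            raise ValueError("explicit layout map shape differs from scene shape")
        return np.clip(m, 0.0, 1.0)
    if isinstance(layout, LayerLayout):
        m = np.zeros(shape)
        r0, r1 = (int(round(f * h)) for f in layout.row_frac)
        m[r0:r1] = layout.amplitude
        return np.clip(m, 0.0, 1.0)
    if isinstance(layout, HotspotLayout):
        rr, cc = np.mgrid[0:h, 0:w]
        m = np.zeros(shape)
        r0 = layout.row_frac[0] * h
        r1 = layout.row_frac[1] * h
        for _ in range(layout.count):
            cy = rng.uniform(r0, r1)
            cx = rng.uniform(layout.radius_px, w - layout.radius_px)
            d2 = (rr - cy) ** 2 + (cc - cx) ** 2
            m += layout.amplitude * np.exp(-d2 / (2.0 * layout.radius_px**2))
        return np.clip(m, 0.0, 1.0)
    raise TypeError(f"unsupported layout {type(layout).__name__}")


def synth_hyperspectral_scene(params: SceneParams) -> SceneData:
    """Generate raw/dark/standard stacks and ground-truth pigment maps."""
    rng = np.random.default_rng(params.seed)
    wl = params.wavelengths
    h, w = params.shape
    u = (wl - wl[0]) / (wl[-1] - wl[0])
    baseline = np.polynomial.polynomial.polyval(u, params.baseline_coeffs)
    if params.baseline_gauss is not None:
        c, s, amp = params.baseline_gauss
        baseline = baseline + amp * np.exp(-((wl - c) ** 2) / (2.0 * s**2))
    if np.any(baseline <= 0):
        raise ValueError("baseline reflectance must stay positive")

    refl = np.broadcast_to(baseline[:, None, None], (wl.size, h, w)).copy()
    truth: dict[str, ScalarImage] = {}
    for p in params.pigments:
        amap = p.max_depth * _layout_map(p.layout, params.shape, rng)
        g = np.exp(-((wl - p.center_nm) ** 2) / (2.0 * p.sigma_nm**2))
        refl *= 1.0 - amap[None] * g[:, None, None]
        truth[p.name] = ScalarImage(amap, units="true dip depth (0-1)")

    # acquisition model: counts = reflectance/standard_pct · standard_ref + dark
    standard_ref = params.standard_level * (0.9 + 0.2 * u)  # smooth lamp spectrum
    sigma_counts = params.noise_sigma_pct * standard_ref / params.standard_pct
    raw = refl / params.standard_pct * standard_ref[:, None, None] + params.dark_level
    std = np.broadcast_to(
        standard_ref[:, None, None] + params.dark_level, (wl.size, h, w)
    ).copy()
    if params.noise_sigma_pct > 0:
        raw = raw + rng.standard_normal(raw.shape) * sigma_counts[:, None, None]
        std = std + rng.standard_normal(std.shape) * sigma_counts[:, None, None]
    dark = np.full((wl.size, h, w), params.dark_level)
    return SceneData(
        raw=SpectralCube(wl, np.clip(raw, 0.0, None), kind="raw"),
        dark=SpectralCube(wl, dark, kind="raw"),
        standard=SpectralCube(wl, np.clip(std, 0.0, None), kind="raw"),
        standard_dark=SpectralCube(wl, dark.copy(), kind="raw"),
        reflectance_true=SpectralCube(wl, refl, kind="reflectance"),
        truth=truth,
        params=params,
    )


# ---------------------------------------------------------------------------
# optode time series
# ---------------------------------------------------------------------------

@dataclass
class OptodeParams:
    """Configuration of a synthetic ratiometric-optode experiment.

    Defaults emulate the study protocol: the anoxic dark sample is imaged
    every 5 min, actinic NIR is switched on at t = 50 min (after the ≥ 45 min
    dark-anoxic reference window), held for 30 min while O2 hotspots rise
    toward ``c_ss_airsat`` (50% air saturation, matching the observed 40–50%
    within 15–20 min for τ = 5 min), then switched off for 30 min.
    The calibration truth (a = 1.5, b = 0.02 per % air sat) keeps the sensor
    sensitive across the full 0–100% range (ΔR at 100% ≈ 86% of the
    asymptote), as for typical ratiometric indicator/reference paints.
    ``noise_sigma`` is additive Gaussian camera noise in counts; the
    reference SNR is ``green_level / noise_sigma`` (the default σ = 0 is
    noiseless). ``dynamics='ramp'`` replaces
    the exponential relaxation with a linear ramp over ``ramp_minutes``
    (piecewise-constant true rates).
    """

    shape: tuple[int, int] = (48, 64)
    a: float = 1.5
    b: float = 0.02  # per % air saturation
    r_inf: float = 0.5  # red/green ratio at infinite O2
    green_level: float = 1000.0
    blue_level: float = 100.0
    c_ss_airsat: float = 50.0
    c_ss_field: np.ndarray | None = None  # explicit steady-state map, % air sat
    hotspots: HotspotLayout = field(
        default_factory=lambda: HotspotLayout(3, 5.0, 1.0, (0.3, 0.8))
    )
    tau_minutes: float = 5.0
    frame_interval: float = 5.0
    t_light_on: float = 50.0
    t_light_off: float = 80.0
    t_end: float = 110.0
    dynamics: str = "exponential"  # or "ramp"
    ramp_minutes: float = 15.0
    noise_sigma: float = 0.0
    temp_c: float = 23.0
    salinity: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.tau_minutes > 0):
            raise ValueError("a, b and tau must be positive")
        if not 0 < self.t_light_on < self.t_light_off < self.t_end:
            raise ValueError("need 0 < t_light_on < t_light_off < t_end")
        if self.dynamics not in ("exponential", "ramp"):
            raise ValueError(f"unknown dynamics {self.dynamics!r}")


@dataclass
class OptodeData:
    """Synthetic optode frames plus analytic ground truth."""

    frames: list[RGBFrame]
    manifest: pd.DataFrame
    c_fields: np.ndarray  # (T, H, W) true O2, % air saturation
    inst_rates: np.ndarray  # (T, H, W) true dC/dt, µmol O2 L⁻¹ min⁻¹
    bracket_rates: dict[str, np.ndarray]  # event kind → bracket-mean rate map
    c_ss: np.ndarray
    events: list[LightEvent]
    params: OptodeParams


def _o2_field(p: OptodeParams, c_ss: np.ndarray, t: float) -> np.ndarray:
    """True O2 field at time t under pixel-local relaxation dynamics."""
    if t <= p.t_light_on:
        return np.zeros_like(c_ss)
    if p.dynamics == "exponential":
        if t <= p.t_light_off:
            return c_ss * (1.0 - np.exp(-(t - p.t_light_on) / p.tau_minutes))
        c_off = c_ss * (1.0 - np.exp(-(p.t_light_off - p.t_light_on) / p.tau_minutes))
        return c_off * np.exp(-(t - p.t_light_off) / p.tau_minutes)
    # linear ramp: piecewise-constant rates
    if t <= p.t_light_off:
        return c_ss * min((t - p.t_light_on) / p.ramp_minutes, 1.0)
    c_off = c_ss * min((p.t_light_off - p.t_light_on) / p.ramp_minutes, 1.0)
    frac = max(1.0 - (t - p.t_light_off) / p.ramp_minutes, 0.0)
    return c_off * frac


def _inst_rate(p: OptodeParams, c_ss: np.ndarray, t: float) -> np.ndarray:
    """Analytic dC/dt at time t, % air sat per minute."""
    eps = 1e-9
    if t <= p.t_light_on:
        return np.zeros_like(c_ss)
    if p.dynamics == "exponential":
        if t <= p.t_light_off:
            return c_ss / p.tau_minutes * np.exp(-(t - p.t_light_on) / p.tau_minutes)
        c_off = c_ss * (1.0 - np.exp(-(p.t_light_off - p.t_light_on) / p.tau_minutes))
        return -c_off / p.tau_minutes * np.exp(-(t - p.t_light_off) / p.tau_minutes)
    if t <= p.t_light_off:
        return (c_ss / p.ramp_minutes if t - p.t_light_on < p.ramp_minutes - eps
                else np.zeros_like(c_ss))
    c_off = c_ss * min((p.t_light_off - p.t_light_on) / p.ramp_minutes, 1.0)
    return (-c_off / p.ramp_minutes if t - p.t_light_off < p.ramp_minutes - eps
            else np.zeros_like(c_ss))


def synth_optode_timeseries(p: OptodeParams) -> OptodeData:
    """Generate an optode RGB time series with analytic rate truth.

    Truth exported per frame: the O2 field (% air saturation) and the
    instantaneous rate dC/dt (µmol O2 L⁻¹ min⁻¹). Truth per light event:
    the bracket-mean rate (C_after − C_before)/Δt over the frame pair around
    the event — the quantity the finite-difference estimator targets.
    """
    rng = np.random.default_rng(p.seed)
    if p.c_ss_field is not None:
        c_ss = np.asarray(p.c_ss_field, dtype=float)
        if c_ss.shape != p.shape:
            raise ValueError("c_ss_field shape differs from scene shape")
        if np.any(c_ss < 0):
            raise ValueError("steady-state O2 must be nonnegative")
    else:
        c_ss = p.c_ss_airsat * _layout_map(p.hotspots, p.shape, rng)

    times = np.arange(0.0, p.t_end + 1e-9, p.frame_interval)
    events = [LightEvent(p.t_light_on, "light_on"), LightEvent(p.t_light_off, "light_off")]

    conv = float(airsat_to_concentration(100.0, p.temp_c, p.salinity)) / 100.0
    frames, rows = [], []
    c_fields = np.empty((times.size,) + p.shape)
    inst = np.empty_like(c_fields)
    for k, t in enumerate(times):
        c = _o2_field(p, c_ss, t)
        c_fields[k] = c
        inst[k] = _inst_rate(p, c_ss, t) * conv
        light = "nir_on" if p.t_light_on < t <= p.t_light_off else "dark"
        red = p.green_level * (p.a * np.exp(-p.b * c) + p.r_inf)
        green = np.full(p.shape, p.green_level)
        blue = np.full(p.shape, p.blue_level)
        if p.noise_sigma > 0:
            red = red + rng.standard_normal(p.shape) * p.noise_sigma
            green = green + rng.standard_normal(p.shape) * p.noise_sigma
            blue = blue + rng.standard_normal(p.shape) * p.noise_sigma
        frames.append(RGBFrame(red, green, blue, t=float(t), light=light))
        rows.append({"frame": k, "t_minutes": float(t), "light_state": light})

    bracket = {}
    for ev in events:
        i = int(np.nonzero(times <= ev.t)[0][-1])
        j = int(np.nonzero(times > ev.t)[0][0])
        bracket[ev.kind] = (c_fields[j] - c_fields[i]) / (times[j] - times[i]) * conv
    return OptodeData(
        frames=frames,
        manifest=pd.DataFrame(rows),
        c_fields=c_fields,
        inst_rates=inst,
        bracket_rates=bracket,
        c_ss=c_ss,
        events=events,
        params=p,
    )


def synth_calibration_series(
    a: float,
    b: float,
    levels: int | Sequence[float] = 8,
    sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """ΔR-vs-O2 calibration pairs from the forward model, optionally noisy.

    ``levels`` is the number of evenly spaced O2 levels spanning 0–100% air
    saturation, or an explicit sequence of levels.
    """
    c = (np.linspace(0.0, 100.0, int(levels)) if np.isscalar(levels)
         else np.asarray(levels, dtype=float))
    if c.min() > 5.0 or c.max() < 95.0:
        raise ValueError("calibration levels should span ~0–100% air saturation")
    rng = np.random.default_rng(seed)
    dr = a * (1.0 - np.exp(-b * c))
    if sigma > 0:
        dr = dr + rng.standard_normal(c.shape) * sigma
    return pd.DataFrame({"delta_r": dr, "o2_percent_airsat": c})


# ---------------------------------------------------------------------------
# linked scenes: shared spatial truth for co-location checks
# ---------------------------------------------------------------------------

def linked_beachrock_pair(
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    c_ss_airsat: float = 50.0,
    **scene_kwargs,
) -> tuple[SceneParams, OptodeParams]:
    """Scene and optode configurations sharing one chl-f hotspot field.

    The far-red pigment abundance map of the hyperspectral scene and the
    steady-state O2 production field of the optode series are the same
    spatial field, emulating NIR-driven O2 hotspots that co-locate with
    chlorophyll-f patches.
    """
    rng = np.random.default_rng(seed)
    layout = HotspotLayout(3, 5.0, 1.0, (0.4, 0.8))
    fieldmap = _layout_map(layout, shape, rng)
    scene = SceneParams(
        shape=shape,
        pigments=(
            PigmentSpec("chla", 675.0, 8.0, 0.6, LayerLayout((0.0, 0.25), 1.0)),
            PigmentSpec("chlf", 720.0, 8.0, 0.4, fieldmap),
        ),
        seed=seed,
        **scene_kwargs,
    )
    optode = OptodeParams(shape=shape, c_ss_field=c_ss_airsat * fieldmap, seed=seed)
    return scene, optode
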