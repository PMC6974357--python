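"""Shared container types for the imaging pipeline.

All images are 2-D ``(H, W)`` numpy arrays in 0-based (row, col) coordinates
with the origin at the top-left. Spectral cubes are ``(bands, H, W)`` with an
ascending wavelength vector in nm. Invalid pixels are tracked with explicit
boolean masks (``True`` = invalid); masks only ever grow along the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "SpectralCube",
    "BandWindow",
    "ScalarImage",
    "PigmentMaps",
    "RGBFrame",
    "RatioImage",
    "DeltaRatioImage",
    "CalibrationModel",
    "O2Image",
    "LightEvent",
    "O2Series",
    "RateMaps",
    "ArealRate",
    "DimensionError",
]

CubeKind = Literal["raw", "dark_corrected", "reflectance", "fluorescence", "derivative"]


class DimensionError(ValueError):
    """Shapes or wavelength vectors of two inputs do not match."""


@dataclass
class SpectralCube:
    """A hyperspectral image stack: one image plane per wavelength band.

    Parameters
    ----------
    wavelengths : array of float
        Strictly ascending band-center wavelengths in nm, length ``W``.
    data : array
        ``(W, H, Wd)`` array of nonnegative intensities (counts) or
        % reflectance, depending on ``kind``.
    kind : str
        One of ``raw``, ``dark_corrected``, ``reflectance``, ``fluorescence``,
        ``derivative``.
    """

    wavelengths: np.ndarray
    data: np.ndarray
    kind: CubeKind = "raw"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be a 1-D vector")
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (bands, rows, cols)")
        if len(self.wavelengths) != self.data.shape[0]:
            raise DimensionError(
                f"{len(self.wavelengths)} wavelengths but {self.data.shape[0]} planes"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind == "reflectance" and np.nanmax(self.data, initial=0.0) > 100.0:
            # Values above the 100% ceiling are physically possible for specular
            # glints; keep them but flag the cube.
            self.overrange = True
        else:
            self.overrange = False

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def band_index(self, nm: float, tol: float = 5.0) -> int:
        """Index of the sampled band nearest ``nm``.

        Ties snap to the lower wavelength. Raises if the nearest band is
        farther than ``tol`` nm away.
        """
        d = np.abs(self.wavelengths - nm)
        i = int(np.argmin(d))  # argmin returns the first (lower-λ) minimum
        if d[i] > tol:
            raise ValueError(
                f"no sampled band within {tol} nm of {nm} nm "
                f"(nearest is {self.wavelengths[i]:g} nm)"
            )
        return i

    def plane(self, nm: float, tol: float = 5.0) -> np.ndarray:
        return self.data[self.band_index(nm, tol)]


@dataclass(frozen=True)
class BandWindow:
    """An inclusive wavelength window [lo, hi] in nm."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lo) and math.isfinite(self.hi)):
            raise ValueError("band limits must be finite")
        if self.lo > self.hi:
            raise ValueError(f"band lo ({self.lo}) exceeds hi ({self.hi})")

    def indices(self, wavelengths: np.ndarray) -> np.ndarray:
        """Indices of sampled bands in the window, endpoints snapped to the
        nearest sampled wavelengths (inclusive)."""
        wavelengths = np.asarray(wavelengths, dtype=float)
        if self.lo < wavelengths[0] or self.hi > wavelengths[-1]:
            raise ValueError(
                f"band {self.lo}-{self.hi} nm outside sampled range "
                f"{wavelengths[0]:g}-{wavelengths[-1]:g} nm"
            )
        i_lo = int(np.argmin(np.abs(wavelengths - self.lo)))
        i_hi = int(np.argmin(np.abs(wavelengths - self.hi)))
        return np.arange(i_lo, i_hi + 1)


@dataclass
class ScalarImage:
    """A 2-D map with a units tag and an optional invalid-pixel mask."""

    data: np.ndarray
    units: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ScalarImage data must be 2-D")
        if self.mask is None:
            self.mask = ~np.isfinite(self.data)
        else:
            self.mask = np.asarray(self.mask, dtype=bool) | ~np.isfinite(self.data)
        if self.mask.shape != self.data.shape:
            raise DimensionError("mask shape differs from data shape")

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask


@dataclass
class PigmentMaps:
    """Per-pixel pigment absorption amplitudes from derivative spectroscopy.

    ``chla``/``chlf`` are raw fourth-derivative band amplitudes (attenuation
    proxies, arbitrary units); ``chlf_rel`` is the 0-1 scaled relative
    chlorophyll-f abundance map.
    """

    chla: ScalarImage
    chlf: ScalarImage
    chlf_rel: ScalarImage

    def __post_init__(self) -> None:
        v = self.chlf_rel.data[self.chlf_rel.valid]
        if v.size and (v.min() < 0 or v.max() > 1 + 1e-12):
            raise ValueError("chlf_rel values must lie in [0, 1]")


@dataclass
class RGBFrame:
    """A three-channel image, optionally timestamped (optode frames).

    ``t`` is minutes since experiment start; ``light`` is ``nir_on`` or
    ``dark`` for optode frames, ``None`` for display composites.
    ``scale`` records per-channel rescaling factors applied by composites.
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    t: float | None = None
    light: Literal["nir_on", "dark"] | None = None
    scale: dict | None = None

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        self.blue = np.asarray(self.blue, dtype=float)
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise DimensionError("RGB channels must share a shape")
        if self.red.ndim != 2:
            raise ValueError("channels must be 2-D")
        if self.t is not None and not math.isfinite(self.t):
            raise ValueError("timestamp must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    def stack(self) -> np.ndarray:
        """(H, W, 3) channel-last array."""
        return np.stack([self.red, self.green, self.blue], axis=-1)


@dataclass
class RatioImage:
    """Pixelwise red/green ratio R of an optode frame."""

    data: np.ndarray
    mask: np.ndarray
    t: float | None = None
    light: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise DimensionError("mask shape differs from data shape")


@dataclass
class DeltaRatioImage:
    """ΔR = R_dark − R, referenced to the dark-anoxic ratio image."""

    data: np.ndarray
    mask: np.ndarray
    reference_t: float | None = None
    t: float | None = None
    light: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise DimensionError("mask shape differs from data shape")


@dataclass
class CalibrationModel:
    """Exponential-saturation optode calibration ΔR(C) = a·(1 − e^(−b·C)).

    ``a`` is the anoxic-reference asymptote (dimensionless ratio units);
    ``b`` the quenching rate constant per % air saturation. The model is
    strictly increasing and saturating, with ΔR(0) = 0 by construction.
    """

    a: float
    b: float
    rss: float
    n: int

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"calibration requires a, b > 0 (got a={self.a}, b={self.b})")

    def predict(self, c):
        """ΔR at O2 concentration ``c`` (% air saturation)."""
        return self.a * (1.0 - np.exp(-self.b * np.asarray(c, dtype=float)))


@dataclass
class O2Image:
    """Calibrated O2 image in % air saturation."""

    data: np.ndarray
    mask: np.ndarray
    t: float | None = None
    light: str | None = None
    clamped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise DimensionError("mask shape differs from data shape")
        if self.clamped is None:
            self.clamped = np.zeros_like(self.mask)


@dataclass(frozen=True)
class LightEvent:
    """An actinic-light transition at time ``t`` minutes."""

    t: float
    kind: Literal["light_on", "light_off"]

    def __post_init__(self) -> None:
        if self.kind not in ("light_on", "light_off"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class O2Series:
    """A time-ordered sequence of calibrated O2 images plus light events."""

    frames: list[O2Image]
    events: list[LightEvent]

    def __post_init__(self) -> None:
        ts = [f.t for f in self.frames]
        if any(t is None for t in ts):
            raise ValueError("all frames in a series need timestamps")
        if np.any(np.diff(ts) <= 0):
            raise ValueError("frame timestamps must be strictly increasing")
        for ev in self.events:
            if not (ts[0] <= ev.t <= ts[-1]):
                raise ValueError(
                    f"event {ev.kind} at t={ev.t} outside frame range [{ts[0]}, {ts[-1]}]"
                )

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t for f in self.frames], dtype=float)

    def events_of(self, kind: str) -> list[LightEvent]:
        return [e for e in self.events if e.kind == kind]


@dataclass
class RateMaps:
    """Co-registered dark-respiration, net and gross photosynthesis maps.

    Rates are d[O2]/dt in µmol O2 L⁻¹ min⁻¹ — consumption is negative.
    ``p_gross = p_net + |r_dark|`` pixelwise by construction.
    """

    r_dark: ScalarImage
    p_net: ScalarImage
    p_gross: ScalarImage

    def __post_init__(self) -> None:
        if not (self.r_dark.data.shape == self.p_net.data.shape == self.p_gross.data.shape):
            raise DimensionError("rate maps must be co-registered")


#: unit chain for the areal scale-up, kept exactly as the printed arithmetic:
#: µmol L⁻¹ min⁻¹ × (porosity) × (thickness cm) × 10⁻⁶ × 10⁴ × 60
#: = mmol O2 m⁻² h⁻¹ (µmol cm⁻³ ≡ µmol per mL of pore water; 10⁻⁶ µmol→mol
#: per the L↔1000 cm³ bridge, 10⁴ cm²→m², 60 min→h, net mol→mmol ×10³).
AREAL_UNIT_CHAIN = 1e-6 * 1e4 * 60.0


@dataclass
class ArealRate:
    """Areal O2 production scaled up from a volumetric rate.

    value (mmol O2 m⁻² h⁻¹) = volumetric_rate (µmol O2 L⁻¹ min⁻¹)
    × porosity × thickness_cm × 10⁻⁶ × 10⁴ × 60.
    """

    value: float
    porosity: float
    thickness_cm: float
    volumetric_rate: float

    def __post_init__(self) -> None:
        expected = self.volumetric_rate * self.porosity * self.thickness_cm * AREAL_UNIT_CHAIN
        if not math.isclose(self.value, expected, rel_tol=1e-12, abs_tol=1e-15):
            raise ValueError("ArealRate value inconsistent with its unit chain")
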