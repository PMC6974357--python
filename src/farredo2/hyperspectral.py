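"""Hyperspectral reflectance processing and pigment absorption mapping.

The pipeline converts raw hyperspectral stacks of rock cross-sections into
calibrated % reflectance (dark correction, normalization against a calibrated
reflectance standard), then localizes narrow pigment absorption bands with
fourth-derivative spectroscopy. A smooth scattering baseline contributes
(locally) a low-degree polynomial to each reflectance spectrum, which the
fourth derivative suppresses, while narrow absorption dips — chlorophyll a
around 670–680 nm and the far-red chlorophyll f band around 718–722 nm —
survive as localized derivative features. Band-amplitude maps of those
features give per-pixel attenuation proxies that, scaled 0–1, serve as
relative pigment abundance maps for false-color overlays on the structural
RGB composite.

Sign convention: for an absorption dip (a negative Gaussian on the
reflectance baseline) the fourth derivative is negative at the dip center
with positive flanking lobes. Band amplitudes are therefore taken from the
*negated* fourth derivative, whose maximum sits at the dip center and scales
linearly with dip depth; amplitudes are floored at 0 so "extent of light
attenuation" is nonnegative.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import savgol_filter

from .types import (
    BandWindow,
    DimensionError,
    PigmentMaps,
    RGBFrame,
    ScalarImage,
    SpectralCube,
)

__all__ = [
    "dark_correct",
    "to_reflectance",
    "rgb_composite",
    "spectral_fourth_derivative",
    "band_amplitude_map",
    "normalize_abundance",
    "pigment_maps",
    "pigment_overlay",
    "extract_roi_spectrum",
    "emission_band_map",
    "CHLA_BAND",
    "CHLF_BAND",
]

#: In-vivo absorption windows used for the band maps (nm).
CHLA_BAND = BandWindow(670.0, 680.0)
CHLF_BAND = BandWindow(718.0, 722.0)


def _check_aligned(a: SpectralCube, b: SpectralCube) -> None:
    if a.data.shape != b.data.shape:
        raise DimensionError(f"cube shapes differ: {a.data.shape} vs {b.data.shape}")
    if not np.array_equal(a.wavelengths, b.wavelengths):
        raise DimensionError("cube wavelength vectors differ")


def dark_correct(raw: SpectralCube, dark: SpectralCube) -> SpectralCube:
    """Subtract the dark (shutter-closed) stack, clipping at zero counts."""
    _check_aligned(raw, dark)
    out = np.clip(raw.data - dark.data, 0.0, None)
    return SpectralCube(raw.wavelengths, out, kind="dark_corrected")


def to_reflectance(
    sample: SpectralCube,
    standard: SpectralCube,
    standard_pct: float = 20.0,
) -> SpectralCube:
    """Normalize a dark-corrected stack to % reflectance.

    The reflectance-standard stack is reduced to a single per-wavelength
    reference spectrum by spatial averaging (the standard is imaged
    separately, so per-pixel registration is meaningless), then

        reflectance(λ, x, y) = standard_pct × sample(λ, x, y) / standard_ref(λ)

    Wavelengths where the reference is zero are masked (NaN) with a warning.
    """
    if not np.array_equal(sample.wavelengths, standard.wavelengths):
        raise DimensionError("sample and standard wavelength vectors differ")
    ref = standard.data.reshape(standard.n_bands, -1).mean(axis=1)
    bad = ref <= 0
    if bad.any():
        warnings.warn(
            f"reflectance standard has zero signal at {int(bad.sum())} band(s); masked",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = standard_pct * sample.data / ref[:, None, None]
    out[bad] = np.nan
    return SpectralCube(sample.wavelengths, out, kind="reflectance")


def rgb_composite(
    cube: SpectralCube,
    r: float = 650.0,
    g: float = 550.0,
    b: float = 450.0,
    tol: float = 5.0,
) -> RGBFrame:
    """'True color' composite from three reflectance bands.

    Each channel is the nearest sampled plane to the requested wavelength
    (lower wavelength wins exact ties), independently rescaled to [0, 1];
    the scale factors are recorded on the frame.
    """
    if cube.kind != "reflectance":
        raise ValueError("rgb_composite expects a reflectance cube")
    channels, scale = [], {}
    for name, nm in (("red", r), ("green", g), ("blue", b)):
        plane = cube.plane(nm, tol=tol)
        hi = np.nanmax(plane)
        factor = 1.0 / hi if hi > 0 else 1.0
        channels.append(np.clip(plane * factor, 0.0, 1.0))
        scale[name] = {"wavelength_nm": float(cube.wavelengths[cube.band_index(nm, tol)]),
                       "factor": float(factor)}
    return RGBFrame(*channels, scale=scale)


def spectral_fourth_derivative(
    cube: SpectralCube,
    window: int = 25,
    polyorder: int = 5,
) -> SpectralCube:
    """Per-pixel fourth derivative of the spectra by Savitzky–Golay filtering.

    The filter fits a local polynomial of ``polyorder`` over ``window`` bands
    and differentiates it analytically, so any spectrum that is globally a
    polynomial of degree ≤ 3 is annihilated exactly — the property that makes
    derivative spectroscopy baseline-insensitive. Edge bands (half a window
    on each side) have no centered fit and are masked (NaN).

    Requires a (near-)uniform wavelength grid; the mean spacing is used.
    """
    if polyorder < 4:
        raise ValueError("polyorder must be ≥ 4 to carry a fourth derivative")
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and larger than polyorder")
    if cube.n_bands < window:
        raise ValueError(f"need at least {window} bands, have {cube.n_bands}")
    spacing = np.diff(cube.wavelengths)
    delta = float(spacing.mean())
    if np.ptp(spacing) > 0.01 * delta:
        raise ValueError("fourth derivative requires a uniform wavelength grid")
    deriv = savgol_filter(
        cube.data, window_length=window, polyorder=polyorder, deriv=4,
        delta=delta, axis=0, mode="interp",
    )
    half = window // 2
    deriv[:half] = np.nan
    deriv[-half:] = np.nan
    return SpectralCube(cube.wavelengths, deriv, kind="derivative")


def band_amplitude_map(
    deriv: SpectralCube,
    band: BandWindow,
    stat: str = "max",
) -> ScalarImage:
    """Attenuation amplitude of an absorption band from the 4th derivative.

    Amplitude = per-pixel maximum of the *negated* fourth derivative over the
    band (endpoints snapped to sampled wavelengths, inclusive), floored at 0.
    An absorption dip has a negative 4th-derivative trough at its center, so
    the negated maximum peaks at the dip center and is linear in dip depth.
    ``stat='mean'`` averages the negated derivative instead (floored at 0).
    """
    if deriv.kind != "derivative":
        raise ValueError("band_amplitude_map expects a derivative cube")
    idx = band.indices(deriv.wavelengths)
    sub = -deriv.data[idx]
    if np.all(np.isnan(sub)):
        raise ValueError(
            f"band {band.lo}-{band.hi} nm falls entirely in the masked filter edge"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns → NaN
        if stat == "max":
            amp = np.nanmax(sub, axis=0)
        elif stat == "mean":
            amp = np.nanmean(sub, axis=0)
        else:
            raise ValueError(f"unknown band statistic {stat!r}")
    amp = np.where(np.isnan(amp), np.nan, np.clip(amp, 0.0, None))
    return ScalarImage(amp, units="attenuation (a.u.)")


def normalize_abundance(img: ScalarImage, clip_pct: float = 99.5) -> ScalarImage:
    """Rescale a nonnegative amplitude map linearly to a 0–1 relative scale.

    The map is scaled so the ``clip_pct`` percentile maps to 1; values above
    it saturate at 1 (guards against hot pixels). An all-zero map stays zero.
    """
    v = img.data[img.valid]
    if v.size and v.min() < 0:
        raise ValueError("normalize_abundance expects a nonnegative map")
    top = np.percentile(v, clip_pct) if v.size else 0.0
    if top <= 0:
        out = np.zeros_like(img.data)
        out[img.mask] = np.nan
        return ScalarImage(out, units="relative abundance (0-1)", mask=img.mask.copy())
    out = np.clip(img.data / top, 0.0, 1.0)
    return ScalarImage(out, units="relative abundance (0-1)", mask=img.mask.copy())


def pigment_maps(
    reflectance: SpectralCube,
    chla_band: BandWindow = CHLA_BAND,
    chlf_band: BandWindow = CHLF_BAND,
    window: int = 25,
    polyorder: int = 5,
    clip_pct: float = 99.5,
) -> PigmentMaps:
    """Full derivative-spectroscopy pass: reflectance cube → pigment maps."""
    deriv = spectral_fourth_derivative(reflectance, window=window, polyorder=polyorder)
    chla = band_amplitude_map(deriv, chla_band)
    chlf = band_amplitude_map(deriv, chlf_band)
    return PigmentMaps(chla=chla, chlf=chlf, chlf_rel=normalize_abundance(chlf, clip_pct))


def pigment_overlay(
    rgb: RGBFrame,
    maps: PigmentMaps,
    chla_thresh: float,
    chlf_thresh: float,
    mode: str = "binary",
    cmap: str = "inferno",
) -> RGBFrame:
    """False-color pigment overlay on the structural composite.

    ``binary`` mode paints pixels whose chlorophyll-a amplitude exceeds
    ``chla_thresh`` green and those whose chlorophyll-f amplitude exceeds
    ``chlf_thresh`` red; chlorophyll f takes precedence where both exceed
    (far-red patches sit inside a chl-a-rich matrix and must stay visible).
    ``continuous`` mode blends a colormapped 0–1 relative chl-f abundance
    over the composite wherever it exceeds ``chlf_thresh``.
    """
    if maps.chla.data.shape != rgb.shape or maps.chlf.data.shape != rgb.shape:
        raise DimensionError("overlay maps are not co-registered with the composite")
    out = rgb.stack().copy()
    if mode == "binary":
        green = np.nan_to_num(maps.chla.data) > chla_thresh
        red = np.nan_to_num(maps.chlf.data) > chlf_thresh
        green &= ~red  # chl f precedence
        out[green] = (0.0, 1.0, 0.0)
        out[red] = (1.0, 0.0, 0.0)
    elif mode == "continuous":
        import matplotlib

        rel = np.nan_to_num(maps.chlf_rel.data)
        sel = rel > chlf_thresh
        colors = matplotlib.colormaps[cmap](rel)[..., :3]
        out[sel] = colors[sel]
    else:
        raise ValueError(f"unknown overlay mode {mode!r}")
    return RGBFrame(out[..., 0], out[..., 1], out[..., 2])


def extract_roi_spectrum(cube: SpectralCube, roi: np.ndarray):
    """Mean ± SD spectrum over a region of interest.

    ``roi`` is a boolean mask of the cube's image shape. Returns
    ``(wavelengths, mean, sd)``; SD is the population SD over ROI pixels.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != cube.image_shape:
        raise DimensionError("ROI mask shape differs from cube image shape")
    if not roi.any():
        raise ValueError("ROI is empty")
    px = cube.data[:, roi]  # (bands, n_pixels)
    return cube.wavelengths.copy(), px.mean(axis=1), px.std(axis=1, ddof=0)


def emission_band_map(
    fluor: SpectralCube,
    bands: list[tuple[BandWindow, str]],
) -> RGBFrame:
    """False-color composite of fluorescence emission bands.

    Each ``(window, channel)`` pair contributes the per-pixel mean emission
    intensity within the window to the named channel (``red``/``green``/
    ``blue``), independently normalized to [0, 1]. Used to co-display e.g.
    phycobiliprotein (650–660 nm), chlorophyll a (690–700 nm) and
    chlorophyll f (740–750 nm) emission from confocal stacks.
    """
    if fluor.kind != "fluorescence":
        raise ValueError("emission_band_map expects a fluorescence cube")
    shape = fluor.image_shape
    channels = {"red": np.zeros(shape), "green": np.zeros(shape), "blue": np.zeros(shape)}
    for window, channel in bands:
        if channel not in channels:
            raise ValueError(f"unknown channel {channel!r}")
        idx = window.indices(fluor.wavelengths)
        img = fluor.data[idx].mean(axis=0)
        hi = np.nanmax(img)
        channels[channel] = np.maximum(channels[channel], img / hi if hi > 0 else img)
    return RGBFrame(channels["red"], channels["green"], channels["blue"])
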