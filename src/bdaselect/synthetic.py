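"""Synthetic NIR-like spectra with known informative wavelengths.

The generator follows a Beer-Lambert-style linear mixing model: each latent
chemical component contributes a smooth Gaussian absorption band, a sample's
spectrum is the concentration-weighted sum of those bands plus additive
instrument noise, and the target property is a linear combination of the
concentrations of a designated *informative* subset of components plus
measurement noise. Because the informative bands are known, selection
quality is directly measurable: a good wavelength selector should
concentrate its "1" bits inside the informative bands.

The default specification mirrors a typical benchtop calibration study:
60 samples on a 900-1700 nm grid at 2 nm (401 channels), four overlapping
bands of which two carry the target signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectraDataset, WavelengthMask, make_wavelength_grid

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "informative_channel_set"]


@dataclass
class SyntheticSpec:
    """Parameters of the linear-mixing spectra generator.

    Defaults give 60 samples x 401 channels with 4 Gaussian bands, 2 of
    which determine the target. Concentrations are drawn uniform on
    [0.2, 1.0]; absorbance noise (0.005 AU) is small relative to unit band
    amplitudes, as for a well-maintained NIR instrument, and target noise
    (0.05) is moderate relative to the target's spread (~0.3).
    """

    n_samples: int = 60
    grid: tuple[float, float, float] = (900.0, 1700.0, 2.0)
    n_components: int = 4
    band_centers_nm: tuple[float, ...] = (1050.0, 1220.0, 1420.0, 1600.0)
    band_widths_nm: tuple[float, ...] = (30.0, 45.0, 35.0, 50.0)
    informative_components: tuple[int, ...] = (0, 2)
    coefficients: tuple[float, ...] = (1.0, 0.6)
    noise_sd_absorbance: float = 0.005
    noise_sd_target: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if len(self.band_centers_nm) != self.n_components:
            raise ValueError("one band center per component required")
        if len(self.band_widths_nm) != self.n_components:
            raise ValueError("one band width per component required")
        if any(w <= 0 for w in self.band_widths_nm):
            raise ValueError("band widths must be positive")
        if not self.informative_components:
            raise ValueError("informative_components must be non-empty")
        if len(self.coefficients) != len(self.informative_components):
            raise ValueError("one coefficient per informative component required")
        if self.noise_sd_absorbance < 0 or self.noise_sd_target < 0:
            raise ValueError("noise standard deviations must be non-negative")
        start, stop, _ = self.grid
        for c in self.band_centers_nm:
            if not (start <= c <= stop):
                raise ValueError(f"band center {c} nm outside grid [{start}, {stop}]")


@dataclass
class GroundTruth:
    """What the generator knows and a selector should recover."""

    informative_mask: WavelengthMask
    concentrations: np.ndarray  # (n_samples, n_components)
    informative_centers_nm: np.ndarray
    informative_widths_nm: np.ndarray

    def __post_init__(self) -> None:
        if self.informative_mask.n_selected < 1:
            raise ValueError("informative mask must select at least one channel")


def _band_profiles(spec: SyntheticSpec, wavelengths: np.ndarray) -> np.ndarray:
    """Unit-amplitude Gaussian band per component, shape (n_components, n_channels)."""
    centers = np.asarray(spec.band_centers_nm)[:, None]
    widths = np.asarray(spec.band_widths_nm)[:, None]
    return np.exp(-0.5 * ((wavelengths[None, :] - centers) / widths) ** 2)


def generate(spec: SyntheticSpec) -> tuple[SpectraDataset, GroundTruth]:
    """Draw one dataset from the mixing model; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    wavelengths = make_wavelength_grid(*spec.grid)
    profiles = _band_profiles(spec, wavelengths)

    conc = rng.uniform(0.2, 1.0, size=(spec.n_samples, spec.n_components))
    absorbance = conc @ profiles
    if spec.noise_sd_absorbance > 0:
        absorbance = absorbance + rng.normal(
            0.0, spec.noise_sd_absorbance, size=absorbance.shape
        )

    coef = np.asarray(spec.coefficients, dtype=float)
    target = conc[:, list(spec.informative_components)] @ coef
    if spec.noise_sd_target > 0:
        target = target + rng.normal(0.0, spec.noise_sd_target, size=target.shape)

    dataset = SpectraDataset(
        absorbance=absorbance, wavelengths_nm=wavelengths, target=target
    )
    centers = np.asarray(spec.band_centers_nm)[list(spec.informative_components)]
    widths = np.asarray(spec.band_widths_nm)[list(spec.informative_components)]
    # default informative window: +/- 1 band width around each informative center
    bits = np.zeros(wavelengths.size, dtype=np.int8)
    for center, width in zip(centers, widths):
        bits |= (np.abs(wavelengths - center) <= width + 1e-12).astype(np.int8)
    truth = GroundTruth(
        informative_mask=WavelengthMask(bits),
        concentrations=conc,
        informative_centers_nm=centers,
        informative_widths_nm=widths,
    )
    return dataset, truth


def informative_channel_set(
    truth: GroundTruth,
    band_halfwidth_multiplier: float,
    wavelengths_nm: np.ndarray,
) -> WavelengthMask:
    """Channels within ``multiplier * width`` of any informative band center."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    bits = np.zeros(wl.size, dtype=np.int8)
    for center, width in zip(
        truth.informative_centers_nm, truth.informative_widths_nm
    ):
        half = band_halfwidth_multiplier * width
        bits |= (np.abs(wl - center) <= half + 1e-12).astype(np.int8)
    return WavelengthMask(bits)
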