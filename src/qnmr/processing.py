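"""Region integration, noise estimation and baseline correction.

Areas are trapezoidal integrals over the ppm axis (intensity·ppm units);
only area ratios are consumed downstream, so the axis-unit choice cancels.
S/N follows the spectrometer-software convention: peak height divided by
twice the detrended RMS noise of a signal-free region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, QnmrError
from .spectral_model import AcquisitionParams, Analyte, Spectrum

__all__ = [
    "IntegrationRegion",
    "IntegralResult",
    "DEFAULT_NOISE_REGION",
    "default_regions",
    "estimate_noise",
    "baseline_correct",
    "integrate_region",
    "area_ratio",
]


@dataclass(frozen=True)
class IntegrationRegion:
    """A ppm interval, inclusive of both endpoints."""

    label: str
    high_ppm: float
    low_ppm: float

    def __post_init__(self) -> None:
        if not self.high_ppm > self.low_ppm:
            raise InvalidParameterError(
                f"region {self.label!r}: high_ppm ({self.high_ppm}) must exceed "
                f"low_ppm ({self.low_ppm})"
            )

    @property
    def width(self) -> float:
        return self.high_ppm - self.low_ppm

    def overlaps(self, other: "IntegrationRegion") -> bool:
        return self.low_ppm <= other.high_ppm and other.low_ppm <= self.high_ppm

    def mask(self, spectrum: Spectrum) -> np.ndarray:
        m = (spectrum.ppm >= self.low_ppm) & (spectrum.ppm <= self.high_ppm)
        if not m.any():
            raise QnmrError(
                f"region {self.label!r} [{self.low_ppm}, {self.high_ppm}] ppm "
                "contains no points of the spectrum axis"
            )
        return m


@dataclass(frozen=True)
class IntegralResult:
    """Area, peak height and S/N for one region of one spectrum."""

    region: IntegrationRegion
    area: float
    peak_height: float
    snr: float


#: Default signal-free window for noise estimation (empty in the
#: tadalafil / 2,4-DNT system).
DEFAULT_NOISE_REGION = IntegrationRegion("noise", high_ppm=10.5, low_ppm=10.0)


def default_regions(
    analytes: tuple[Analyte, ...] | list[Analyte],
    params: AcquisitionParams | None = None,
    halfwidth_linewidths: float = 30.0,
) -> dict[str, IntegrationRegion]:
    """Analytical regions centred on every quantification site.

    Each region spans ±``halfwidth_linewidths`` total linewidths around the
    site, clipped at the midpoint to any neighbouring analytical site so
    regions never overlap.  Labels are the shift printed to 2 decimals
    (e.g. ``"5.91"``).
    """
    params = params or AcquisitionParams()
    hw = halfwidth_linewidths * params.total_linewidth / params.spectrometer_freq
    centers = sorted(
        (site.shift, f"{site.shift:.2f}")
        for analyte in analytes
        for site in analyte.quant_sites
    )
    regions: dict[str, IntegrationRegion] = {}
    for i, (shift, label) in enumerate(centers):
        low = shift - hw
        high = shift + hw
        if i > 0:
            low = max(low, (shift + centers[i - 1][0]) / 2.0)
        if i + 1 < len(centers):
            high = min(high, (shift + centers[i + 1][0]) / 2.0)
        regions[label] = IntegrationRegion(label, high_ppm=high, low_ppm=low)
    return regions


def estimate_noise(
    spectrum: Spectrum,
    noise_region: IntegrationRegion = DEFAULT_NOISE_REGION,
    exclude_regions: tuple[IntegrationRegion, ...] = (),
) -> float:
    """Detrended RMS noise of a signal-free region.

    A linear trend is removed before taking the RMS so a sloping baseline
    does not inflate the estimate.  Refuses a noise region that overlaps any
    of ``exclude_regions`` (the configured analytical windows).
    """
    for reg in exclude_regions:
        if noise_region.overlaps(reg):
            raise InvalidParameterError(
                f"noise region {noise_region.label!r} overlaps analytical "
                f"region {reg.label!r}; pick a signal-free window"
            )
    m = noise_region.mask(spectrum)
    if m.sum() < 16:
        raise InvalidParameterError(
            f"noise region {noise_region.label!r} holds only {int(m.sum())} points; "
            ">= 16 required"
        )
    x = spectrum.ppm[m]
    y = spectrum.intensity[m]
    coeffs = np.polyfit(x, y, 1)
    resid = y - np.polyval(coeffs, x)
    return float(np.sqrt(np.mean(resid**2)))


def baseline_correct(
    spectrum: Spectrum,
    anchor_regions: list[IntegrationRegion] | tuple[IntegrationRegion, ...],
    poly_degree: int = 1,
) -> Spectrum:
    """Subtract a polynomial fitted through signal-free anchor regions.

    The polynomial (degree ≤ 5) is least-squares fitted to the points of all
    anchor regions and subtracted from the whole trace.
    """
    if poly_degree < 0 or poly_degree > 5:
        raise InvalidParameterError("poly_degree must be between 0 and 5")
    masks = [reg.mask(spectrum) for reg in anchor_regions]
    if not masks:
        raise InvalidParameterError("at least one anchor region required")
    m = np.logical_or.reduce(masks)
    n_anchor = int(m.sum())
    if n_anchor < poly_degree + 1:
        raise InvalidParameterError(
            f"{n_anchor} anchor points cannot determine a degree-{poly_degree} baseline"
        )
    coeffs = np.polyfit(spectrum.ppm[m], spectrum.intensity[m], poly_degree)
    corrected = spectrum.intensity - np.polyval(coeffs, spectrum.ppm)
    return Spectrum(
        ppm=spectrum.ppm.copy(),
        intensity=corrected,
        params=spectrum.params,
        provenance=f"{spectrum.provenance}; baseline degree {poly_degree}",
    )


def integrate_region(
    spectrum: Spectrum,
    region: IntegrationRegion,
    noise_region: IntegrationRegion | None = DEFAULT_NOISE_REGION,
    snr_noise_multiplier: float = 2.0,
) -> IntegralResult:
    """Trapezoidal area, peak height and S/N of a region.

    S/N = peak height / (``snr_noise_multiplier`` × detrended RMS noise);
    the default multiplier of 2 is the common peak-to-peak convention.  With
    ``noise_region=None`` (or exactly zero noise and zero signal) the S/N is
    reported as 0, or infinity when signal is present but noise is zero.
    """
    if region.low_ppm < spectrum.ppm.min() or region.high_ppm > spectrum.ppm.max():
        raise QnmrError(
            f"region {region.label!r} [{region.low_ppm}, {region.high_ppm}] ppm "
            "extends outside the spectrum axis"
        )
    m = region.mask(spectrum)
    if m.sum() < 2:
        raise QnmrError(f"region {region.label!r} is effectively zero-width")
    x = spectrum.ppm[m]
    y = spectrum.intensity[m]
    # positive orientation regardless of the descending display axis
    area = float(np.trapezoid(y[::-1], x[::-1]))
    height = float(y.max())
    if noise_region is None:
        snr = 0.0
    else:
        noise = estimate_noise(spectrum, noise_region, exclude_regions=(region,))
        if noise == 0.0:
            snr = 0.0 if height == 0.0 else math.inf
        else:
            snr = height / (snr_noise_multiplier * noise)
    return IntegralResult(region=region, area=area, peak_height=height, snr=snr)


def area_ratio(sample: IntegralResult, standard: IntegralResult) -> float:
    """A_x / A_std with a division guard on the standard area."""
    if standard.area <= 0:
        raise QnmrError(
            f"standard region {standard.region.label!r} area is "
            f"{standard.area}; must be positive"
        )
    return sample.area / standard.area
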