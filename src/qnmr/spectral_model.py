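"""Domain types and closed-form physics for internal-standard qNMR.

The assay quantifies an analyte against a co-dissolved internal standard by
comparing integrated resonance areas.  The types here describe the two
compounds (``Analyte``), their assayable resonances (``ProtonSite``), the
acquisition settings of a 1D experiment (``AcquisitionParams``) and a
frequency-domain trace (``Spectrum``).  The helpers implement the small
pieces of NMR physics the pipeline relies on: first-order multiplet
splitting, longitudinal (T1) saturation of signal areas as a function of the
repetition delay, and ppm/Hz unit conversion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidParameterError, QnmrError

__all__ = [
    "ProtonSite",
    "Analyte",
    "AcquisitionParams",
    "Spectrum",
    "DelayCheck",
    "multiplet_lines",
    "saturation_factor",
    "check_repetition_delay",
    "ppm_to_hz",
    "hz_to_ppm",
]


@dataclass(frozen=True)
class ProtonSite:
    """One assayable resonance of a compound.

    Parameters
    ----------
    label : str
        Site name, e.g. ``"H-12"``.
    shift : float
        Chemical shift in ppm.
    n_protons : int
        Number of equivalent protons producing the signal (the ``N`` of the
        internal-standard ratio equation).
    j_values : tuple of float
        Scalar couplings in Hz; empty means a singlet.
    t1 : float or None
        Longitudinal relaxation time in seconds.  ``None`` means unmeasured;
        repetition-delay checks fail loudly on such a site.
    """

    label: str
    shift: float
    n_protons: int = 1
    j_values: tuple[float, ...] = ()
    t1: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "j_values", tuple(float(j) for j in self.j_values))
        if self.n_protons < 1:
            raise InvalidParameterError(
                f"site {self.label!r}: n_protons must be >= 1, got {self.n_protons}"
            )
        if self.t1 is not None and self.t1 <= 0:
            raise InvalidParameterError(
                f"site {self.label!r}: t1 must be positive, got {self.t1}"
            )
        if any(j <= 0 for j in self.j_values):
            raise InvalidParameterError(
                f"site {self.label!r}: all J values must be positive, got {self.j_values}"
            )


@dataclass(frozen=True)
class Analyte:
    """A compound taking part in the assay.

    ``purity`` is a mass fraction in (0, 1]; for the internal standard it is
    the certified purity P_std, for the analyte the (usually unknown, in
    simulation the true) purity P_x.  ``quant_labels`` flags which sites are
    used for quantification.
    """

    name: str
    mol_weight: float
    sites: tuple[ProtonSite, ...]
    purity: float = 1.0
    quant_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        object.__setattr__(self, "quant_labels", tuple(self.quant_labels))
        if self.mol_weight <= 0:
            raise InvalidParameterError(
                f"analyte {self.name!r}: mol_weight must be positive"
            )
        if not (0 < self.purity <= 1):
            raise InvalidParameterError(
                f"analyte {self.name!r}: purity must be in (0, 1], got {self.purity}"
            )
        if not self.sites:
            raise InvalidParameterError(f"analyte {self.name!r}: needs at least one site")
        labels = {s.label for s in self.sites}
        if not self.quant_labels:
            raise InvalidParameterError(
                f"analyte {self.name!r}: at least one site must be flagged for quantification"
            )
        missing = set(self.quant_labels) - labels
        if missing:
            raise InvalidParameterError(
                f"analyte {self.name!r}: quant_labels {sorted(missing)} not among sites"
            )

    def site(self, label: str) -> ProtonSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(f"analyte {self.name!r} has no site {label!r}")

    @property
    def quant_sites(self) -> tuple[ProtonSite, ...]:
        return tuple(self.site(lbl) for lbl in self.quant_labels)


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition settings of a 1D experiment.

    Defaults follow a 500.06 MHz proton experiment: 90° excitation, 32 scans,
    60 s repetition delay, 10330.578 Hz sweep, and 0.3 Hz exponential line
    broadening.  ``natural_linewidth`` is a simulator parameter: the intrinsic
    Lorentzian FWHM before apodization.  Exponential apodization of a
    Lorentzian line adds exactly its broadening factor to the FWHM, so the
    rendered linewidth is ``natural_linewidth + line_broadening``.
    """

    spectrometer_freq: float = 500.06  # MHz
    spectral_width: float = 10330.578  # Hz
    n_points: int = 65536
    repetition_delay: float = 60.0  # s
    line_broadening: float = 0.3  # Hz
    natural_linewidth: float = 1.0  # Hz
    n_scans: int = 32
    reference_shift: float = 2.49  # ppm, solvent reference (DMSO-d6)
    center_ppm: float = 6.0  # ppm at the middle of the spectral window

    def __post_init__(self) -> None:
        for name in (
            "spectrometer_freq",
            "spectral_width",
            "n_points",
            "line_broadening",
            "natural_linewidth",
            "n_scans",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.repetition_delay < 0:
            raise InvalidParameterError("repetition_delay must be >= 0")

    @property
    def total_linewidth(self) -> float:
        """Rendered Lorentzian FWHM in Hz."""
        return self.natural_linewidth + self.line_broadening

    @property
    def window_ppm(self) -> tuple[float, float]:
        """(low, high) bounds of the spectral window in ppm."""
        half = self.spectral_width / self.spectrometer_freq / 2.0
        return (self.center_ppm - half, self.center_ppm + half)

    def ppm_axis(self) -> np.ndarray:
        """Strictly decreasing ppm axis (NMR display convention)."""
        low, high = self.window_ppm
        return np.linspace(high, low, self.n_points)


@dataclass
class Spectrum:
    """A frequency-domain 1D trace: ppm axis, intensities, metadata."""

    ppm: np.ndarray
    intensity: np.ndarray
    params: AcquisitionParams = field(default_factory=AcquisitionParams)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise QnmrError("spectrum axes must be one-dimensional")
        if self.ppm.size != self.intensity.size or self.ppm.size < 2:
            raise QnmrError("spectrum axes must have equal length >= 2")
        if not np.all(np.diff(self.ppm) < 0):
            raise QnmrError("ppm axis must be strictly decreasing")
        if not np.all(np.isfinite(self.intensity)):
            raise QnmrError("spectrum intensities must be finite")

    def __len__(self) -> int:
        return int(self.ppm.size)


def multiplet_lines(site: ProtonSite) -> list[tuple[float, float]]:
    """First-order splitting pattern of a site.

    Each coupling J splits every line in two, displaced by ±J/2, so k
    couplings give 2^k lines of equal weight 1/2^k.  Offsets are in Hz,
    centred on zero (the pattern is symmetric about the site's shift); weights
    sum to one.  Lines are returned sorted by offset and are NOT merged when
    couplings coincide, so a triplet appears as its four degenerate lines.
    """
    if not site.j_values:
        return [(0.0, 1.0)]
    weight = 1.0 / 2 ** len(site.j_values)
    lines = [
        (sum(signs[i] * site.j_values[i] / 2.0 for i in range(len(signs))), weight)
        for signs in itertools.product((-1.0, +1.0), repeat=len(site.j_values))
    ]
    lines.sort(key=lambda t: t[0])
    return lines


def saturation_factor(t1: float, repetition_delay: float) -> float:
    """Steady-state recovery factor 1 − exp(−TR/T1) after a 90° pulse.

    With repetition delay TR between scans, longitudinal magnetization only
    recovers a fraction 1 − exp(−TR/T1) of its equilibrium value, and signal
    areas are scaled accordingly.  TR ≥ ~5×T1 makes the factor ≥ 0.993, i.e.
    areas quantitative to better than 1%.
    """
    if t1 is None or t1 <= 0:
        raise InvalidParameterError(f"t1 must be positive, got {t1}")
    if repetition_delay < 0:
        raise InvalidParameterError("repetition_delay must be >= 0")
    return 1.0 - math.exp(-repetition_delay / t1)


@dataclass(frozen=True)
class DelayCheck:
    """Outcome of a repetition-delay adequacy check."""

    passed: bool
    limiting_site: str
    max_t1: float
    required_delay: float
    repetition_delay: float
    factor: float


def check_repetition_delay(
    sites: Iterable[ProtonSite],
    repetition_delay: float,
    factor: float = 5.0,
) -> DelayCheck:
    """Check TR ≥ factor × max(T1) over the quantified sites.

    The slowest-relaxing site sets the requirement.  A site without a
    measured T1 cannot be certified and raises, naming the site — such sites
    must be excluded from quantification rather than silently trusted.
    """
    sites = list(sites)
    if not sites:
        raise InvalidParameterError("no sites given for repetition-delay check")
    for s in sites:
        if s.t1 is None:
            raise InvalidParameterError(
                f"T1 unknown for site {s.label!r}; cannot certify the repetition delay"
            )
    limiting = max(sites, key=lambda s: s.t1)
    required = factor * limiting.t1
    return DelayCheck(
        passed=repetition_delay >= required,
        limiting_site=limiting.label,
        max_t1=limiting.t1,
        required_delay=required,
        repetition_delay=repetition_delay,
        factor=factor,
    )


def ppm_to_hz(delta_ppm: float, freq_mhz: float) -> float:
    """Convert a shift offset in ppm to Hz at the given spectrometer frequency."""
    if freq_mhz <= 0:
        raise InvalidParameterError("spectrometer frequency must be positive")
    return delta_ppm * freq_mhz


def hz_to_ppm(offset_hz: float, freq_mhz: float) -> float:
    """Convert a frequency offset in Hz to ppm."""
    if freq_mhz <= 0:
        raise InvalidParameterError("spectrometer frequency must be positive")
    return offset_hz / freq_mhz
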