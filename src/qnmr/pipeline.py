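"""High-level assay pipelines tying simulation, processing and quantification.

``quantify_spectrum`` is the workhorse: integrate the analyte signal and
every internal-standard quantification signal, apply the internal-standard
ratio equation per signal, and summarize across signals.
"""

from __future__ import annotations

from dataclasses import dataclass

from .processing import (
    DEFAULT_NOISE_REGION,
    IntegralResult,
    IntegrationRegion,
    area_ratio,
    default_regions,
    integrate_region,
)
from .quantification import (
    GravimetricRecord,
    QuantResult,
    amount_per_dose,
    purity_internal_standard,
    summarize_signals,
)
from .spectral_model import Analyte, Spectrum
from .validation import DEFAULT_SNR_THRESHOLD, LoqResult, loq_gate

__all__ = ["QuantifyOutcome", "quantify_spectrum", "signal_area_ratios"]


@dataclass
class QuantifyOutcome:
    """Everything one quantification run produced."""

    result: QuantResult
    integrals: dict[str, IntegralResult]
    loq: dict[str, LoqResult]


def _resolve_regions(
    system: tuple[Analyte, Analyte],
    spectrum: Spectrum,
    regions: dict[str, IntegrationRegion] | None,
) -> dict[str, IntegrationRegion]:
    if regions is not None:
        return regions
    return default_regions(list(system), spectrum.params)


def signal_area_ratios(
    spectrum: Spectrum,
    system: tuple[Analyte, Analyte],
    regions: dict[str, IntegrationRegion] | None = None,
    noise_region: IntegrationRegion | None = DEFAULT_NOISE_REGION,
) -> tuple[dict[str, float], dict[str, IntegralResult]]:
    """A_x/A_std per internal-standard signal, keyed by signal label."""
    analyte, standard = system
    regions = _resolve_regions(system, spectrum, regions)
    x_label = f"{analyte.quant_sites[0].shift:.2f}"
    ax = integrate_region(spectrum, regions[x_label], noise_region)
    integrals = {x_label: ax}
    ratios = {}
    for site in standard.quant_sites:
        label = f"{site.shift:.2f}"
        astd = integrate_region(spectrum, regions[label], noise_region)
        integrals[label] = astd
        ratios[label] = area_ratio(ax, astd)
    return ratios, integrals


def quantify_spectrum(
    spectrum: Spectrum,
    system: tuple[Analyte, Analyte],
    grav: GravimetricRecord,
    mode: str = "purity",
    regions: dict[str, IntegrationRegion] | None = None,
    noise_region: IntegrationRegion | None = DEFAULT_NOISE_REGION,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
) -> QuantifyOutcome:
    """Quantify one spectrum against the internal standard.

    ``mode="purity"`` applies the bulk-drug purity equation (needs ``m_x``);
    ``mode="content"`` the per-tablet content equation (needs ``m_powder``
    and ``avg_tablet_weight``).  One value per standard signal, summarized
    by the unweighted mean and %RSD.  S/N gates are evaluated per signal but
    never block the computation — a failed gate is reported alongside.
    """
    if mode not in ("purity", "content"):
        raise ValueError(f"mode must be 'purity' or 'content', got {mode!r}")
    analyte, standard = system
    x_site = analyte.quant_sites[0]
    _, integrals = signal_area_ratios(spectrum, system, regions, noise_region)
    x_label = f"{x_site.shift:.2f}"
    ax = integrals[x_label]
    per_signal = {}
    for site in standard.quant_sites:
        label = f"{site.shift:.2f}"
        astd = integrals[label]
        if mode == "purity":
            per_signal[label] = purity_internal_standard(
                ax.area, astd.area, x_site, site, analyte, standard, grav
            )
        else:
            per_signal[label] = amount_per_dose(
                ax.area, astd.area, x_site, site, analyte, standard, grav
            )
    loq = {
        label: loq_gate(res.snr, snr_threshold)
        for label, res in integrals.items()
        if noise_region is not None
    }
    units = "% purity" if mode == "purity" else "mg/dose"
    return QuantifyOutcome(
        result=summarize_signals(per_signal, units=units),
        integrals=integrals,
        loq=loq,
    )
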