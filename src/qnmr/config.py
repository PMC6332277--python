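"""Assay configuration: a validated JSON-serializable description of the
whole run — compounds, acquisition, integration regions, thresholds and
simulation defaults.

Validation is eager: region labels must resolve to defined sites and every
region and site must sit inside the spectral window before any computation
starts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, Field, model_validator

from .datasets import tadalafil_dnt_system
from .errors import ConfigurationError
from .processing import IntegrationRegion, default_regions
from .spectral_model import AcquisitionParams, Analyte, ProtonSite
from .synthetic_data import DEFAULT_NOISE_SIGMA, DEFAULT_WEIGHING_CV
from .validation import DEFAULT_SNR_THRESHOLD

__all__ = ["AssayConfig", "SiteConfig", "AnalyteConfig", "RegionConfig"]


class SiteConfig(BaseModel):
    label: str
    shift: float
    n_protons: int = 1
    j_values: list[float] = Field(default_factory=list)
    t1: float | None = None

    def to_domain(self) -> ProtonSite:
        return ProtonSite(
            label=self.label,
            shift=self.shift,
            n_protons=self.n_protons,
            j_values=tuple(self.j_values),
            t1=self.t1,
        )


class AnalyteConfig(BaseModel):
    name: str
    mol_weight: float
    purity: float = 1.0
    quant_labels: list[str]
    sites: list[SiteConfig]

    def to_domain(self) -> Analyte:
        return Analyte(
            name=self.name,
            mol_weight=self.mol_weight,
            purity=self.purity,
            quant_labels=tuple(self.quant_labels),
            sites=tuple(s.to_domain() for s in self.sites),
        )


class AcquisitionConfig(BaseModel):
    spectrometer_freq: float = 500.06
    spectral_width: float = 10330.578
    n_points: int = 65536
    repetition_delay: float = 60.0
    line_broadening: float = 0.3
    natural_linewidth: float = 1.0
    n_scans: int = 32
    reference_shift: float = 2.49
    center_ppm: float = 6.0

    def to_domain(self) -> AcquisitionParams:
        return AcquisitionParams(**self.model_dump())


class RegionConfig(BaseModel):
    label: str
    high_ppm: float
    low_ppm: float

    def to_domain(self) -> IntegrationRegion:
        return IntegrationRegion(self.label, high_ppm=self.high_ppm, low_ppm=self.low_ppm)


class SimulationConfig(BaseModel):
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    weighing_cv: float = DEFAULT_WEIGHING_CV
    excipient_level: float = 0.0
    mass_pairs: list[tuple[float, float]] | None = None


class AssayConfig(BaseModel):
    """Top-level, validating assay configuration."""

    analyte: AnalyteConfig
    standard: AnalyteConfig
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    regions: list[RegionConfig] | None = None
    noise_region: RegionConfig = Field(
        default_factory=lambda: RegionConfig(label="noise", high_ppm=10.5, low_ppm=10.0)
    )
    snr_threshold: float = DEFAULT_SNR_THRESHOLD
    display_digits: int = 2
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    seed: int = 0

    @model_validator(mode="after")
    def _cross_validate(self) -> "AssayConfig":
        params = self.acquisition.to_domain()
        low, high = params.window_ppm
        for comp in (self.analyte, self.standard):
            comp.to_domain()  # site/purity invariants
            for site in comp.sites:
                if not (low <= site.shift <= high):
                    raise ConfigurationError(
                        f"site {site.label!r} at {site.shift} ppm outside the "
                        f"spectral window [{low:.2f}, {high:.2f}] ppm"
                    )
        site_labels = {f"{s.shift:.2f}" for c in (self.analyte, self.standard) for s in c.sites}
        if self.regions is not None:
            for reg in self.regions:
                reg.to_domain()
                if reg.label not in site_labels:
                    raise ConfigurationError(
                        f"region {reg.label!r} does not match any defined site shift"
                    )
                if reg.low_ppm < low or reg.high_ppm > high:
                    raise ConfigurationError(
                        f"region {reg.label!r} outside the spectral window"
                    )
        return self

    # -- domain accessors ---------------------------------------------------
    def system(self) -> tuple[Analyte, Analyte]:
        return self.analyte.to_domain(), self.standard.to_domain()

    def params(self) -> AcquisitionParams:
        return self.acquisition.to_domain()

    def integration_regions(self) -> dict[str, IntegrationRegion]:
        if self.regions is None:
            return default_regions(list(self.system()), self.params())
        return {r.label: r.to_domain() for r in self.regions}

    def noise_region_domain(self) -> IntegrationRegion:
        return self.noise_region.to_domain()

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    # -- construction -------------------------------------------------------
    @classmethod
    def default(cls) -> "AssayConfig":
        """The packaged tadalafil / 2,4-DNT assay."""
        analyte, standard = tadalafil_dnt_system()

        def _cfg(a: Analyte) -> AnalyteConfig:
            return AnalyteConfig(
                name=a.name,
                mol_weight=a.mol_weight,
                purity=a.purity,
                quant_labels=list(a.quant_labels),
                sites=[
                    SiteConfig(
                        label=s.label,
                        shift=s.shift,
                        n_protons=s.n_protons,
                        j_values=list(s.j_values),
                        t1=s.t1,
                    )
                    for s in a.sites
                ],
            )

        return cls(analyte=_cfg(analyte), standard=_cfg(standard))

    @classmethod
    def from_json(cls, path: str | Path) -> "AssayConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))
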