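"""Seeded synthetic 1D spectra with the statistical structure of the assay.

The forward model renders each proton site as a first-order Lorentzian
multiplet in the frequency domain.  The total area of a site (in
intensity·ppm units) is

    scale = (mass_mg / mol_weight) · purity · n_protons
            · saturation_factor(T1, TR) · n_scans

i.e. proportional to the molar amount of protons, attenuated by incomplete
T1 recovery.  The solvent volume is not modelled: it cancels in every ratio
the pipeline consumes.  On top of the signal the generator can add a
polynomial baseline, broad Gaussian excipient humps (tablet matrix), and
i.i.d. Gaussian noise per point.  Everything is deterministic given the
mixture seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InvalidParameterError
from .spectral_model import (
    AcquisitionParams,
    Analyte,
    ProtonSite,
    Spectrum,
    multiplet_lines,
    saturation_factor,
)

__all__ = [
    "MixtureSpec",
    "DEFAULT_LINEARITY_MASS_PAIRS",
    "DEFAULT_NOISE_SIGMA",
    "DEFAULT_WEIGHING_CV",
    "site_scale",
    "synthesize_spectrum",
    "make_linearity_series",
    "make_tablet_spectrum",
    "simulate_replicates",
]

logger = logging.getLogger(__name__)

#: The six-level (m_std, m_x) linearity design in mg, spanning mass ratios
#: 0.47–3.88 analyte per mg of internal standard.
DEFAULT_LINEARITY_MASS_PAIRS: tuple[tuple[float, float], ...] = (
    (5.18, 2.41),
    (4.83, 3.45),
    (5.56, 5.14),
    (6.46, 11.72),
    (5.48, 14.56),
    (5.00, 19.40),
)

#: Per-point Gaussian noise (intensity units) giving the analyte singlet an
#: S/N of roughly 1200 at the 5 mg working scale, the order observed on the
#: instrument this generator emulates.
DEFAULT_NOISE_SIGMA: float = 0.084

#: Coefficient of variation of the gravimetric step (balance + transfer),
#: applied to the true dissolved mass while the recorded mass stays nominal.
DEFAULT_WEIGHING_CV: float = 0.002

# Broad tablet-excipient humps; chosen in the crowded sugar/polyol region so
# the 5.91 and 7.8-8.8 ppm analytical windows stay clean.
_EXCIPIENT_CENTERS: tuple[float, ...] = (3.25, 3.45, 3.70)
_EXCIPIENT_SIGMA_PPM: float = 0.12


@dataclass(frozen=True)
class MixtureSpec:
    """Recipe for one synthetic sample.

    ``components`` holds (compound, dissolved mass in mg) pairs.
    ``matrix_excipient_level`` scales the tablet-matrix humps (0 = bulk
    drug).  ``baseline_coeffs`` are polynomial coefficients in the ppm
    coordinate, highest power first (numpy convention).
    """

    components: tuple[tuple[Analyte, float], ...]
    noise_sigma: float = 0.0
    baseline_coeffs: tuple[float, ...] = ()
    matrix_excipient_level: float = 0.0
    excipient_centers: tuple[float, ...] = _EXCIPIENT_CENTERS
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "baseline_coeffs", tuple(self.baseline_coeffs))
        object.__setattr__(self, "excipient_centers", tuple(self.excipient_centers))
        for analyte, mass in self.components:
            if mass < 0:
                raise InvalidParameterError(
                    f"component {analyte.name!r}: mass must be >= 0, got {mass}"
                )
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be >= 0")
        if self.matrix_excipient_level < 0:
            raise InvalidParameterError("matrix_excipient_level must be >= 0")


def site_scale(
    analyte: Analyte, mass_mg: float, site: ProtonSite, params: AcquisitionParams
) -> float:
    """Closed-form total area of a site in intensity·ppm units.

    A site with unmeasured T1 is rendered fully relaxed (factor 1); such
    sites are never quantified, only displayed.
    """
    sat = 1.0 if site.t1 is None else saturation_factor(site.t1, params.repetition_delay)
    return (mass_mg / analyte.mol_weight) * analyte.purity * site.n_protons * sat * params.n_scans


def _render_site(
    ppm: np.ndarray,
    analyte: Analyte,
    mass_mg: float,
    site: ProtonSite,
    params: AcquisitionParams,
    out: np.ndarray,
) -> None:
    scale = site_scale(analyte, mass_mg, site, params)
    if scale == 0.0:
        return
    gamma_ppm = params.total_linewidth / params.spectrometer_freq  # FWHM
    half = gamma_ppm / 2.0
    for offset_hz, weight in multiplet_lines(site):
        x0 = site.shift + offset_hz / params.spectrometer_freq
        # unit-area Lorentzian on the ppm axis
        out += (scale * weight / np.pi) * half / ((ppm - x0) ** 2 + half**2)


def _analytical_windows(spec: MixtureSpec, params: AcquisitionParams) -> list[tuple[float, float]]:
    hw = 30.0 * params.total_linewidth / params.spectrometer_freq
    return [
        (site.shift - hw, site.shift + hw)
        for analyte, _ in spec.components
        for site in analyte.quant_sites
    ]


def synthesize_spectrum(
    spec: MixtureSpec, params: AcquisitionParams | None = None
) -> Spectrum:
    """Render a mixture recipe into a frequency-domain spectrum.

    Deterministic given (spec, params): same seed, same bits.  With zero
    noise and baseline, the numerically integrated area of a site's region
    matches :func:`site_scale` up to Lorentzian tail truncation outside the
    region (documented in the methods note).

    Raises
    ------
    ConfigurationError
        If any site of any component falls outside the spectral window.
    """
    params = params or AcquisitionParams()
    low, high = params.window_ppm
    for analyte, _mass in spec.components:
        for site in analyte.sites:
            if not (low <= site.shift <= high):
                raise ConfigurationError(
                    f"site {site.label!r} of {analyte.name!r} at {site.shift} ppm "
                    f"lies outside the spectral window [{low:.2f}, {high:.2f}] ppm"
                )

    ppm = params.ppm_axis()
    intensity = np.zeros_like(ppm)
    for analyte, mass in spec.components:
        for site in analyte.sites:
            _render_site(ppm, analyte, mass, site, params, intensity)

    if spec.matrix_excipient_level > 0:
        windows = _analytical_windows(spec, params)
        for center in spec.excipient_centers:
            for wlow, whigh in windows:
                if wlow <= center <= whigh:
                    logger.warning(
                        "excipient hump at %.2f ppm overlaps the analytical "
                        "window [%.3f, %.3f] ppm",
                        center,
                        wlow,
                        whigh,
                    )
            intensity += spec.matrix_excipient_level * np.exp(
                -0.5 * ((ppm - center) / _EXCIPIENT_SIGMA_PPM) ** 2
            )

    if spec.baseline_coeffs:
        intensity += np.polyval(spec.baseline_coeffs, ppm)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity + rng.normal(0.0, spec.noise_sigma, ppm.size)

    return Spectrum(
        ppm=ppm,
        intensity=intensity,
        params=params,
        provenance=f"simulated seed={spec.seed}",
    )


def _child_seed(seed: int, index: int) -> int:
    # deterministic, collision-resistant, and small enough for any RNG API
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] & 0x7FFFFFFF)


def make_linearity_series(
    system: tuple[Analyte, Analyte],
    mass_pairs: tuple[tuple[float, float], ...] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    params: AcquisitionParams | None = None,
) -> list[tuple[MixtureSpec, Spectrum]]:
    """One spectrum per (m_std, m_x) calibration level.

    ``system`` is the (analyte, internal standard) pair; the default mass
    pairs span analyte/standard mass ratios 0.47–3.88.
    """
    analyte, standard = system
    pairs = DEFAULT_LINEARITY_MASS_PAIRS if mass_pairs is None else tuple(mass_pairs)
    if not pairs:
        raise InvalidParameterError("mass_pairs must be non-empty")
    for m_std, m_x in pairs:
        if m_std < 0 or m_x < 0:
            raise InvalidParameterError(f"negative mass in pair ({m_std}, {m_x})")
    out = []
    for i, (m_std, m_x) in enumerate(pairs):
        spec = MixtureSpec(
            components=((analyte, m_x), (standard, m_std)),
            noise_sigma=noise_sigma,
            seed=_child_seed(seed, i),
        )
        out.append((spec, synthesize_spectrum(spec, params)))
    return out


def make_tablet_spectrum(
    system: tuple[Analyte, Analyte],
    tablet_content_mg: float = 5.0,
    powder_mass_mg: float = 100.0,
    avg_tablet_weight_mg: float = 100.0,
    is_mass_mg: float = 5.0,
    excipient_level: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    params: AcquisitionParams | None = None,
) -> tuple[MixtureSpec, Spectrum]:
    """Tablet-powder sample: drug + internal standard + excipient background.

    The dissolved analyte mass follows from the label claim: a powder
    aliquot of ``powder_mass_mg`` from tablets of average weight
    ``avg_tablet_weight_mg`` containing ``tablet_content_mg`` per tablet
    carries ``tablet_content_mg · powder_mass_mg / avg_tablet_weight_mg`` of
    drug.  With ``excipient_level`` 0 the result is identical to a bulk-drug
    mixture.
    """
    analyte, standard = system
    drug_mass = tablet_content_mg * powder_mass_mg / avg_tablet_weight_mg
    if powder_mass_mg < drug_mass:
        raise InvalidParameterError(
            "powder mass must be at least the drug-equivalent mass"
        )
    spec = MixtureSpec(
        components=((analyte, drug_mass), (standard, is_mass_mg)),
        noise_sigma=noise_sigma,
        matrix_excipient_level=excipient_level,
        seed=seed,
    )
    return spec, synthesize_spectrum(spec, params)


def simulate_replicates(
    system: tuple[Analyte, Analyte],
    masses_mg: tuple[float, float],
    n_replicates: int,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    weighing_cv: float = DEFAULT_WEIGHING_CV,
    seed: int = 0,
    params: AcquisitionParams | None = None,
) -> list[tuple[MixtureSpec, Spectrum]]:
    """Independent sample preparations at a nominal (m_x, m_std) design point.

    Each replicate perturbs the TRUE dissolved masses by a Gaussian factor of
    CV ``weighing_cv`` while the caller keeps computing with the nominal
    masses — emulating gravimetric error — and draws fresh spectral noise.
    The returned ``MixtureSpec`` records the true perturbed masses.
    """
    analyte, standard = system
    m_x, m_std = masses_mg
    out = []
    for i in range(n_replicates):
        # separate streams for the gravimetric and the spectral noise
        rng = np.random.default_rng(_child_seed(seed, 2 * i + 1))
        fx = 1.0 + rng.normal(0.0, weighing_cv)
        fs = 1.0 + rng.normal(0.0, weighing_cv)
        spec = MixtureSpec(
            components=((analyte, m_x * fx), (standard, m_std * fs)),
            noise_sigma=noise_sigma,
            seed=_child_seed(seed, 2 * i),
        )
        out.append((spec, synthesize_spectrum(spec, params)))
    return out
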