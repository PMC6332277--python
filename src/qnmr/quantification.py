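"""Internal-standard purity and content equations, plus the external-standard
HPLC arithmetic used for cross-method comparison.

The core relation of internal-standard qNMR: areas are proportional to molar
proton amounts, so the analyte purity follows from an area ratio and the
gravimetric bookkeeping,

    P_x = (A_x/A_std) · (N_std/N_x) · (M_x/M_std) · (m_std/m_x) · P_std · 100%

and the per-tablet content from the same ratio referenced to the powder
aliquot and average tablet weight T,

    m_x = (A_x/A_std) · (N_std/N_x) · (M_x/M_std) · (m_std/m_powder) · P_std · T.

The HPLC counterparts are plain external-standard ratios of already
integrated peak responses:

    P_x = (A_x/A_s) · (m_s/m_x) · P_s · 100%
    m_x = (A_x/A_s) · (m_s/m_powder) · P_s · T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import DivisionGuardError, InvalidParameterError
from .spectral_model import Analyte, ProtonSite

__all__ = [
    "GravimetricRecord",
    "QuantResult",
    "purity_internal_standard",
    "amount_per_dose",
    "purity_hplc",
    "amount_hplc",
    "summarize_signals",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GravimetricRecord:
    """Weighed masses and standard purities for one sample.

    All masses in mg.  ``m_x`` is the analyte mass (bulk-drug assay),
    ``m_powder`` the tablet-powder aliquot, ``m_s`` the external (HPLC)
    reference-standard mass, ``avg_tablet_weight`` the mean tablet weight T.
    ``p_std`` / ``p_s`` are the internal- and external-standard purities as
    fractions in (0, 1].
    """

    m_std: float | None = None
    m_x: float | None = None
    m_powder: float | None = None
    m_s: float | None = None
    p_std: float = 1.0
    p_s: float | None = None
    avg_tablet_weight: float | None = None

    def __post_init__(self) -> None:
        for name in ("m_std", "m_x", "m_powder", "m_s", "avg_tablet_weight"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DivisionGuardError(f"{name} must be positive, got {v}")
        if not (0 < self.p_std <= 1):
            raise InvalidParameterError(f"p_std must be in (0, 1], got {self.p_std}")
        if self.p_s is not None and not (0 < self.p_s <= 1):
            raise InvalidParameterError(f"p_s must be in (0, 1], got {self.p_s}")

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise InvalidParameterError(
                f"gravimetric record is missing required field(s): {', '.join(missing)}"
            )


def _ratio_core(
    ax: float,
    astd: float,
    x_site: ProtonSite,
    std_site: ProtonSite,
    x: Analyte,
    std: Analyte,
) -> float:
    if astd <= 0:
        raise DivisionGuardError(f"standard area must be positive, got {astd}")
    return (
        (ax / astd)
        * (std_site.n_protons / x_site.n_protons)
        * (x.mol_weight / std.mol_weight)
    )


def purity_internal_standard(
    ax: float,
    astd: float,
    x_site: ProtonSite,
    std_site: ProtonSite,
    x: Analyte,
    std: Analyte,
    grav: GravimetricRecord,
) -> float:
    """Analyte purity in % from one analyte/standard area pair."""
    grav.require("m_std", "m_x")
    value = (
        _ratio_core(ax, astd, x_site, std_site, x, std)
        * (grav.m_std / grav.m_x)
        * grav.p_std
        * 100.0
    )
    logger.info(
        "purity: Ax=%.6g Astd=%.6g N=%d/%d M=%.4g/%.4g m=%.4g/%.4g Pstd=%.4g -> %.4f%%",
        ax, astd, x_site.n_protons, std_site.n_protons, x.mol_weight,
        std.mol_weight, grav.m_std, grav.m_x, grav.p_std, value,
    )
    return value


def amount_per_dose(
    ax: float,
    astd: float,
    x_site: ProtonSite,
    std_site: ProtonSite,
    x: Analyte,
    std: Analyte,
    grav: GravimetricRecord,
) -> float:
    """Analyte content in mg per tablet from a tablet-powder sample."""
    grav.require("m_std", "m_powder", "avg_tablet_weight")
    value = (
        _ratio_core(ax, astd, x_site, std_site, x, std)
        * (grav.m_std / grav.m_powder)
        * grav.p_std
        * grav.avg_tablet_weight
    )
    logger.info(
        "content: Ax=%.6g Astd=%.6g m_std=%.4g m_powder=%.4g T=%.4g -> %.4f mg",
        ax, astd, grav.m_std, grav.m_powder, grav.avg_tablet_weight, value,
    )
    return value


def purity_hplc(ax_peak: float, as_peak: float, grav: GravimetricRecord) -> float:
    """External-standard purity in % from HPLC peak responses."""
    grav.require("m_s", "m_x", "p_s")
    if as_peak <= 0:
        raise DivisionGuardError(f"standard peak response must be positive, got {as_peak}")
    return (ax_peak / as_peak) * (grav.m_s / grav.m_x) * grav.p_s * 100.0


def amount_hplc(ax_peak: float, as_peak: float, grav: GravimetricRecord) -> float:
    """External-standard per-tablet content in mg from HPLC peak responses."""
    grav.require("m_s", "m_powder", "p_s", "avg_tablet_weight")
    if as_peak <= 0:
        raise DivisionGuardError(f"standard peak response must be positive, got {as_peak}")
    return (
        (ax_peak / as_peak)
        * (grav.m_s / grav.m_powder)
        * grav.p_s
        * grav.avg_tablet_weight
    )


@dataclass(frozen=True)
class QuantResult:
    """Per-signal values with their mean and %RSD.

    ``units`` is ``"% purity"`` or ``"mg/dose"``.  With a single signal the
    RSD is reported as 0 and ``n`` records the group size.
    """

    per_signal: dict[str, float]
    mean: float
    rsd_percent: float
    n: int
    units: str = "% purity"


def summarize_signals(per_signal: Mapping[str, float], units: str = "% purity") -> QuantResult:
    """Unweighted mean and %RSD across the standard's quantification signals."""
    if not per_signal:
        raise InvalidParameterError("no per-signal values to summarize")
    values = np.asarray(list(per_signal.values()), dtype=float)
    mean = float(values.mean())
    if values.size >= 2:
        if mean == 0:
            raise DivisionGuardError("mean of signal values is zero; RSD undefined")
        rsd = float(100.0 * values.std(ddof=1) / mean)
    else:
        rsd = 0.0
    return QuantResult(
        per_signal=dict(per_signal), mean=mean, rsd_percent=rsd,
        n=int(values.size), units=units,
    )
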