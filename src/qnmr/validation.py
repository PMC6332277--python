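"""Method-validation statistics: linearity, precision, recovery, LOQ gating.

Conventions, verified against the assay's published validation records:
%RSD uses the n−1 sample standard deviation over the arithmetic mean;
recovery is computed against the amount added, 100·(found − present)/added;
linearity is unweighted ordinary least squares of area ratio on mass ratio
with R² the squared Pearson correlation.  Reported tables round half-up to
2 decimals (4 for R²); full precision is kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InvalidParameterError, QnmrError

__all__ = [
    "LinearityResult",
    "RecoveryRecord",
    "LoqResult",
    "ValidationReport",
    "fit_linearity",
    "percent_rsd",
    "recovery_percent",
    "loq_gate",
    "validation_report",
    "round_display",
]

#: S/N below which a signal is considered unfit for 1%-uncertainty quantification.
DEFAULT_SNR_THRESHOLD = 150.0


def round_display(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding for report display (1.005 → 1.01)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    range_low: float
    range_high: float


@dataclass(frozen=True)
class RecoveryRecord:
    """One spiked-sample record; masses in mg."""

    in_tablets: float
    added: float
    found: float

    def __post_init__(self) -> None:
        if self.added <= 0:
            raise InvalidParameterError(f"added mass must be positive, got {self.added}")
        if self.found < 0:
            raise InvalidParameterError("found mass must be non-negative")

    @property
    def recovery_percent(self) -> float:
        return recovery_percent(self.in_tablets, self.added, self.found)


@dataclass(frozen=True)
class LoqResult:
    passed: bool
    snr: float
    threshold: float


def fit_linearity(points: Sequence[tuple[float, float]]) -> LinearityResult:
    """Unweighted OLS of area ratio (y) on mass ratio (x)."""
    if len(points) < 3:
        raise InvalidParameterError(f"need >= 3 points for a linearity fit, got {len(points)}")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise InvalidParameterError("degenerate linearity design: all mass ratios equal")
    res = stats.linregress(x, y)
    return LinearityResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
        range_low=float(x.min()),
        range_high=float(x.max()),
    )


def percent_rsd(values: Sequence[float]) -> float:
    """100 × sample standard deviation (n−1) / arithmetic mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InvalidParameterError(f"RSD needs >= 2 values, got {v.size}")
    mean = v.mean()
    if mean == 0:
        raise QnmrError("RSD undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def recovery_percent(in_tablets: float, added: float, found: float) -> float:
    """Spike recovery: 100 × (found − present) / added."""
    if added <= 0:
        raise InvalidParameterError(f"added mass must be positive, got {added}")
    return 100.0 * (found - in_tablets) / added


def loq_gate(snr: float, threshold: float = DEFAULT_SNR_THRESHOLD) -> LoqResult:
    """Pass iff S/N ≥ threshold (inclusive); carries both numbers for reporting."""
    if snr < 0:
        raise InvalidParameterError(f"S/N must be non-negative, got {snr}")
    return LoqResult(passed=snr >= threshold, snr=snr, threshold=threshold)


@dataclass(frozen=True)
class ReplicateSection:
    """A set of replicate values with their mean and %RSD."""

    values: tuple[float, ...]
    mean: float
    rsd_percent: float


def _section(values: Sequence[float]) -> ReplicateSection:
    v = tuple(float(x) for x in values)
    return ReplicateSection(
        values=v,
        mean=float(np.mean(v)),
        rsd_percent=percent_rsd(v) if len(v) >= 2 else 0.0,
    )


@dataclass
class ValidationReport:
    """Assembled validation battery, one entry per standard signal label."""

    linearity: dict[str, LinearityResult] = field(default_factory=dict)
    precision: dict[str, ReplicateSection] = field(default_factory=dict)
    repeatability: dict[str, ReplicateSection] = field(default_factory=dict)
    stability: dict[str, ReplicateSection] = field(default_factory=dict)
    recovery: dict[str, ReplicateSection] = field(default_factory=dict)
    loq: dict[str, LoqResult] = field(default_factory=dict)

    def to_dict(self, display: bool = False) -> dict:
        """Nested plain-python report; ``display=True`` applies table rounding."""
        r2 = (lambda x: round_display(x, 2)) if display else float
        r4 = (lambda x: round_display(x, 4)) if display else float
        out: dict = {}
        if self.linearity:
            out["linearity"] = {
                lbl: {
                    "slope": r4(fit.slope),
                    "intercept": r4(fit.intercept),
                    "r_squared": r4(fit.r_squared),
                    "n": fit.n,
                    "range": [fit.range_low, fit.range_high],
                }
                for lbl, fit in self.linearity.items()
            }
        for name in ("precision", "repeatability", "stability", "recovery"):
            sections: dict = getattr(self, name)
            if sections:
                out[name] = {
                    lbl: {
                        "values": [r2(v) for v in sec.values],
                        "mean": r2(sec.mean),
                        "rsd_percent": r2(sec.rsd_percent),
                    }
                    for lbl, sec in sections.items()
                }
        if self.loq:
            out["loq"] = {
                lbl: {"passed": g.passed, "snr": r2(g.snr), "threshold": g.threshold}
                for lbl, g in self.loq.items()
            }
        return out


def validation_report(
    linearity: Mapping[str, Sequence[tuple[float, float]]] | None = None,
    precision_sets: Mapping[str, Sequence[float]] | None = None,
    repeatability_sets: Mapping[str, Sequence[float]] | None = None,
    stability_sets: Mapping[str, Sequence[float]] | None = None,
    recovery_sets: Mapping[str, Sequence[float]] | None = None,
    loq_snrs: Mapping[str, float] | None = None,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
) -> ValidationReport:
    """Assemble the full battery from per-signal raw inputs.

    ``linearity`` maps signal label → (mass_ratio, area_ratio) points;
    the replicate sets map signal label → measured values (% or mg);
    ``recovery_sets`` take already-computed recovery percentages;
    ``loq_snrs`` map signal label → observed S/N.  Absent sections stay empty.
    """
    report = ValidationReport()
    if linearity:
        report.linearity = {lbl: fit_linearity(pts) for lbl, pts in linearity.items()}
    if precision_sets:
        report.precision = {lbl: _section(v) for lbl, v in precision_sets.items()}
    if repeatability_sets:
        report.repeatability = {lbl: _section(v) for lbl, v in repeatability_sets.items()}
    if stability_sets:
        report.stability = {lbl: _section(v) for lbl, v in stability_sets.items()}
    if recovery_sets:
        report.recovery = {lbl: _section(v) for lbl, v in recovery_sets.items()}
    if loq_snrs:
        report.loq = {lbl: loq_gate(snr, snr_threshold) for lbl, snr in loq_snrs.items()}
    return report
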