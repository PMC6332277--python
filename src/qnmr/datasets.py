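"""Packaged reference data for the tadalafil / 2,4-dinitrotoluene assay.

Ships the default assay system (both compounds with their assayable sites,
multiplicities, J couplings and T1 values) and the published validation
records of that assay — linearity mass/area-ratio pairs, precision,
repeatability and stability purity replicates, and spike-recovery records —
as tidy DataFrames.  Signal columns are suffixed with the chemical shift of
the internal-standard signal used, e.g. ``purity_8.72``.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .spectral_model import Analyte, ProtonSite

__all__ = [
    "tadalafil_dnt_system",
    "linearity_table",
    "precision_table",
    "repeatability_table",
    "stability_table",
    "recovery_table",
    "SIGNAL_LABELS",
]

#: Chemical shifts (ppm) of the three internal-standard quantification signals.
SIGNAL_LABELS = ("8.72", "8.45", "7.82")


def _data_path(name: str):
    return resources.files("qnmr.data").joinpath(name)


def _analyte_from_dict(d: dict) -> Analyte:
    return Analyte(
        name=d["name"],
        mol_weight=d["mol_weight"],
        purity=d.get("purity", 1.0),
        quant_labels=tuple(d["quant_labels"]),
        sites=tuple(
            ProtonSite(
                label=s["label"],
                shift=s["shift"],
                n_protons=s["n_protons"],
                j_values=tuple(s.get("j_values", ())),
                t1=s.get("t1"),
            )
            for s in d["sites"]
        ),
    )


def tadalafil_dnt_system() -> tuple[Analyte, Analyte]:
    """Default (analyte, internal standard) pair.

    Tadalafil (M = 389.4 g/mol) quantified on its 2-proton methylenedioxy
    singlet at 5.91 ppm; 2,4-dinitrotoluene (M = 182.14 g/mol) integrated on
    its three aromatic one-proton signals at 8.72, 8.45 and 7.82 ppm.  The
    2,4-DNT methyl at 2.63 ppm carries no T1 value and is excluded from
    quantification.
    """
    with _data_path("tadalafil_dnt.json").open("r") as fh:
        raw = json.load(fh)
    return _analyte_from_dict(raw["analyte"]), _analyte_from_dict(raw["standard"])


def linearity_table() -> pd.DataFrame:
    """Six-level linearity design: masses, mass ratios and area ratios."""
    return pd.read_csv(_data_path("linearity.csv"))


def precision_table() -> pd.DataFrame:
    """Six independent sample preparations: masses and measured purities."""
    return pd.read_csv(_data_path("precision.csv"))


def repeatability_table() -> pd.DataFrame:
    """Six repeated measurements of one preparation."""
    return pd.read_csv(_data_path("repeatability.csv"))


def stability_table() -> pd.DataFrame:
    """One preparation re-measured at 0–24 h."""
    return pd.read_csv(_data_path("stability.csv"))


def recovery_table() -> pd.DataFrame:
    """Nine spiked-tablet recovery records (per-signal found masses and recoveries)."""
    return pd.read_csv(_data_path("recovery.csv"))
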