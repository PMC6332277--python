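"""Spectrum and tabular file I/O.

Spectra are exchanged as JCAMP-DX (the de facto NMR text interchange
format) or a plain two-column ppm/intensity TSV.  The JCAMP reader handles
``XYDATA=(X++(Y..Y))`` in AFFN form and the SQZ/DIF/DUP compressed ASDF
forms; the writer emits AFFN with an integer Y representation and a
``##YFACTOR`` chosen to preserve about seven significant digits.
Gravimetric records travel as CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SpectrumParseError
from .quantification import GravimetricRecord
from .spectral_model import AcquisitionParams, Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_jcampdx",
    "write_jcampdx",
    "read_tsv",
    "write_tsv",
    "read_gravimetrics",
    "write_gravimetrics",
]

# ASDF pseudo-digit tables
_SQZ = {"@": 0}
_SQZ.update({chr(ord("A") + i): i + 1 for i in range(9)})
_SQZ.update({chr(ord("a") + i): -(i + 1) for i in range(9)})
_DIF = {"%": 0}
_DIF.update({chr(ord("J") + i): i + 1 for i in range(9)})
_DIF.update({chr(ord("j") + i): -(i + 1) for i in range(9)})
_DUP = {chr(ord("S") + i): i + 1 for i in range(8)}
_DUP["s"] = 9


def _tokenize_asdf(text: str) -> list[str]:
    """Split a JCAMP data line into AFFN/SQZ/DIF/DUP tokens."""
    tokens: list[str] = []
    cur = ""
    for ch in text:
        if ch in " \t,;":
            if cur:
                tokens.append(cur)
                cur = ""
        elif ch in "+-" or ch in _SQZ or ch in _DIF or ch in _DUP:
            if cur:
                tokens.append(cur)
            cur = ch
        elif ch.isdigit() or ch == ".":
            if not cur:
                cur = ch
            else:
                cur += ch
        else:
            raise SpectrumParseError(f"unexpected character {ch!r} in data line {text!r}")
    if cur:
        tokens.append(cur)
    return tokens


def _decode_line(tokens: list[str], last_y: float | None, in_dif: bool):
    """Decode the Y tokens of one line.

    Returns (values, ended_in_dif).  When the previous line ended in DIF
    mode, the first value of this line is a check point duplicating the last
    emitted Y and is dropped.
    """
    values: list[float] = []
    ended_in_dif = False
    y = last_y
    prev_kind: str | None = None  # 'abs' | 'dif'
    prev_delta = 0.0
    for tok in tokens:
        head = tok[0]
        if head in _DUP:
            if prev_kind is None:
                raise SpectrumParseError(f"DUP token {tok!r} with nothing to repeat")
            # leading pseudo-digit carries the first digit; the rest are literal
            count = int(str(_DUP[head]) + tok[1:])
            for _ in range(count - 1):
                if prev_kind == "dif":
                    y = y + prev_delta
                    values.append(y)
                else:
                    values.append(y)
            ended_in_dif = prev_kind == "dif"
            continue
        if head in _SQZ:
            num = float(str(_SQZ[head]) + tok[1:]) if _SQZ[head] >= 0 else -float(
                str(-_SQZ[head]) + tok[1:]
            )
            y = num
            values.append(y)
            prev_kind, prev_delta = "abs", 0.0
            ended_in_dif = False
        elif head in _DIF:
            delta = float(str(_DIF[head]) + tok[1:]) if _DIF[head] >= 0 else -float(
                str(-_DIF[head]) + tok[1:]
            )
            if y is None:
                raise SpectrumParseError("DIF token before any absolute Y value")
            y = y + delta
            values.append(y)
            prev_kind, prev_delta = "dif", delta
            ended_in_dif = True
        else:  # AFFN
            try:
                y = float(tok)
            except ValueError as exc:
                raise SpectrumParseError(f"bad AFFN token {tok!r}") from exc
            values.append(y)
            prev_kind, prev_delta = "abs", 0.0
            ended_in_dif = False
    if in_dif and values:
        check = values.pop(0)
        if last_y is not None and abs(check - last_y) > max(1e-6, 1e-6 * abs(last_y)):
            raise SpectrumParseError(
                f"DIF check point mismatch: expected {last_y}, got {check}"
            )
    return values, ended_in_dif


def read_jcampdx(path: str | Path) -> Spectrum:
    """Read a 1D JCAMP-DX spectrum (XYDATA, AFFN or SQZ/DIF/DUP)."""
    path = Path(path)
    headers: dict[str, str] = {}
    y_scaled: list[float] = []
    in_data = False
    in_dif = False
    saw_end = False
    with path.open("r") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("$$", 1)[0].rstrip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper()
                if key == "END":
                    saw_end = True
                    break
                if key == "XYDATA":
                    in_data = True
                    continue
                headers[key] = value.strip()
                continue
            if not in_data:
                continue
            try:
                tokens = _tokenize_asdf(line.strip())
            except SpectrumParseError as exc:
                raise SpectrumParseError(f"{path}:{lineno}: {exc}") from exc
            if not tokens:
                continue
            # first token on a data line is the X start value (AFFN); drop it
            vals, in_dif = _decode_line(
                tokens[1:], y_scaled[-1] if y_scaled else None, in_dif
            )
            y_scaled.extend(vals)
    if not in_data:
        raise SpectrumParseError(f"{path}: no ##XYDATA block found")
    if not saw_end:
        raise SpectrumParseError(f"{path}: truncated file, ##END missing")

    def _need(key: str) -> str:
        if key not in headers:
            raise SpectrumParseError(f"{path}: missing required header ##{key}")
        return headers[key]

    npoints = int(float(_need("NPOINTS")))
    if len(y_scaled) != npoints:
        raise SpectrumParseError(
            f"{path}: ##NPOINTS={npoints} but {len(y_scaled)} Y values decoded"
        )
    firstx = float(_need("FIRSTX"))
    lastx = float(_need("LASTX"))
    xfactor = float(headers.get("XFACTOR", "1"))
    yfactor = float(headers.get("YFACTOR", "1"))
    x = np.linspace(firstx, lastx, npoints) * xfactor
    y = np.asarray(y_scaled) * yfactor

    xunits = headers.get("XUNITS", "PPM").upper()
    freq = float(headers.get(".OBSERVE FREQUENCY", "0") or 0)
    if xunits == "HZ":
        if freq <= 0:
            raise SpectrumParseError(
                f"{path}: XUNITS=HZ requires ##.OBSERVE FREQUENCY"
            )
        x = x / freq
    if x[0] < x[-1]:  # normalize to the descending display convention
        x = x[::-1]
        y = y[::-1]
    params = AcquisitionParams(
        spectrometer_freq=freq if freq > 0 else AcquisitionParams.spectrometer_freq,
        n_points=npoints,
        spectral_width=(
            abs(x[0] - x[-1]) * (freq if freq > 0 else AcquisitionParams.spectrometer_freq)
        ),
        center_ppm=float((x[0] + x[-1]) / 2),
    )
    return Spectrum(ppm=x, intensity=y, params=params, provenance=str(path))


def write_jcampdx(spectrum: Spectrum, path: str | Path, title: str = "qnmr spectrum") -> None:
    """Write a spectrum as JCAMP-DX, AFFN ``(X++(Y..Y))`` with integer Y."""
    path = Path(path)
    y = spectrum.intensity
    ymax = float(np.abs(y).max())
    yfactor = ymax / (2**24) if ymax > 0 else 1.0
    yint = np.rint(y / yfactor).astype(np.int64)
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=5.00",
        "##DATA TYPE=NMR SPECTRUM",
        "##DATA CLASS=XYDATA",
        "##ORIGIN=qnmr",
        "##OWNER=qnmr",
        f"##.OBSERVE FREQUENCY={spectrum.params.spectrometer_freq}",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        f"##FIRSTX={spectrum.ppm[0]:.8f}",
        f"##LASTX={spectrum.ppm[-1]:.8f}",
        f"##NPOINTS={len(spectrum)}",
        "##XFACTOR=1.0",
        f"##YFACTOR={yfactor!r}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 8
    for i in range(0, len(yint), per_line):
        chunk = yint[i : i + per_line]
        lines.append(f"{spectrum.ppm[i]:.8f} " + " ".join(str(int(v)) for v in chunk))
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


def read_tsv(path: str | Path) -> Spectrum:
    """Read a two-column ppm/intensity TSV (``#`` lines are metadata)."""
    path = Path(path)
    freq = 0.0
    xs: list[float] = []
    ys: list[float] = []
    with path.open("r") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "spectrometer_freq_mhz" in line and "=" in line:
                    freq = float(line.split("=", 1)[1])
                continue
            parts = line.split()
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(f"{path}:{lineno}: non-numeric value") from exc
    if len(xs) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data rows")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if x[0] < x[-1]:
        x, y = x[::-1], y[::-1]
    params = AcquisitionParams(
        spectrometer_freq=freq if freq > 0 else AcquisitionParams.spectrometer_freq,
        n_points=len(x),
        spectral_width=(
            abs(x[0] - x[-1]) * (freq if freq > 0 else AcquisitionParams.spectrometer_freq)
        ),
        center_ppm=float((x[0] + x[-1]) / 2),
    )
    return Spectrum(ppm=x, intensity=y, params=params, provenance=str(path))


def write_tsv(spectrum: Spectrum, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# spectrometer_freq_mhz={spectrum.params.spectrometer_freq}\n")
        fh.write("# columns: ppm intensity\n")
        for x, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{x:.8f}\t{y:.8e}\n")


_JCAMP_SUFFIXES = {".jdx", ".dx", ".jcamp"}


def read_spectrum(path: str | Path, fmt: str | None = None) -> Spectrum:
    """Read a spectrum, auto-detecting JCAMP-DX vs TSV by suffix."""
    path = Path(path)
    if fmt is None:
        fmt = "jcamp" if path.suffix.lower() in _JCAMP_SUFFIXES else "tsv"
    if fmt == "jcamp":
        return read_jcampdx(path)
    if fmt == "tsv":
        return read_tsv(path)
    raise ValueError(f"unknown spectrum format {fmt!r}")


def write_spectrum(spectrum: Spectrum, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "jcamp" if path.suffix.lower() in _JCAMP_SUFFIXES else "tsv"
    if fmt == "jcamp":
        write_jcampdx(spectrum, path)
    elif fmt == "tsv":
        write_tsv(spectrum, path)
    else:
        raise ValueError(f"unknown spectrum format {fmt!r}")


_GRAV_COLUMNS = {
    "m_std_mg": "m_std",
    "m_x_mg": "m_x",
    "m_powder_mg": "m_powder",
    "m_s_mg": "m_s",
    "p_std": "p_std",
    "p_s": "p_s",
    "t_mg": "avg_tablet_weight",
}


def read_gravimetrics(path: str | Path) -> list[tuple[str, GravimetricRecord]]:
    """Read gravimetric records from CSV.

    Recognized columns (others pass through untouched): ``sample_id``,
    ``m_std_mg``, ``m_x_mg``, ``m_powder_mg``, ``m_s_mg``, ``p_std``,
    ``p_s``, ``t_mg``.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for col, fieldname in _GRAV_COLUMNS.items():
            if col in df.columns and pd.notna(row[col]):
                kwargs[fieldname] = float(row[col])
        sample_id = str(row["sample_id"]) if "sample_id" in df.columns else str(len(out) + 1)
        out.append((sample_id, GravimetricRecord(**kwargs)))
    return out


def write_gravimetrics(
    records: list[tuple[str, GravimetricRecord]], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id"] + list(_GRAV_COLUMNS))
        for sample_id, rec in records:
            writer.writerow(
                [sample_id]
                + [getattr(rec, fieldname) for fieldname in _GRAV_COLUMNS.values()]
            )
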