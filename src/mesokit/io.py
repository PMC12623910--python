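"""Plain-text I/O for scattering patterns, curves and dielectric spectra.

Scattering data travel as two-column text (".xy" dialect): whitespace- or
comma-delimited numeric columns, with optional '#'-prefixed header lines
carrying ``key: value`` metadata (``wavelength``, ``label``).  Dielectric
spectra are CSV with columns ``freq,eps_real,eps_imag`` (or ``freq,eps_imag``)
and the temperature in a ``# temperature: <K>`` header.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .dielectric import DielectricSpectrum
from .reduction import PDFCurve, ScatteringPattern, StructureFactor

__all__ = [
    "read_xy",
    "write_xy",
    "read_structure_factor",
    "write_structure_factor",
    "write_pdf",
    "read_pdf",
    "read_dielectric_csv",
    "write_dielectric_csv",
]

PathLike = Union[str, Path]


def _parse_two_columns(path: PathLike) -> Tuple[np.ndarray, np.ndarray, Dict[str, str]]:
    meta: Dict[str, str] = {}
    xs: List[float] = []
    ys: List[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip().lower()] = value.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric value in {line!r}"
                ) from None
    if not xs:
        raise ValueError(f"{path}: no data rows")
    return np.array(xs), np.array(ys), meta


def read_xy(path: PathLike) -> ScatteringPattern:
    """Read a two-column Q/intensity file into a ScatteringPattern."""
    q, intensity, meta = _parse_two_columns(path)
    wavelength = float(meta["wavelength"]) if "wavelength" in meta else None
    return ScatteringPattern(
        q=q, intensity=intensity, wavelength=wavelength,
        label=meta.get("label", Path(path).stem),
    )


def _write_two_columns(path: PathLike, x, y, header: Dict[str, object], columns: str):
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in header.items():
            if value is not None and value != "":
                fh.write(f"# {key}: {value}\n")
        fh.write(f"# columns: {columns}\n")
        for xi, yi in zip(x, y):
            fh.write(f"{xi:.17g} {yi:.17g}\n")


def write_xy(pattern: ScatteringPattern, path: PathLike) -> None:
    """Write a pattern as two-column text; read_xy round-trips it."""
    _write_two_columns(
        path, pattern.q, pattern.intensity,
        {"label": pattern.label, "wavelength": pattern.wavelength},
        "Q[1/A] intensity",
    )


def write_structure_factor(sf: StructureFactor, path: PathLike) -> None:
    _write_two_columns(
        path, sf.q, sf.s, {"label": sf.label, "qmax": sf.qmax}, "Q[1/A] S(Q)"
    )


def read_structure_factor(path: PathLike) -> StructureFactor:
    q, s, meta = _parse_two_columns(path)
    qmax = float(meta["qmax"]) if "qmax" in meta else 0.0
    return StructureFactor(q=q, s=s, qmax=qmax, label=meta.get("label", Path(path).stem))


def write_pdf(pdf: PDFCurve, path: PathLike) -> None:
    _write_two_columns(path, pdf.r, pdf.g, {"label": pdf.label}, "r[A] G(r)[1/A^2]")


def read_pdf(path: PathLike) -> PDFCurve:
    r, g, meta = _parse_two_columns(path)
    return PDFCurve(r=r, g=g, label=meta.get("label", Path(path).stem))


def read_dielectric_csv(path: PathLike, temperature: Optional[float] = None) -> DielectricSpectrum:
    """Read a per-temperature spectrum: CSV columns freq[,eps_real],eps_imag.

    The temperature comes from a ``# temperature: <K>`` header line unless
    supplied explicitly.
    """
    meta: Dict[str, str] = {}
    rows: List[List[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, rec in enumerate(reader, start=1):
            if not rec:
                continue
            if rec[0].strip().startswith("#"):
                body = ",".join(rec).lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip().lower()] = value.strip()
                continue
            try:
                rows.append([float(v) for v in rec if v.strip() != ""])
            except ValueError:
                if not rows:  # a single column-name header row is allowed
                    continue
                raise ValueError(f"{path}: line {lineno}: non-numeric row {rec!r}") from None
    if temperature is None:
        if "temperature" not in meta:
            raise ValueError(f"{path}: temperature not in header and not supplied")
        temperature = float(meta["temperature"])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows)
    if arr.shape[1] == 2:
        return DielectricSpectrum(freq=arr[:, 0], eps_imag=arr[:, 1], temperature=temperature)
    if arr.shape[1] >= 3:
        return DielectricSpectrum(
            freq=arr[:, 0], eps_real=arr[:, 1], eps_imag=arr[:, 2], temperature=temperature
        )
    raise ValueError(f"{path}: expected 2 or 3 numeric columns")


def write_dielectric_csv(spec: DielectricSpectrum, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# temperature: {spec.temperature}\n")
        if spec.eps_real is None:
            fh.write("freq,eps_imag\n")
            for f, e2 in zip(spec.freq, spec.eps_imag):
                fh.write(f"{f:.17g},{e2:.17g}\n")
        else:
            fh.write("freq,eps_real,eps_imag\n")
            for f, e1, e2 in zip(spec.freq, spec.eps_real, spec.eps_imag):
                fh.write(f"{f:.17g},{e1:.17g},{e2:.17g}\n")
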