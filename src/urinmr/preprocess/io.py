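"""Reading and writing spectrum sets.

Two plain-text formats are supported: a spectra TSV (first column ``ppm``,
one column per sample — the format the synthetic generator writes) and
single-spectrum JCAMP-DX files restricted to the common
``##XYDATA=(X++(Y..Y))`` form with fixed-step abscissa.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..datatypes import Spectrum, stack_spectra

__all__ = ["read_spectra_tsv", "write_spectra_tsv", "read_jcamp"]


def read_spectra_tsv(path) -> list:
    """Read a ppm + per-sample-column TSV into a list of Spectrum."""
    frame = pd.read_csv(path, sep="\t")
    if "ppm" not in frame.columns:
        raise ValueError("spectra TSV needs a 'ppm' column")
    ppm = frame.pop("ppm").to_numpy(float)
    return [Spectrum(ppm, frame[c].to_numpy(float), sample_id=str(c)) for c in frame.columns]


def write_spectra_tsv(spectra, path) -> None:
    ppm, mat, ids = stack_spectra(spectra)
    frame = pd.DataFrame(mat.T, columns=ids)
    frame.insert(0, "ppm", ppm)
    frame.to_csv(path, sep="\t", index=False)


def read_jcamp(path) -> Spectrum:
    """Minimal JCAMP-DX reader for ``##XYDATA=(X++(Y..Y))`` blocks.

    Honours ##FIRSTX/##LASTX/##NPOINTS, ##XFACTOR/##YFACTOR and ##XUNITS
    (HZ is converted to ppm via ##.OBSERVE FREQUENCY when present).
    """
    path = Path(path)
    header: dict = {}
    y: list = []
    in_data = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            value = value.strip()
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                break
            header[key] = value
            in_data = False
            continue
        if in_data and not line.startswith("$$"):
            nums = line.replace(",", " ").split()
            if nums:
                y.extend(float(v) for v in nums[1:])  # first number is the X check value
    if not y:
        raise ValueError(f"no XYDATA found in {path}")
    npoints = int(float(header.get("NPOINTS", len(y))))
    y = np.asarray(y[:npoints], dtype=float) * float(header.get("YFACTOR", 1.0))
    xfactor = float(header.get("XFACTOR", 1.0))
    firstx = float(header.get("FIRSTX", 0.0)) * xfactor
    lastx = float(header.get("LASTX", npoints - 1.0)) * xfactor
    x = np.linspace(firstx, lastx, y.size)
    if header.get("XUNITS", "").upper() == "HZ":
        obs = float(header.get(".OBSERVE FREQUENCY", 0) or 0)
        if obs > 0:
            x = x / obs
    return Spectrum(x, y, sample_id=header.get("TITLE", path.stem))
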