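"""Core containers: single spectra and binned sample × bin matrices.

Axis convention: chemical shift in ppm, stored *descending* left to right
(the NMR plotting convention); bins are labelled by their (hi, lo) ppm
edges and are half-open on the low side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "BinnedMatrix", "stack_spectra"]


@dataclass
class Spectrum:
    """One 1D spectrum: a ppm axis (descending) and matching intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D and the same length")
        if self.ppm.size >= 2 and self.ppm[0] < self.ppm[-1]:  # ascending input
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        if self.ppm.size >= 2 and not np.all(np.diff(self.ppm) < 0):
            raise ValueError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def copy(self, intensity=None) -> "Spectrum":
        return Spectrum(
            self.ppm.copy(),
            self.intensity.copy() if intensity is None else np.asarray(intensity, float),
            self.sample_id,
        )

    def __len__(self) -> int:
        return self.ppm.size


def stack_spectra(spectra) -> tuple[np.ndarray, np.ndarray, list]:
    """Common axis + (n_samples, n_points) intensity matrix from a spectrum set."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("empty spectra set")
    ppm = spectra[0].ppm
    for s in spectra[1:]:
        if s.ppm.shape != ppm.shape or not np.allclose(s.ppm, ppm):
            raise ValueError("all spectra must share one ppm axis")
    mat = np.vstack([s.intensity for s in spectra])
    ids = [s.sample_id for s in spectra]
    return ppm, mat, ids


@dataclass
class BinnedMatrix:
    """Samples × bins intensity matrix with ppm bin edges.

    ``bin_edges`` is (n_bins, 2) of (hi, lo) ppm pairs, ordered by
    descending position; ``metadata`` carries provenance (preprocessing
    parameters, normalization factors, planted-truth flags from the
    synthetic generator, ...).
    """

    values: np.ndarray
    bin_edges: np.ndarray
    sample_ids: list
    excluded_regions: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64).reshape(-1, 2)
        if self.values.ndim != 2:
            raise ValueError("values must be samples × bins")
        if self.values.shape[1] != self.bin_edges.shape[0]:
            raise ValueError("one (hi, lo) edge pair per bin required")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("one sample_id per row required")
        if np.any(self.bin_edges[:, 0] <= self.bin_edges[:, 1]):
            raise ValueError("each bin needs hi > lo")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_edges.mean(axis=1)

    @property
    def bin_labels(self) -> list:
        return [f"{hi:.4f}-{lo:.4f}" for hi, lo in self.bin_edges]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.bin_labels)

    def select_bins(self, mask) -> "BinnedMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return BinnedMatrix(
            self.values[:, idx],
            self.bin_edges[idx],
            list(self.sample_ids),
            list(self.excluded_regions),
            dict(self.metadata),
        )

    def with_values(self, values, **meta) -> "BinnedMatrix":
        md = dict(self.metadata)
        md.update(meta)
        return BinnedMatrix(values, self.bin_edges.copy(), list(self.sample_ids),
                            list(self.excluded_regions), md)

    def to_csv(self, path) -> None:
        """Write values as CSV plus a ``<path>.meta.json`` sidecar of edges
        and provenance."""
        path = Path(path)
        self.to_frame().to_csv(path, index_label="sample_id")
        sidecar = {
            "bin_edges": self.bin_edges.tolist(),
            "excluded_regions": [list(map(float, r)) for r in self.excluded_regions],
            "metadata": _jsonable(self.metadata),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path) -> "BinnedMatrix":
        path = Path(path)
        frame = pd.read_csv(path, index_col=0)
        sidecar_path = path.with_suffix(path.suffix + ".meta.json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            edges = np.asarray(sidecar["bin_edges"], dtype=float)
            excluded = [tuple(r) for r in sidecar.get("excluded_regions", [])]
            meta = sidecar.get("metadata", {})
        else:  # parse "hi-lo" column labels
            edges = np.array(
                [[float(a), float(b)] for a, b in (c.rsplit("-", 1) for c in frame.columns)]
            )
            excluded, meta = [], {}
        return cls(frame.to_numpy(float), edges, [str(i) for i in frame.index], excluded, meta)


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return {str(c): _jsonable(obj[c].tolist()) for c in obj.columns}
    if isinstance(obj, pd.Series):
        return _jsonable(obj.tolist())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
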