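"""Result assembly: discriminant-metabolite tables, score-plot exports and
run provenance.

Bin → metabolite annotation is a user-supplied mapping of ppm ranges (the
original assignments would come from 2D NMR, outside this package's scope);
a default map for the synthetic panel can be derived from any
:class:`~urinmr.synth.MetabolitePanel`.  Significant bins without an
annotation are reported as "unknown".
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import _jsonable

__all__ = [
    "RunProvenance",
    "load_annotation",
    "annotation_from_panel",
    "annotate_bins",
    "make_table2",
    "export_scoreplots",
]


@dataclass
class RunProvenance:
    """Per-stage parameter log so every reported number is traceable."""

    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    software_version: str = __version__
    stages: list = field(default_factory=list)
    started: float = field(default_factory=time.time)

    def log(self, stage: str, **params) -> None:
        self.stages.append({"stage": stage, "params": _jsonable(params),
                            "time": time.time()})

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "software_version": self.software_version,
                    "config": _jsonable(self.config),
                    "seeds": _jsonable(self.seeds),
                    "started": self.started,
                    "stages": self.stages,
                },
                indent=1,
            )
        )


def load_annotation(path) -> list:
    """Read a YAML of ``name: [lo_ppm, hi_ppm]`` (or a list of such ranges)
    into a flat [(lo, hi, name)] list."""
    data = yaml.safe_load(Path(path).read_text())
    out = []
    for name, ranges in data.items():
        if ranges and not isinstance(ranges[0], (list, tuple)):
            ranges = [ranges]
        for lo, hi in ranges:
            out.append((float(lo), float(hi), str(name)))
    return out


def annotation_from_panel(panel, tol_ppm: float = 0.02) -> list:
    """Annotation ranges covering each panel peak ± its width + tolerance."""
    out = []
    for entry in panel:
        for peak in entry.peaks:
            half = peak.width_ppm + tol_ppm
            out.append((peak.center_ppm - half, peak.center_ppm + half, entry.name))
    return out


def annotate_bins(bin_edges: np.ndarray, annotation: list) -> list:
    """Metabolite name per bin ('unknown' when no range covers its centre;
    the lexicographically first name wins on overlaps)."""
    names = []
    for hi, lo in np.asarray(bin_edges).reshape(-1, 2):
        centre = (hi + lo) / 2.0
        hits = sorted({name for a_lo, a_hi, name in annotation if a_lo <= centre <= a_hi})
        names.append(hits[0] if hits else "unknown")
    return names


def make_table2(selection, annotation, bin_edges=None) -> pd.DataFrame:
    """Discriminant-metabolite table: metabolite, CV1 weight sign, group.

    ``selection`` is a :class:`~urinmr.plslda.VariableSelectionResult`;
    ``annotation`` a [(lo, hi, name)] list (see :func:`load_annotation`).
    ``bin_edges`` defaults to parsing the selection's "hi-lo" variable names.
    """
    frame = selection.frame
    sig = frame[frame["significant"]]
    if sig.empty:
        return pd.DataFrame(columns=["metabolite", "cv1_sign", "associated_group"])
    if bin_edges is None:
        bin_edges = np.array(
            [[float(a), float(b)] for a, b in (str(v).rsplit("-", 1) for v in sig.index)]
        )
    else:
        bin_edges = np.asarray(bin_edges).reshape(-1, 2)[frame["significant"].to_numpy()]
    names = annotate_bins(bin_edges, annotation)
    rows = []
    for name in dict.fromkeys(names):  # first-appearance order
        idx = [i for i, n in enumerate(names) if n == name]
        weights = sig["mean_weight"].to_numpy()[idx]
        sign = int(np.sign(weights[np.argmax(np.abs(weights))]))
        rows.append(
            {
                "metabolite": name,
                "cv1_sign": "+" if sign > 0 else "-",
                "associated_group": sig["associated_group"].iloc[
                    idx[int(np.argmax(np.abs(weights)))]
                ],
                "n_bins": len(idx),
            }
        )
    return pd.DataFrame(rows)


def export_scoreplots(
    pcoa_result=None,
    plslda_scores=None,
    labels=None,
    stability=None,
    sample_ids=None,
    outdir=".",
) -> dict:
    """Write plot-ready CSVs for the PCoA and PLS-LDA score plots.

    Returns a dict of written paths.  The PCoA export carries one
    coordinate column per axis plus a companion axes CSV with the explained
    variance of each principal coordinate; the PLS-LDA export carries the
    first-canonical-variate score, the group and the cross-validation
    stability category per sample.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    if pcoa_result is not None:
        frame = pcoa_result.to_frame()
        if labels is not None:
            frame["group"] = np.asarray(labels)
        path = outdir / "pcoa_scores.csv"
        frame.to_csv(path, index_label="sample_id")
        axes = pd.DataFrame(
            {
                "axis": [f"PCo{i + 1}" for i in range(len(pcoa_result.explained_pct))],
                "explained_pct": pcoa_result.explained_pct,
                "eigenvalue": pcoa_result.eigenvalues,
            }
        )
        axes_path = outdir / "pcoa_axes.csv"
        axes.to_csv(axes_path, index=False)
        written["pcoa_scores"] = path
        written["pcoa_axes"] = axes_path
    if plslda_scores is not None:
        scores = np.asarray(plslda_scores, dtype=float)
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(scores.shape[0])]
        frame = pd.DataFrame({"cv1_score": scores}, index=pd.Index(sample_ids, name="sample_id"))
        if labels is not None:
            frame["group"] = np.asarray(labels)
        if stability is not None:
            frame["stability"] = np.asarray(stability)
        path = outdir / "plslda_scores.csv"
        frame.to_csv(path)
        written["plslda_scores"] = path
    return written
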