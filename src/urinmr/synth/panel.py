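"""Metabolite panel: names, multiplet definitions and group effects.

The default panel carries 27 urinary metabolites with their worker/resident
association signs (9 elevated in workers, 18 in residents); chemical shifts
and couplings are plausible reference values stored in
``metabolite_shifts.yaml`` next to this module, so they can be versioned
and edited without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = ["Peak", "MetaboliteEntry", "MetabolitePanel", "build_default_panel"]

DEFAULT_EFFECT_SIZE = 0.5  # log-fold-change between groups for discriminants


@dataclass(frozen=True)
class Peak:
    """One multiplet: a binomially weighted comb of Lorentzian lines."""

    center_ppm: float
    multiplicity: int = 1
    J_hz: float = 0.0
    width_ppm: float = 0.002  # FWHM of each line
    relative_area: float = 1.0

    def lines(self, sf_mhz: float = 600.0):
        """(offsets_ppm, weights) of the individual lines; weights sum to 1."""
        m = int(self.multiplicity)
        j_ppm = self.J_hz / sf_mhz
        k = np.arange(m)
        offsets = (k - (m - 1) / 2.0) * j_ppm
        weights = np.array([_binom(m - 1, i) for i in k], dtype=float)
        weights /= weights.sum()
        return offsets, weights


def _binom(n, k):
    out = 1.0
    for i in range(k):
        out = out * (n - i) / (i + 1)
    return out


@dataclass
class MetaboliteEntry:
    name: str
    peaks: list
    base_concentration: float = 1.0
    group_sign: int = 0  # +1 higher in workers, -1 higher in residents
    effect_size: float = 0.0  # |log-fold-change| between group means

    def __post_init__(self):
        self.peaks = [p if isinstance(p, Peak) else Peak(*p) for p in self.peaks]
        if self.base_concentration <= 0:
            raise ValueError(f"{self.name}: base_concentration must be positive")
        for p in self.peaks:
            if p.width_ppm <= 0 or p.relative_area <= 0:
                raise ValueError(f"{self.name}: widths and areas must be positive")
        if self.group_sign not in (-1, 0, 1):
            raise ValueError(f"{self.name}: group_sign must be -1, 0 or +1")
        # a null effect and a null sign imply each other
        if self.effect_size == 0:
            self.group_sign = 0
        if self.group_sign == 0:
            self.effect_size = 0.0

    @property
    def total_area(self) -> float:
        return float(sum(p.relative_area for p in self.peaks))


@dataclass
class MetabolitePanel:
    """An ordered collection of metabolite entries."""

    entries: list = field(default_factory=list)

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate metabolite names in panel")

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> MetaboliteEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def names(self) -> list:
        return [e.name for e in self.entries]

    @property
    def signs(self) -> np.ndarray:
        return np.array([e.group_sign for e in self.entries], dtype=int)

    def check_axis(self, ppm_min: float, ppm_max: float) -> None:
        for e in self.entries:
            for p in e.peaks:
                if not (ppm_min <= p.center_ppm <= ppm_max):
                    raise ValueError(
                        f"{e.name}: peak at {p.center_ppm} ppm outside axis "
                        f"[{ppm_min}, {ppm_max}]"
                    )

    def with_effect_sizes(self, effect_size: float) -> "MetabolitePanel":
        """Same panel with every discriminant effect set to ``effect_size``.

        Setting 0 nulls the panel: every group_sign collapses to 0.
        """
        out = []
        for e in self.entries:
            out.append(
                MetaboliteEntry(
                    e.name, list(e.peaks), e.base_concentration,
                    e.group_sign, effect_size if e.group_sign != 0 else 0.0,
                )
            )
        return MetabolitePanel(out)

    def null_panel(self) -> "MetabolitePanel":
        return self.with_effect_sizes(0.0)

    @classmethod
    def from_yaml(cls, path, effect_size: float = DEFAULT_EFFECT_SIZE) -> "MetabolitePanel":
        data = yaml.safe_load(Path(path).read_text())
        entries = []
        for m in data["metabolites"]:
            sign = int(m.get("group_sign", 0))
            entries.append(
                MetaboliteEntry(
                    name=m["name"],
                    peaks=[Peak(*p) for p in m["peaks"]],
                    base_concentration=float(m.get("base_concentration", 1.0)),
                    group_sign=sign,
                    effect_size=float(m.get("effect_size", effect_size if sign else 0.0)),
                )
            )
        return cls(entries)

    def to_yaml(self, path) -> None:
        data = {
            "metabolites": [
                {
                    "name": e.name,
                    "group_sign": int(e.group_sign),
                    "base_concentration": float(e.base_concentration),
                    "effect_size": float(e.effect_size),
                    "peaks": [
                        [p.center_ppm, p.multiplicity, p.J_hz, p.width_ppm, p.relative_area]
                        for p in e.peaks
                    ],
                }
                for e in self.entries
            ]
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def build_default_panel(effect_size: float = DEFAULT_EFFECT_SIZE) -> MetabolitePanel:
    """The 27-metabolite urinary panel with worker/resident signs.

    ``effect_size`` is the |log-fold-change| planted for every discriminant
    metabolite; 0 returns a null panel (all signs 0).
    """
    ref = resources.files("urinmr.synth").joinpath("metabolite_shifts.yaml")
    with resources.as_file(ref) as path:
        return MetabolitePanel.from_yaml(path, effect_size=effect_size)
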