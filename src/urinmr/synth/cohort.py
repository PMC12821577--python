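"""Synthetic urine-NMR cohorts with known ground truth.

Each sample's noiseless spectrum is a sum of Lorentzian multiplets, one set
per panel metabolite, scaled by that sample's realized concentration and a
log-normal dilution factor (urine concentration varies strongly between
voids — this gives the quotient-normalization stage something real to
remove).  On top come a slow baseline drift, per-metabolite chemical-shift
jitter (pH/ionic-strength effects) and additive Gaussian noise.

Group structure: for a discriminant metabolite with sign s and effect size
e, workers draw log-concentrations centred at ``log(base) + s*e/2`` and
residents at ``log(base) - s*e/2``; biological between-subject variability
adds ``conc_log_sd`` on the log scale for everyone.

Covariates (age, sex, smoking, alcohol, BMI) are generated to match the
study's cohort structure (residents older, workers smoking more) but by
default have no causal link to the spectra; an optional ``confounded_by``
mode couples a binary covariate to a subset of metabolites for
negative-control experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..datatypes import BinnedMatrix, Spectrum
from .panel import MetabolitePanel, build_default_panel

__all__ = [
    "CovariateGroupModel",
    "CohortDesign",
    "Cohort",
    "simulate_cohort",
    "cohort_to_binned",
    "write_cohort",
    "read_cohort",
]

WORKER, RESIDENT = "worker", "resident"


@dataclass
class CovariateGroupModel:
    """Per-group covariate distributions (ages in years, BMI in kg/m^2)."""

    age_mean: float
    age_sd: float
    p_male: float
    p_smoker: float
    p_alcohol: float
    bmi_mean: float
    bmi_sd: float
    bmi_range: tuple = (16.0, 45.0)

    def draw(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        age = np.clip(rng.normal(self.age_mean, self.age_sd, n), 18, 80)
        sex = np.where(rng.random(n) < self.p_male, "M", "F")
        smoker = rng.random(n) < self.p_smoker
        alcohol = rng.random(n) < self.p_alcohol
        bmi = np.clip(rng.normal(self.bmi_mean, self.bmi_sd, n), *self.bmi_range)
        return pd.DataFrame(
            {"age": age, "sex": sex, "smoker": smoker, "alcohol": alcohol, "bmi": bmi}
        )


def default_covariate_model() -> dict:
    """Worker/resident covariate models mirroring the study cohort:
    workers age 47 ± 8 with 24/64 smokers, residents 57 ± 10 with 7/78
    smokers; sex, alcohol and BMI near-homogeneous between groups."""
    return {
        WORKER: CovariateGroupModel(
            age_mean=47, age_sd=8, p_male=38 / 64, p_smoker=24 / 64,
            p_alcohol=44 / 64, bmi_mean=24.4, bmi_sd=2.6, bmi_range=(18.4, 31.2),
        ),
        RESIDENT: CovariateGroupModel(
            age_mean=57, age_sd=10, p_male=41 / 77, p_smoker=7 / 78,
            p_alcohol=58 / 78, bmi_mean=25.0, bmi_sd=3.5, bmi_range=(18.4, 39.4),
        ),
    }


@dataclass
class CohortDesign:
    """Everything needed to simulate one cohort reproducibly."""

    n_workers: int = 64
    n_residents: int = 78
    panel: MetabolitePanel = None
    dilution_log_sd: float = 0.4
    conc_log_sd: float = 0.2  # biological between-subject variability (log scale)
    shift_jitter_sd_ppm: float = 0.002
    noise_sd: float = 0.5
    baseline_amplitude: float = 5.0
    # unassigned background metabolites: urine spectra are crowded, and even
    # "empty" regions carry dilution-scaled signals with their own
    # between-subject variability — without them, quotient-normalized null
    # bins would all collapse onto 1/dilution
    n_background: int = 250
    background_conc: float = 0.3
    background_conc_log_sd: float = 0.3
    background_width_ppm: float = 0.002
    # broad macromolecule-like humps filling the gaps between sharp lines
    n_broad: int = 30
    broad_conc: float = 0.5
    broad_width_range: tuple = (0.01, 0.06)
    axis: tuple = (0.2, 9.8, 4096)  # (ppm_min, ppm_max, n_points)
    sf_mhz: float = 600.0
    covariate_model: dict = None
    confounded_by: str = None  # e.g. "smoker": couples covariate to spectra
    confound_strength: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.panel is None:
            self.panel = build_default_panel()
        if self.covariate_model is None:
            self.covariate_model = default_covariate_model()
        if self.n_workers < 2 or self.n_residents < 2:
            raise ValueError("need at least 2 samples per group")
        if self.axis[2] < 256:
            raise ValueError("axis needs >= 256 points")
        if min(self.dilution_log_sd, self.conc_log_sd, self.shift_jitter_sd_ppm,
               self.noise_sd, self.baseline_amplitude) < 0:
            raise ValueError("spreads must be non-negative")
        self.panel.check_axis(self.axis[0], self.axis[1])

    @property
    def n_samples(self) -> int:
        return self.n_workers + self.n_residents

    def ppm_axis(self) -> np.ndarray:
        lo, hi, n = self.axis
        return np.linspace(hi, lo, int(n))  # descending, NMR convention


@dataclass
class Cohort:
    """Simulated cohort: spectra, labels, covariates and the planted truth."""

    spectra: list
    labels: np.ndarray
    covariates: pd.DataFrame
    truth: dict  # dilution (n,), concentrations (n × m) DataFrame, jitter
    design: CohortDesign

    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.spectra]


def _line_table(panel: MetabolitePanel, sf_mhz: float):
    """Flatten the panel into per-line arrays (metabolite idx, center, HWHM, area)."""
    midx, centers, gammas, areas = [], [], [], []
    for i, entry in enumerate(panel):
        for peak in entry.peaks:
            offs, wts = peak.lines(sf_mhz)
            for o, w in zip(offs, wts):
                midx.append(i)
                centers.append(peak.center_ppm + o)
                gammas.append(peak.width_ppm / 2.0)
                areas.append(peak.relative_area * w)
    return (np.array(midx), np.array(centers), np.array(gammas), np.array(areas))


def _background_table(design: CohortDesign):
    """Fixed background layout for a design (deterministic given the seed).

    Background compounds carry 1–3 sharp peaks each; a further set of broad
    macromolecule-like humps fills the gaps between sharp lines.  Returns
    per-line arrays (center, HWHM, area weight, compound index) plus the
    per-compound base concentrations; per-sample concentrations are drawn
    per compound and shared by its lines.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(design.seed), 0xB6]))
    lo, hi, _ = design.axis
    # urine spectra carry essentially no signal beyond ~9.3 ppm — that is
    # what makes the high-field end usable as a noise region
    lo = lo + 0.05
    hi = min(hi - 0.05, 9.35)
    pad = 0.0
    centers, gammas, weights, comp = [], [], [], []
    base = []
    k = 0
    for _ in range(design.n_background):
        base.append(design.background_conc * np.exp(rng.normal(0.0, 0.5)))
        n_peaks = int(rng.integers(1, 4))
        w = rng.dirichlet(np.ones(n_peaks))
        for j in range(n_peaks):
            centers.append(rng.uniform(lo + pad, hi - pad))
            gammas.append(design.background_width_ppm / 2.0)
            weights.append(w[j])
            comp.append(k)
        k += 1
    for _ in range(design.n_broad):
        base.append(design.broad_conc * np.exp(rng.normal(0.0, 0.5)))
        centers.append(rng.uniform(lo + pad, hi - pad))
        gammas.append(rng.uniform(*design.broad_width_range) / 2.0)
        weights.append(1.0)
        comp.append(k)
        k += 1
    return (
        np.asarray(centers),
        np.asarray(gammas),
        np.asarray(weights),
        np.asarray(comp, dtype=int),
        np.asarray(base),
    )


def _draw_concentrations(design: CohortDesign, rng: np.random.Generator):
    """Realized per-sample concentrations, dilutions and covariates."""
    panel = design.panel
    n_w, n_r = design.n_workers, design.n_residents
    n, m = n_w + n_r, len(panel)
    labels = np.array([WORKER] * n_w + [RESIDENT] * n_r)
    is_worker = labels == WORKER

    cov_parts = []
    for grp, cnt in ((WORKER, n_w), (RESIDENT, n_r)):
        cov_parts.append(design.covariate_model[grp].draw(cnt, rng))
    covariates = pd.concat(cov_parts, ignore_index=True)
    covariates.insert(0, "group", labels)

    base = np.log([e.base_concentration for e in panel])
    shift = np.array([e.group_sign * e.effect_size / 2.0 for e in panel])
    mu = np.where(is_worker[:, None], base + shift, base - shift)
    logc = mu + rng.normal(0.0, design.conc_log_sd, size=(n, m))
    if design.confounded_by is not None:
        flag = covariates[design.confounded_by].to_numpy()
        if flag.dtype != bool:
            flag = flag == flag[0]
        k = max(1, m // 5)
        logc[:, :k] += np.where(flag, design.confound_strength, 0.0)[:, None]
    conc = np.exp(logc)
    dilution = np.exp(rng.normal(0.0, design.dilution_log_sd, size=n))
    bg_base = _background_table(design)[4]
    bg_conc = bg_base[None, :] * np.exp(
        rng.normal(0.0, design.background_conc_log_sd, size=(n, bg_base.size))
    )
    return labels, covariates, conc, dilution, bg_conc


def simulate_cohort(design: CohortDesign) -> Cohort:
    """Simulate a full-resolution spectral cohort (deterministic given seed)."""
    rng = np.random.default_rng(design.seed)
    labels, covariates, conc, dilution, bg_conc = _draw_concentrations(design, rng)
    n, m = conc.shape
    midx, centers, gammas, areas = _line_table(design.panel, design.sf_mhz)
    bg_centers, bg_gammas, bg_weights, bg_comp, _ = _background_table(design)
    ppm = design.ppm_axis()
    npts = ppm.size
    jitter = rng.normal(0.0, design.shift_jitter_sd_ppm, size=(n, m))
    span = design.axis[1] - design.axis[0]
    phase = rng.uniform(0, 2 * np.pi, size=n)
    cycles = rng.uniform(0.5, 2.0, size=n)
    spectra = []
    x = ppm[None, :]
    all_gammas = np.concatenate([gammas, bg_gammas])
    for i in range(n):
        amp = conc[i, midx] * areas * dilution[i]  # per-line absolute area
        c = centers + jitter[i, midx]
        amp = np.concatenate([amp, bg_conc[i, bg_comp] * bg_weights * dilution[i]])
        c = np.concatenate([c, bg_centers])
        d = x - c[:, None]
        lor = (amp[:, None] / np.pi) * (all_gammas[:, None] / (d * d + all_gammas[:, None] ** 2))
        intensity = lor.sum(axis=0)
        if design.baseline_amplitude > 0:
            intensity = intensity + design.baseline_amplitude * (
                1 + np.sin(phase[i] + 2 * np.pi * cycles[i] * (ppm - design.axis[0]) / span)
            )
        if design.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, design.noise_sd, npts)
        spectra.append(Spectrum(ppm.copy(), intensity, sample_id=f"s{i:03d}"))
    truth = {
        "dilution": dilution,
        "concentrations": pd.DataFrame(
            conc, columns=design.panel.names, index=[s.sample_id for s in spectra]
        ),
        "jitter_ppm": jitter,
        "background_concentrations": bg_conc,
    }
    return Cohort(spectra, labels, covariates, truth, design)


def flag_truth_bins(
    source,
    bin_edges: np.ndarray,
    sf_mhz: float = 600.0,
    dominance: float = 0.5,
    null_max: float = 0.05,
    min_content: float = 0.01,
) -> dict:
    """Ground-truth classification of arbitrary (hi, lo) ppm bins.

    Bins are judged by their *expected content* at base concentrations —
    Lorentzian tails of strong metabolites count, because a bin whose
    intensity is mostly the tail of a discriminant peak genuinely carries
    that metabolite's group effect.  A bin is

    * *planted* with sign s when metabolites of sign s contribute at least
      ``dominance`` of its expected content and the opposite sign at most
      10%;
    * *null* when discriminant metabolites contribute at most ``null_max``
      of its content, or when its total expected content is negligible
      (below ``min_content`` of the best-filled bin);
    * *ambiguous* otherwise (contaminated or sign-mixed) — such bins belong
      to neither the planted nor the null set in recovery studies.

    ``source`` is a :class:`CohortDesign` (background compounds included in
    the content accounting) or a bare :class:`MetabolitePanel`.

    Returns ``bin_signs`` (+1/-1/0), ``null_bins``, ``truth_bins`` (planted
    with either sign), ``mixed_bins`` (ambiguous) and the metabolite × bin
    ``share`` matrix.
    """
    if isinstance(source, CohortDesign):
        panel, design = source.panel, source
        sf_mhz = source.sf_mhz
    else:
        panel, design = source, None
    midx, centers, gammas, areas = _line_table(panel, sf_mhz)
    edges = np.asarray(bin_edges, dtype=float).reshape(-1, 2)
    n_bins = edges.shape[0]
    hi, lo = edges[:, 0], edges[:, 1]
    z_hi = (hi[None, :] - centers[:, None]) / gammas[:, None]
    z_lo = (lo[None, :] - centers[:, None]) / gammas[:, None]
    share = (np.arctan(z_hi) - np.arctan(z_lo)) / np.pi * areas[:, None]
    m = len(panel)
    metab_share = np.zeros((m, n_bins))
    np.add.at(metab_share, midx, share)
    base = np.array([e.base_concentration for e in panel])
    expected = metab_share * base[:, None]
    signs = panel.signs
    pos = expected[signs > 0].sum(axis=0) if (signs > 0).any() else np.zeros(n_bins)
    neg = expected[signs < 0].sum(axis=0) if (signs < 0).any() else np.zeros(n_bins)
    neu = expected[signs == 0].sum(axis=0) if (signs == 0).any() else np.zeros(n_bins)
    if design is not None:
        bg_centers, bg_gammas, bg_weights, bg_comp, bg_base = _background_table(design)
        if bg_centers.size:
            zb_hi = (hi[None, :] - bg_centers[:, None]) / bg_gammas[:, None]
            zb_lo = (lo[None, :] - bg_centers[:, None]) / bg_gammas[:, None]
            bshare = (np.arctan(zb_hi) - np.arctan(zb_lo)) / np.pi * bg_weights[:, None]
            neu = neu + (bg_base[bg_comp, None] * bshare).sum(axis=0)
    total = pos + neg + neu
    negligible = total < min_content * max(total.max(), 1e-300)
    total = np.maximum(total, 1e-300)
    fpos, fneg = pos / total, neg / total
    bin_signs = np.zeros(n_bins, dtype=int)
    bin_signs[(fpos >= dominance) & (fneg <= 0.1)] = 1
    bin_signs[(fneg >= dominance) & (fpos <= 0.1)] = -1
    bin_signs[negligible] = 0
    null_bins = ((fpos + fneg) <= null_max) | negligible
    truth_bins = bin_signs != 0
    mixed = ~truth_bins & ~null_bins
    return {
        "truth_bins": truth_bins,
        "bin_signs": bin_signs,
        "null_bins": null_bins,
        "mixed_bins": mixed,
        "share": metab_share,
    }


def cohort_to_binned(
    design: CohortDesign,
    bin_width_ppm: float = 0.04,
    noise_sd: float = 0.0,
    noise_floor: float = 0.05,
) -> BinnedMatrix:
    """Fast path: analytic uniform-bin integration, bypassing spectral synthesis.

    Bin areas come from the closed-form Lorentzian integral (arctan), using
    each sample's realized concentration × dilution — i.e. the noiseless
    expectation.  With ``noise_sd > 0``, bins additionally receive a small
    positive floor plus Gaussian noise (clipped positive), which makes the
    matrix usable directly in statistical studies that need non-degenerate
    null bins.  Ground-truth columns are flagged in ``metadata`` via
    :func:`flag_truth_bins` (``bin_signs``, ``null_bins``, ``mixed_bins``).
    """
    lo, hi, _ = design.axis
    if bin_width_ppm > hi - lo:
        raise ValueError("bin width exceeds the axis span")
    rng = np.random.default_rng(design.seed)
    labels, covariates, conc, dilution, bg_conc = _draw_concentrations(design, rng)
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width_ppm - 1e-9)))
    edges_asc = lo + bin_width_ppm * np.arange(n_bins + 1)
    edges_asc[-1] = hi
    # descending bin order to match the axis convention
    bin_edges = np.column_stack([edges_asc[1:], edges_asc[:-1]])[::-1]
    flags = flag_truth_bins(design, bin_edges)
    values = (conc * dilution[:, None]) @ flags["share"]
    bg_centers, bg_gammas, bg_weights, bg_comp, _ = _background_table(design)
    if bg_centers.size:
        z_hi = (bin_edges[:, 0][None, :] - bg_centers[:, None]) / bg_gammas[:, None]
        z_lo = (bin_edges[:, 1][None, :] - bg_centers[:, None]) / bg_gammas[:, None]
        bg_share = (np.arctan(z_hi) - np.arctan(z_lo)) / np.pi * bg_weights[:, None]
        values = values + (bg_conc[:, bg_comp] * dilution[:, None]) @ bg_share
    if noise_sd > 0:
        values = values + noise_floor + rng.normal(0.0, noise_sd, values.shape)
        np.clip(values, noise_floor * 1e-3, None, out=values)
    return BinnedMatrix(
        values,
        bin_edges,
        [f"s{i:03d}" for i in range(values.shape[0])],
        metadata={
            "truth_bins": flags["truth_bins"],
            "bin_signs": flags["bin_signs"],
            "null_bins": flags["null_bins"],
            "mixed_bins": flags["mixed_bins"],
            "labels": labels,
            "dilution": dilution,
            "covariates": covariates,
            "bin_width_ppm": bin_width_ppm,
        },
    )


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write spectra TSV (ppm + one column per sample), covariate CSV and
    truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ppm, mat, ids = _spectra_table(cohort.spectra)
    frame = pd.DataFrame(mat.T, columns=ids)
    frame.insert(0, "ppm", ppm)
    frame.to_csv(outdir / "spectra.tsv", sep="\t", index=False)
    cov = cohort.covariates.copy()
    cov.insert(0, "sample_id", ids)
    cov.to_csv(outdir / "samples.csv", index=False)
    truth = {
        "dilution": cohort.truth["dilution"].tolist(),
        "concentrations": cohort.truth["concentrations"].to_dict(orient="list"),
        "jitter_ppm": np.asarray(cohort.truth["jitter_ppm"]).tolist(),
    }
    (outdir / "truth.json").write_text(json.dumps(truth))


def read_cohort(outdir, design: CohortDesign = None) -> Cohort:
    outdir = Path(outdir)
    frame = pd.read_csv(outdir / "spectra.tsv", sep="\t")
    ppm = frame.pop("ppm").to_numpy()
    spectra = [Spectrum(ppm, frame[c].to_numpy(), sample_id=c) for c in frame.columns]
    cov = pd.read_csv(outdir / "samples.csv")
    cov = cov.set_index("sample_id").reset_index(drop=True)
    labels = cov["group"].to_numpy()
    truth_raw = json.loads((outdir / "truth.json").read_text())
    truth = {
        "dilution": np.asarray(truth_raw["dilution"]),
        "concentrations": pd.DataFrame(truth_raw["concentrations"]),
        "jitter_ppm": np.asarray(truth_raw["jitter_ppm"]),
    }
    return Cohort(spectra, labels, cov, truth, design)


def _spectra_table(spectra):
    from ..datatypes import stack_spectra

    return stack_spectra(spectra)
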