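"""End-to-end pipeline: synth → preprocess → URF → PLS-LDA → report.

Driven by a plain dict (or YAML file via the CLI) with optional sections
``synth``, ``preprocess``, ``urf``, ``plslda``; anything omitted uses the
package defaults.  Writes all result artifacts plus a provenance JSON into
the output directory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess, report, synth
from .plslda import PLSLDA, RdCVConfig, permutation_test
from .urf import URF, URFConfig

__all__ = ["run_pipeline", "preprocess_cohort"]


def preprocess_cohort(cohort, params: dict | None = None, provenance=None):
    """Spectra → analysis matrix: baseline, alignment, AI binning, region
    exclusion, PQN, log + auto-scaling.  Returns (matrix, scaled_matrix)."""
    p = dict(params or {})
    spectra = cohort.spectra
    if p.get("baseline", True):
        spectra = [
            preprocess.correct_baseline(
                s, p.get("baseline_smoothness", 1e7), p.get("baseline_asymmetry", 0.001)
            )
            for s in spectra
        ]
    if p.get("align", True):
        spectra = preprocess.align_spectra(
            spectra,
            max_shift_ppm=p.get("max_shift_ppm", 0.02),
            segment_ppm=p.get("segment_ppm", 0.12),
        )
    noise_region = tuple(p.get("noise_region", (9.5, 10.0)))
    matrix = preprocess.ai_binning(
        spectra, resolution_r=p.get("resolution_r", 0.5), noise_region=noise_region
    )
    # water/TSP windows plus the signal-free high-field edge
    excluded = p.get(
        "excluded_regions", preprocess.DEFAULT_EXCLUDED_REGIONS + [(9.3, 10.0)]
    )
    matrix = preprocess.exclude_regions(matrix, excluded)
    matrix.values[matrix.values < 0] = 0.0  # baseline overshoot guard
    normalized = preprocess.normalize_quotient(
        matrix,
        p.get("pqn_reference", "median"),
        quotient_band=p.get("pqn_quotient_band"),
    )
    scaled = preprocess.log_autoscale(normalized)
    if provenance is not None:
        provenance.log(
            "preprocess",
            n_bins=matrix.n_bins,
            noise_region=noise_region,
            resolution_r=p.get("resolution_r", 0.5),
            excluded=excluded,
        )
    return normalized, scaled


def run_pipeline(config: dict, outdir) -> dict:
    """Run the full analysis described by ``config``; returns key results."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = report.RunProvenance(config=config)
    seed = int(config.get("seed", 0))
    prov.seeds["master"] = seed

    scfg = dict(config.get("synth", {}))
    effect = scfg.pop("effect_size", synth.DEFAULT_EFFECT_SIZE)
    design = synth.CohortDesign(
        panel=synth.build_default_panel(effect_size=effect), seed=seed, **scfg
    )
    cohort = synth.simulate_cohort(design)
    synth.write_cohort(cohort, outdir / "cohort")
    prov.log("synth", n_workers=design.n_workers, n_residents=design.n_residents,
             effect_size=effect, axis=design.axis)

    normalized, scaled = preprocess_cohort(cohort, config.get("preprocess"), prov)
    normalized.to_csv(outdir / "binned.csv")
    scaled.to_csv(outdir / "binned_scaled.csv")

    ucfg_in = dict(config.get("urf", {}))
    ucfg = URFConfig(seed=seed, **ucfg_in)
    urf_res = URF(scaled, ucfg).fit()
    urf_res.dissimilarity.to_csv(outdir / "urf_dissimilarity.csv")
    emb = urf_res.pcoa(min(4, urf_res.dissimilarity.n - 1))
    screen = urf_res.confounder_screen(
        cohort.covariates, n_perm=int(config.get("confounder_permutations", 199)), seed=seed
    )
    screen.to_csv(outdir / "confounder_screen.csv")
    prov.log("urf", **{f: getattr(ucfg, f) for f in ucfg.__dataclass_fields__})

    pcfg_in = dict(config.get("plslda", {}))
    run_permutation = pcfg_in.pop("permutation_test", False)
    pcfg = RdCVConfig(seed=seed, **pcfg_in)
    model = PLSLDA.from_dataframe(scaled.to_frame(), cohort.labels, positive_class="worker")
    rd = model.rdcv(pcfg)
    if run_permutation:
        pt = permutation_test(model.X, model.y01, pcfg, observed=rd, model=model)
        pd.Series(pt.p_values).to_json(outdir / "permutation_pvalues.json")
    rd.metrics.to_csv(outdir / "rdcv_metrics.csv", index_label="repetition")
    stability = rd.sample_stability()
    stability.to_csv(outdir / "sample_stability.csv")
    selection = rd.select_variables()
    selection.frame.to_csv(outdir / "cv1_weights.csv")
    prov.log("plslda", **{f: getattr(pcfg, f) for f in pcfg.__dataclass_fields__})

    annotation = report.annotation_from_panel(design.panel)
    table = report.make_table2(selection, annotation, bin_edges=scaled.bin_edges)
    table.to_csv(outdir / "discriminant_metabolites.csv", index=False)
    final = model.fit(max(1, int(np.median(rd.components))))
    report.export_scoreplots(
        pcoa_result=emb,
        plslda_scores=final.canonical_scores,
        labels=cohort.labels,
        stability=stability.to_numpy(),
        sample_ids=model.sample_ids,
        outdir=outdir,
    )
    prov.to_json(outdir / "provenance.json")
    return {
        "design": design,
        "cohort": cohort,
        "scaled": scaled,
        "urf": urf_res,
        "pcoa": emb,
        "confounders": screen,
        "rdcv": rd,
        "selection": selection,
        "table": table,
    }
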