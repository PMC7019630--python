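"""End-to-end pipeline orchestration and plot-ready exports.

``run_pipeline`` chains (optional) cohort simulation, repeated double
cross-validation, the label-permutation test and a final full-data PLS-DA
model with VIP-based discriminant-analyte selection into a single
schema-versioned report.  The report is pure data — JSON with TSV side
exports — so score plots and null-distribution histograms can be rendered
by any plotting front end.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import plsda, validation
from .synthetic_cohort import Dataset, _TOKEN_OF

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"


@dataclass
class PipelineConfig:
    """All knobs of a full pipeline run; echoed verbatim into the report."""

    dcv: validation.DCVConfig = field(default_factory=validation.DCVConfig)
    permutations: int = 1000
    permutation_repetitions: int = 5
    histogram_bins: int = 20

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "k_outer": self.dcv.k_outer,
            "k_inner": self.dcv.k_inner,
            "repetitions": self.dcv.repetitions,
            "max_components": self.dcv.max_components,
            "seed": self.dcv.seed,
            "threshold": self.dcv.threshold,
            "permutations": self.permutations,
            "permutation_repetitions": self.permutation_repetitions,
            "histogram_bins": self.histogram_bins,
        }


def export_scores_plot(model: plsda.PLSModel, dataset: Dataset) -> pd.DataFrame:
    """Per-sample coordinates on the first two latent variables.

    Requires a model with at least two components; the result is the data
    behind the familiar LV1/LV2 scores plot.
    """
    if model.n_components < 2:
        raise ValueError("scores plot needs a model with >= 2 components")
    T = plsda.pls_transform(model, dataset.X)
    return pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "class": [_TOKEN_OF[v] for v in dataset.y],
            "lv1": T[:, 0],
            "lv2": T[:, 1],
        }
    )


def export_null_histograms(
    perm: validation.PermutationResult, bins: int = 20
) -> pd.DataFrame:
    """Binned null distributions for NMC / AUROC / DQ2 plus observed markers.

    One tidy row per bin and statistic; counts per statistic sum to B and
    empty bins are preserved.  The observed value is repeated on every row
    of its statistic so the table is self-contained.
    """
    if perm.B < 1:
        raise ValueError("permutation result is empty")
    pieces = []
    for name, null, observed in (
        ("nmc", perm.null_nmc, perm.observed_nmc),
        ("auroc", perm.null_auroc, perm.observed_auroc),
        ("dq2", perm.null_dq2, perm.observed_dq2),
    ):
        lo, hi = float(null.min()), float(null.max())
        if lo == hi:  # degenerate null: single-bin histogram
            hi = lo + 1e-9
        counts, edges = np.histogram(null, bins=bins, range=(lo, hi))
        pieces.append(
            pd.DataFrame(
                {
                    "statistic": name,
                    "bin_left": edges[:-1],
                    "bin_right": edges[1:],
                    "count": counts,
                    "observed": observed,
                }
            )
        )
    return pd.concat(pieces, ignore_index=True)


@dataclass
class RunReport:
    """Complete, reproducible record of one pipeline run."""

    config: PipelineConfig
    dcv_summary: dict
    permutation: validation.PermutationResult
    selected_components: int
    vip_result: plsda.VIPResult
    scores: pd.DataFrame
    null_histograms: pd.DataFrame
    stage_log: list[dict]

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "config": self.config.to_dict(),
            "dcv": self.dcv_summary,
            "permutation": self.permutation.to_dict(),
            "final_model": {
                "n_components": self.selected_components,
                "vip": {
                    name: float(v)
                    for name, v in zip(
                        self.vip_result.analyte_names, self.vip_result.vip
                    )
                },
                "discriminant_set": self.vip_result.discriminant_set,
            },
            "scores": self.scores.to_dict(orient="list"),
            "null_histograms": self.null_histograms.to_dict(orient="list"),
            "stage_log": self.stage_log,
        }

    def write(self, outdir: str | Path) -> None:
        """Write report.json plus vip.tsv, scores.tsv and null_hist.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(self.to_dict(), indent=1))
        self.vip_result.to_frame().to_csv(
            outdir / "vip.tsv", sep="\t", index=False
        )
        self.scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
        self.null_histograms.to_csv(
            outdir / "null_hist.tsv", sep="\t", index=False
        )


def run_pipeline(dataset: Dataset, config: PipelineConfig | None = None) -> RunReport:
    """Run DCV → permutation test → final model + VIP on one dataset.

    The final model's complexity is chosen by the same inner-CV criterion
    as inside the DCV, applied once to the full dataset; the model is then
    refitted on all samples for VIP inspection and the scores plot (a
    two-component fit is used for the plot when one component suffices for
    classification).
    """
    if config is None:
        config = PipelineConfig()
    log: list[dict] = []

    def _stage(name: str, started: float, **extra) -> None:
        entry = {"stage": name, "seconds": round(time.perf_counter() - started, 3)}
        entry.update(extra)
        log.append(entry)
        logger.info("stage %s finished in %.3fs %s", name, entry["seconds"], extra)

    t0 = time.perf_counter()
    dcv_result = validation.double_cv(dataset, config.dcv)
    _stage("double_cv", t0, seed=config.dcv.seed)

    t0 = time.perf_counter()
    perm = validation.permutation_test(
        dataset,
        config.dcv,
        config.permutations,
        permutation_repetitions=config.permutation_repetitions,
        observed=dcv_result,
    )
    _stage("permutation_test", t0, B=config.permutations)

    t0 = time.perf_counter()
    rng = np.random.default_rng(np.random.SeedSequence((config.dcv.seed, 1)))
    a_final = validation.select_components_inner(
        dataset.X, dataset.y, config.dcv, rng
    )
    model = plsda.pls_fit(
        dataset.X,
        dataset.y,
        a_final,
        threshold=config.dcv.threshold,
        analyte_names=dataset.analyte_names,
    )
    vip_result = plsda.vip(model)
    scores_model = (
        model
        if model.n_components >= 2
        else plsda.pls_fit(
            dataset.X, dataset.y, 2, threshold=config.dcv.threshold,
            analyte_names=dataset.analyte_names,
        )
    )
    scores = export_scores_plot(scores_model, dataset)
    _stage("final_model", t0, n_components=a_final)

    hist = export_null_histograms(perm, config.histogram_bins)
    return RunReport(
        config=config,
        dcv_summary=dcv_result.summary(),
        permutation=perm,
        selected_components=a_final,
        vip_result=vip_result,
        scores=scores,
        null_histograms=hist,
        stage_log=log,
    )
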