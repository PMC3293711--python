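"""End-to-end comparison pipeline: simulate -> normalize -> evaluate -> enrich.

Mirrors the study design of the normalization comparison: every requested
method is applied to the same experiment, the control-vs-promoter
separation is measured per array and on the combined data, and the
sliding-window enrichment finder is run on the combined normalized
log-ratios, reporting region counts at several p-value cut-offs.
Deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ExperimentSet, MAMatrix, compute_ma, write_experiment
from .enrich import EnrichmentParams, count_regions, enrichment_pvalues
from .evaluate import separation_report
from .normalize import NormalizationMethod, normalize
from .simulate import SimulationConfig, SyntheticTruth, simulate_experiment, write_truth

__all__ = ["PipelineConfig", "ComparisonReport", "run_comparison"]

logger = logging.getLogger("regnorm")

ALL_METHODS = tuple(m.value for m in NormalizationMethod)
DEFAULT_ALPHAS = (0.05, 0.10, 0.20, 0.50)


@dataclass
class PipelineConfig:
    """Configuration of a full comparison run.

    Either ``simulation`` (a :class:`SimulationConfig`) or ``input_dir``
    (a directory of pair files plus annotation.tsv) supplies the data.
    """

    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    methods: Sequence[str] = ALL_METHODS
    alphas: Sequence[float] = DEFAULT_ALPHAS
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    output_dir: str | None = None
    seed: int | None = None

    def validate(self) -> None:
        if not self.methods:
            raise ValueError("at least one normalization method is required")
        for m in self.methods:
            NormalizationMethod(m)  # raises on unknown
        if (self.simulation is None) == (self.input_dir is None):
            raise ValueError("exactly one of simulation/input_dir must be given")
        self.enrichment.validate()


@dataclass
class ComparisonReport:
    separation: pd.DataFrame
    region_counts: pd.DataFrame
    qc: pd.DataFrame
    normalized: dict[str, MAMatrix]
    truth: SyntheticTruth | None


def _qc_summary(experiment: ExperimentSet, ma: MAMatrix) -> pd.DataFrame:
    rows = []
    for j, arr in enumerate(experiment.arrays):
        rows.append(
            {
                "array": arr.array_id,
                "green_median": float(np.median(arr.green)),
                "red_median": float(np.median(arr.red)),
                "m_median": float(np.median(ma.M[:, j])),
                "m_sd": float(ma.M[:, j].std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)


def run_comparison(config: PipelineConfig) -> ComparisonReport:
    """Run the full normalization comparison described by ``config``.

    Stages: (1) simulate or load the experiment; (2) apply every requested
    normalization; (3) separation report (per-array + combined ROC/AUC,
    density summaries) for raw data and every method; (4) sliding-window
    enrichment on the combined (across-array mean) normalized log-ratios
    with region counts at each alpha; (5) per-array QC summaries.  When
    ``output_dir`` is set, normalized matrices (TSV), the reports (TSV)
    and a machine-readable JSON summary are written there.
    """
    config.validate()
    truth = None
    if config.simulation is not None:
        sim = config.simulation
        if config.seed is not None:
            sim = dataclasses.replace(sim, seed=config.seed)
        logger.info("simulate: seed=%d arrays=%d", sim.seed, sim.n_arrays)
        experiment, truth = simulate_experiment(sim)
    else:
        from .core import read_experiment_dir

        logger.info("load: %s", config.input_dir)
        experiment = read_experiment_dir(config.input_dir)

    annotation = experiment.annotation
    raw = compute_ma(experiment)
    normalized: dict[str, MAMatrix] = {}
    for name in config.methods:
        logger.info("normalize: method=%s", name)
        try:
            normalized[name] = normalize(experiment, name).as_ma()
        except Exception as exc:
            raise RuntimeError(f"stage normalize[{name}] failed: {exc}") from exc

    by_method = {"raw": raw, **normalized}
    logger.info("evaluate: %d methods", len(by_method))
    separation = separation_report(annotation, by_method)

    region_rows = []
    for name, ma in by_method.items():
        combined_m = ma.M.mean(axis=1)
        result = enrichment_pvalues(annotation, combined_m, config.enrichment)
        counts = count_regions(result, config.alphas)
        for alpha, count in counts.items():
            region_rows.append({"method": name, "alpha": alpha, "n_regions": count})
    region_counts = pd.DataFrame(region_rows)

    qc = _qc_summary(experiment, raw)
    report = ComparisonReport(
        separation=separation,
        region_counts=region_counts,
        qc=qc,
        normalized=normalized,
        truth=truth,
    )

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_report(outdir, config, experiment, report)
    return report


def _float_fmt(x: float) -> str:
    return f"{x:.10g}"


def _write_report(
    outdir: Path,
    config: PipelineConfig,
    experiment: ExperimentSet,
    report: ComparisonReport,
) -> None:
    report.separation.to_csv(
        outdir / "separation_report.tsv", sep="\t", index=False, float_format="%.10g"
    )
    report.region_counts.to_csv(
        outdir / "region_counts.tsv", sep="\t", index=False, float_format="%.10g"
    )
    report.qc.to_csv(outdir / "qc_summary.tsv", sep="\t", index=False, float_format="%.10g")
    for name, ma in report.normalized.items():
        frame = pd.DataFrame(
            np.column_stack([ma.M, ma.A]),
            columns=[f"M_{a}" for a in ma.array_ids] + [f"A_{a}" for a in ma.array_ids],
        )
        frame.insert(0, "probe_id", experiment.annotation.probe_id)
        frame.to_csv(outdir / f"normalized_{name}.tsv", sep="\t", index=False, float_format="%.10g")
    combined = report.separation[report.separation["array"] == "combined"]
    summary = {
        "methods": list(config.methods),
        "seed": config.seed if config.seed is not None else (
            config.simulation.seed if config.simulation else None
        ),
        "combined_auc": {
            r["method"]: round(float(r["auc"]), 10) for _, r in combined.iterrows()
        },
        "region_counts": {
            m: {
                _float_fmt(a): int(c)
                for a, c in zip(
                    report.region_counts[report.region_counts["method"] == m]["alpha"],
                    report.region_counts[report.region_counts["method"] == m]["n_regions"],
                )
            }
            for m in report.region_counts["method"].unique()
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
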