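"""End-to-end analysis pipeline: generate/load -> score -> align -> PCA ->
variability -> association and group comparison, with reproducible outputs.

`run_pipeline` executes every stage and writes five report CSVs plus a run
manifest into the output directory:

* ``adherence.csv`` — per-cohort adherence curve (median/IQR per window)
* ``loadings.csv`` — pooled Mood Zoom PCA loadings and variance rows
* ``association.csv`` — Spearman matrix of weekly measures vs MZ summaries
* ``summary_comparison.csv`` — per-variable cohort medians and Wilcoxon p's
* ``variability_comparison.csv`` — same layout for the variability statistics
* ``manifest.yaml`` — config echo, package/library versions and seed

Re-running with the same configuration reproduces byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .inference import (
    association_table,
    comparison_table,
    participant_summary_values,
    participant_variability_values,
)
from .latent import fit_mz_pca
from .synthetic import StudyConfig, default_presets, generate_study, load_config
from .timeline import adherence_curve, read_study

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run.

    Exactly one input source: either the three CSV paths, or a generator
    `StudyConfig` (``generator``).  The remaining fields surface the
    analysis choices that are genuinely open: alignment method, PCA matrix,
    entropy log base, TKEO variant, gap rule and significance level.
    """

    output_dir: str = "moodkit_out"
    daily_csv: str | None = None
    weekly_csv: str | None = None
    cohorts_csv: str | None = None
    generator: StudyConfig | None = None
    alignment_method: str = "mean_prev_week"
    pca_method: str = "covariance"
    entropy_base: float | None = None
    tkeo_variant: str = "standard"
    max_gap_days: int | None = None
    alpha: float = 0.05
    strict: bool = True
    seed: int = 0

    def __post_init__(self):
        paths = (self.daily_csv, self.weekly_csv, self.cohorts_csv)
        has_paths = all(p is not None for p in paths)
        some_paths = any(p is not None for p in paths)
        if self.generator is not None and some_paths:
            raise ValueError("supply either input CSVs or a generator config, "
                             "not both")
        if self.generator is None and not has_paths:
            raise ValueError("supply all three input CSVs "
                             "(daily, weekly, cohorts) or a generator config")

    def manifest(self) -> dict:
        import numpy
        import scipy

        doc = dataclasses.asdict(self)
        if self.generator is not None:
            doc["generator"] = {
                "seed": self.generator.seed,
                "weekly_prompt_weekday": self.generator.weekly_prompt_weekday,
                "cohorts": [dataclasses.asdict(c) for c in self.generator.cohorts],
            }
        doc["versions"] = {
            "moodkit": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        }
        return doc


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            logger.info("stage %s", name)
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns output paths.

    Any stage error raises `PipelineError` naming the stage; nothing is
    written silently on failure.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("moodkit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        if config.generator is not None:
            study = _stage("generate")(generate_study, config.generator)
            timelines = study.timelines
        else:
            timelines = _stage("read")(
                read_study, config.daily_csv, config.weekly_csv,
                config.cohorts_csv, strict=config.strict)
        logger.info("participants in: %d", len(timelines))

        adherence = _stage("adherence")(adherence_curve, timelines)
        loadings = _stage("pca")(fit_mz_pca, timelines, config.pca_method)
        association = _stage("association")(
            association_table, timelines, loadings, config.alignment_method)
        summaries = _stage("summaries")(
            participant_summary_values, timelines, loadings)
        summary_cmp = _stage("summary_comparison")(
            comparison_table, summaries, alpha=config.alpha)
        var_values = _stage("variability")(
            participant_variability_values, timelines, loadings,
            max_gap_days=config.max_gap_days, tkeo_variant=config.tkeo_variant,
            entropy_base=config.entropy_base)
        var_cmp = _stage("variability_comparison")(
            comparison_table, var_values, alpha=config.alpha)
        logger.info("aligned association cells: %d; comparison tests: %d",
                    len(association), summary_cmp.attrs.get("n_tests", 0)
                    + var_cmp.attrs.get("n_tests", 0))

        paths = {}
        float_fmt = "%.6g"
        for name, frame in [
            ("adherence", adherence),
            ("loadings", loadings.to_frame().reset_index(names="item")),
            ("association", association),
            ("summary_comparison", summary_cmp),
            ("variability_comparison", var_cmp),
        ]:
            path = out / f"{name}.csv"
            frame.to_csv(path, index=False, float_format=float_fmt)
            paths[name] = str(path)
        manifest_path = out / "manifest.yaml"
        with open(manifest_path, "w") as fh:
            yaml.safe_dump(config.manifest(), fh, sort_keys=False)
        paths["manifest"] = str(manifest_path)
        paths["log"] = str(log_path)
        return paths
    finally:
        root.removeHandler(handler)
        handler.close()


def demo_config(output_dir="moodkit_out", seed=0, **preset_kwargs) -> PipelineConfig:
    """Pipeline configuration running the bundled synthetic presets."""
    return PipelineConfig(output_dir=output_dir, seed=seed,
                          generator=default_presets(seed=seed, **preset_kwargs))


def config_from_yaml(path) -> PipelineConfig:
    """Load a PipelineConfig from YAML (generator given inline or by path)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    gen = doc.pop("generator", None)
    if isinstance(gen, str):
        generator = load_config(gen)
    elif isinstance(gen, dict):
        from .synthetic import CohortParams

        generator = StudyConfig(
            cohorts=[CohortParams(**c) for c in gen["cohorts"]],
            seed=int(gen.get("seed", 0)),
            weekly_prompt_weekday=int(gen.get("weekly_prompt_weekday", 0)),
        )
    else:
        generator = None
    doc.pop("versions", None)
    return PipelineConfig(generator=generator, **doc)
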