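"""End-to-end orchestration of the linkage stages.

Stage order: simulate (optional) -> preprocess -> index -> link (retrieve
+ score + assign) -> sample -> label -> ROC/threshold -> classify ->
evaluate.  Every stage is re-runnable from persisted CSV intermediates;
a fixed seed makes the whole run reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .evaluation import (
    TruthMetrics,
    compare_characteristics,
    linkage_rate_by_year,
    truth_metrics,
)
from .index_search import build_index
from .linkage import AttributeWeights, ComparisonPair, LinkDecision, link_registers
from .preprocess import standardize_name
from .synthgen import GeneratorConfig, generate_population
from .threshold import (
    ThresholdModel,
    attach_labels,
    build_roc,
    choose_threshold,
    classify_links,
    stratify_sample,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "LinkageResult", "run_linkage_stage", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Structured configuration for a full run (YAML-serializable)."""

    era: str = "auto"  # auto | dob | age
    k: int = 1000
    dl_floor: float = 0.5
    sample_size: int = 2000
    strata_bounds: tuple[float, float] = (0.90, 0.95)
    seed: int = 0
    weights: AttributeWeights = field(default_factory=AttributeWeights)
    generator: GeneratorConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("era", "k", "dl_floor", "sample_size", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "strata_bounds" in raw:
            kwargs["strata_bounds"] = tuple(raw["strata_bounds"])
        if "weights" in raw:
            kwargs["weights"] = AttributeWeights(**raw["weights"])
        if "generator" in raw:
            gen = dict(raw["generator"])
            if "year_range" in gen:
                gen["year_range"] = tuple(gen["year_range"])
            kwargs["generator"] = GeneratorConfig(**gen)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "era": self.era,
            "k": self.k,
            "dl_floor": self.dl_floor,
            "sample_size": self.sample_size,
            "strata_bounds": list(self.strata_bounds),
            "seed": self.seed,
            "weights": {
                "name": self.weights.name,
                "mother_dob_or_age": self.weights.mother_dob_or_age,
                "state": self.weights.state,
                "municipality": self.weights.municipality,
            },
        }
        if self.generator is not None:
            g = self.generator
            raw["generator"] = {
                "n_cohort": g.n_cohort, "n_births": g.n_births,
                "overlap_fraction": g.overlap_fraction, "typo_rate": g.typo_rate,
                "missing_mother_dob_rate": g.missing_mother_dob_rate,
                "municipality_mismatch_rate": g.municipality_mismatch_rate,
                "covariate_missing_rate": g.covariate_missing_rate,
                "age_perturb_rate": g.age_perturb_rate,
                "year_range": list(g.year_range), "seed": g.seed,
            }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class LinkageResult:
    """Everything one linkage run produces."""

    pairs: list[ComparisonPair]
    assignments: list[LinkDecision]
    decisions: list[LinkDecision]  # post-threshold
    model: ThresholdModel
    metrics: TruthMetrics | None
    linked_pct: float
    rate_table: pd.DataFrame | None = None


def standardize_registers(
    births: pd.DataFrame, cohort: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply name standardization to both registers (idempotent)."""
    births = births.copy()
    cohort = cohort.copy()
    births["mother_name"] = births["mother_name"].astype(str).map(standardize_name)
    cohort["name"] = cohort["name"].astype(str).map(standardize_name)
    return births, cohort


def run_linkage_stage(
    births: pd.DataFrame,
    cohort: pd.DataFrame,
    truth: pd.DataFrame | None = None,
    review: pd.DataFrame | None = None,
    era: str = "auto",
    weights: AttributeWeights = AttributeWeights(),
    k: int = 1000,
    dl_floor: float = 0.5,
    sample_size: int = 2000,
    strata_bounds: tuple[float, float] = (0.90, 0.95),
    seed: int = 0,
) -> LinkageResult:
    """Index, link, select a threshold and classify in one call.

    Labels for threshold selection come from ``truth`` (synthetic runs)
    or ``review``.  If the labeled sample ends up single-class (e.g. a
    noise-free run where every potential link is true), the threshold
    degenerates to the minimum assigned score and is flagged on the
    model.
    """
    births, cohort = standardize_registers(births, cohort)
    index = build_index(cohort)
    pairs, assignments = link_registers(
        births, cohort, index, weights=weights, era=era, k=k, dl_floor=dl_floor
    )
    sample = stratify_sample(
        assignments, sample_size=sample_size, bounds=strata_bounds, seed=seed
    )
    sample = attach_labels(sample, truth=truth, review=review)
    try:
        model = choose_threshold(build_roc(sample))
    except ValueError:
        # single-class sample: no ROC; fall back to the minimum assigned score
        scores = [a.score for a in assignments if a.cohort_id is not None]
        model = ThresholdModel(
            fpr=None, tpr=None, thresholds=None,
            auc=float("nan"), threshold=min(scores), degenerate=True,
        )
        logger.warning(
            "labeled sample is single-class; threshold degenerates to %.4f",
            model.threshold,
        )
    decisions = classify_links(assignments, model.threshold)
    n_linked = sum(1 for d in decisions if d.classification == "link")
    linked_pct = 100.0 * n_linked / len(decisions) if decisions else 0.0
    metrics = truth_metrics(decisions, truth) if truth is not None else None
    rate_table = None
    if "birth_year" in births.columns:
        years = dict(zip(births["birth_id"].astype(str), births["birth_year"]))
        rate_table = linkage_rate_by_year(decisions, years)
    return LinkageResult(
        pairs=pairs,
        assignments=assignments,
        decisions=decisions,
        model=model,
        metrics=metrics,
        linked_pct=linked_pct,
        rate_table=rate_table,
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> LinkageResult:
    """Full pipeline from a structured config; artifacts land in ``outdir``.

    With a ``generator`` section the registers are simulated first;
    the config is echoed into the output directory for provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.generator is None:
        raise ValueError("run_pipeline requires a generator section (or use the CLI stages on existing files)")
    births, cohort, truth = generate_population(config.generator)
    births.to_csv(outdir / "births.csv", index=False)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    truth.to_csv(outdir / "truth.csv", index=False)

    result = run_linkage_stage(
        births, cohort, truth,
        era=config.era, weights=config.weights, k=config.k,
        dl_floor=config.dl_floor, sample_size=config.sample_size,
        strata_bounds=config.strata_bounds, seed=config.seed,
    )
    pd.DataFrame(
        [
            {"birth_id": d.birth_id, "cohort_id": d.cohort_id or "",
             "score": d.score, "classification": d.classification}
            for d in result.decisions
        ]
    ).to_csv(outdir / "decisions.csv", index=False)
    if result.rate_table is not None:
        result.rate_table.to_csv(outdir / "linkage_rates.csv", index=False)
    covs = ["race", "zone", "water_supply", "sewage", "garbage"]
    compare_characteristics(result.decisions, births, covs).to_csv(
        outdir / "bias_report.csv", index=False
    )
    config.to_yaml(outdir / "config_used.yaml")
    return result
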