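"""End-to-end introgression workflow.

Runs the full analysis in order: duplicate removal, per-population
diversity, wild/hatchery centroid simulation, simulated-F1 threshold
calibration, per-individual p(wild) assignment, three-way classification,
an optional hybrid-category cross-check and an optional environmental
model.  Every stage is a pure function of (inputs, config, seed); stage
outputs are written as CSV/JSON under the configured output directory and
a plain-text log records seeds and profile choices.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .admixture import AdmixtureConfig, batch_assign
from .genotypes import GenotypeTable, find_duplicates, read_genotypes
from .hybrids import (HybridClassModel, categorize_and_compare,
                      estimate_class_posterior)
from .mating import CentroidSpec, build_centroids
from .popgen import allele_frequencies, summarize_diversity
from .envmodel import compare_and_average, fit_candidate_models
from .thresholds import calibrate_thresholds, classify_individuals

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """Everything one run needs; see the CLI for the YAML equivalent."""

    genotypes: str | None = None          # path, or None when table given
    format: str = "genepop"
    output_dir: str = "hatchtrace_out"
    seed: int = 0
    centroid: CentroidSpec = field(default_factory=CentroidSpec)
    admixture: AdmixtureConfig = field(default_factory=AdmixtureConfig.desk)
    n_f1: int = 100
    ranks: tuple = (2.5, 97.5)
    min_shared_loci: int = 1
    run_hybrids: bool = False
    hybrid_model: HybridClassModel = field(default_factory=HybridClassModel.desk)
    run_glmm: bool = False
    covariates: str | None = None         # CSV path with a `site` column
    model_sets: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        kw = dict(raw or {})
        if "centroid" in kw:
            kw["centroid"] = CentroidSpec(**kw["centroid"])
        if "admixture" in kw:
            kw["admixture"] = AdmixtureConfig(**kw["admixture"])
        if "hybrid_model" in kw:
            kw["hybrid_model"] = HybridClassModel(**kw["hybrid_model"])
        if "ranks" in kw:
            kw["ranks"] = tuple(kw["ranks"])
        return cls(**kw)


def run_pipeline(
    config: PipelineConfig,
    table: GenotypeTable | None = None,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Execute all stages; returns the result bundle as a dict.

    ``table`` (and ``covariates``) may be passed directly instead of the
    configured paths.  Partial outputs are retained on failure.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"hatchtrace {__version__}",
        f"seed {config.seed}",
        f"admixture burn_in={config.admixture.burn_in} "
        f"sweeps={config.admixture.sweeps}",
        f"started {time.strftime('%Y-%m-%d %H:%M:%S')}",
    ]
    results: dict = {}
    rng = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(s.generate_state(1)[0]) & 0x7FFFFFFF
        for name, s in zip(
            ("centroid", "calibration", "assignment", "hybrids"), rng.spawn(4)
        )
    }

    def stage(name):
        def deco(fn):
            try:
                t0 = time.time()
                fn()
                log_lines.append(f"stage {name}: ok ({time.time() - t0:.1f}s)")
            except Exception as exc:
                log_lines.append(f"stage {name}: FAILED ({exc})")
                (out / "run.log").write_text("\n".join(log_lines) + "\n")
                raise PipelineError(name, exc) from exc
        return deco

    @stage("load")
    def _load():
        nonlocal table
        if table is None:
            if config.genotypes is None:
                raise ValueError("no genotype table or path provided")
            table = read_genotypes(config.genotypes, config.format)
        results["n_input"] = len(table)
        # individuals typed at fewer than half their loci are flagged (and
        # retained); heavy missingness weakens their assignment
        frac = table.missing_fraction()
        flagged = [
            ind for ind, f in zip(table.individuals, frac) if f > 0.5
        ]
        if flagged:
            log_lines.append(
                f"flagged {len(flagged)} individuals with >50% missing loci: "
                + ", ".join(flagged[:10])
                + ("..." if len(flagged) > 10 else "")
            )
        results["high_missingness"] = flagged

    @stage("dedupe")
    def _dedupe():
        nonlocal table
        pairs = find_duplicates(table, config.min_shared_loci)
        drop = {b for _, b in pairs}
        if drop:
            keep = [i for i, ind in enumerate(table.individuals)
                    if ind not in drop]
            table = table.subset(np.array(keep))
        results["duplicates_removed"] = sorted(drop)

    @stage("diversity")
    def _diversity():
        div = summarize_diversity(table)
        div.to_csv(out / "diversity.csv")
        results["diversity"] = div

    @stage("centroids")
    def _centroids():
        spec = dataclasses.replace(config.centroid, seed=seeds["centroid"])
        wild, hatch, manifest = build_centroids(table, spec)
        results["wild_centroid"] = wild
        results["hatchery_centroid"] = hatch
        results["centroid_manifest"] = manifest
        (out / "centroid_manifest.json").write_text(
            json.dumps(manifest, indent=2)
        )

    @stage("calibrate")
    def _calibrate():
        wild_pool = allele_frequencies(
            table.for_group("wild"), "pooled"
        )
        hatch_pool = allele_frequencies(
            table.for_group("hatchery"), "pooled"
        )
        cal = calibrate_thresholds(
            wild_pool, hatch_pool, config.n_f1,
            results["wild_centroid"], results["hatchery_centroid"],
            dataclasses.replace(config.admixture, seed=seeds["calibration"]),
            ranks=config.ranks,
        )
        cal.to_json(out / "calibration.json")
        results["calibration"] = cal

    @stage("assign")
    def _assign():
        res = batch_assign(
            table, results["wild_centroid"], results["hatchery_centroid"],
            dataclasses.replace(config.admixture, seed=seeds["assignment"]),
        )
        results["assignments"] = res

    @stage("classify")
    def _classify():
        frame, by_pop = classify_individuals(
            results["assignments"], results["calibration"]
        )
        div = results["diversity"]
        summary = div.join(by_pop.drop(columns="n"), how="left")
        frame.to_csv(out / "assignments.csv", index=False)
        summary.to_csv(out / "summary.csv")
        results["classification"] = frame
        results["summary"] = summary

    if config.run_hybrids:
        @stage("hybrids")
        def _hybrids():
            post = estimate_class_posterior(
                table, results["wild_centroid"], results["hatchery_centroid"],
                config.hybrid_model, seed=seeds["hybrids"],
            )
            comp = categorize_and_compare(post, results["assignments"])
            post.probabilities.to_csv(out / "hybrid_classes.csv")
            comp["crosstab"].to_csv(out / "hybrid_consensus.csv")
            results["hybrid_posterior"] = post
            results["hybrid_consensus"] = comp

    if config.run_glmm:
        @stage("glmm")
        def _glmm():
            nonlocal covariates
            if covariates is None:
                covariates = pd.read_csv(config.covariates)
            cls = results["classification"]
            groups = pd.Series(list(table.group), index=table.individuals)
            frame = cls[cls["individual"].map(groups) == "wild"]
            # hatchery-assigned wild-caught fish are excluded before fitting
            frame = frame[frame["label"] != "hatchery"]
            data = pd.DataFrame({
                "site": frame["population"].to_numpy(),
                "introgressed": (frame["label"] == "introgressed").astype(int),
            })
            models = fit_candidate_models(
                data, covariates, model_sets=config.model_sets
            )
            comp = compare_and_average(models)
            comp.table.to_csv(out / "model_comparison.csv")
            comp.consensus.to_csv(out / "consensus_coefficients.csv")
            results["glmm_models"] = models
            results["glmm_comparison"] = comp

    log_lines.append(f"finished {time.strftime('%Y-%m-%d %H:%M:%S')}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return results
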