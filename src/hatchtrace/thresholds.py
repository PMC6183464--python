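"""Simulated-F1 threshold calibration and three-way classification.

The classifier needs p(wild) cutoffs that mark the range characteristic of
a first-generation wild x hatchery cross.  They are calibrated by
simulating F1 individuals between the pooled wild and pooled hatchery
frequency pools, estimating p(wild) for each against the two centroids
exactly as for real fish, and taking empirical percentiles (2.5 and 97.5 by
default, linear-interpolation rule) of that sample.  A fish whose p(wild)
falls inside ``[t_lo, t_hi]`` (boundaries inclusive) is classified
introgressed; below is hatchery, above is wild.

``evaluate_error_rate`` repeats the classification on a table with known
ancestry labels to measure, per percentile-rank pair, the fraction of truly
introgressed fish missed, the fraction of pure fish wrongly called
introgressed, and the overall error.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .admixture import AdmixtureConfig, AssignmentResult, batch_assign
from .genotypes import GenotypeTable
from .mating import SimulatedCohort, simulate_random_mating
from .popgen import PopulationFrequencies

__all__ = [
    "ThresholdCalibration", "calibrate_thresholds", "classify_individuals",
    "evaluate_error_rate",
]

PERCENTILE_RULE = "linear"   # numpy 'linear' interpolation between order stats


@dataclass
class ThresholdCalibration:
    """The simulated-F1 p(wild) sample and its derived cutoffs."""

    p_wild_sample: np.ndarray
    lower_rank: float
    upper_rank: float
    t_lo: float
    t_hi: float
    seed: int | None = None
    percentile_rule: str = PERCENTILE_RULE

    def recompute(self, ranks: tuple[float, float] | None = None):
        """Cutoffs for (possibly different) ranks from the stored sample."""
        lo, hi = ranks if ranks is not None else (self.lower_rank, self.upper_rank)
        t_lo, t_hi = np.percentile(
            self.p_wild_sample, [lo, hi], method=self.percentile_rule
        )
        return float(t_lo), float(t_hi)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "p_wild_sample": self.p_wild_sample.tolist(),
            "lower_rank": self.lower_rank,
            "upper_rank": self.upper_rank,
            "t_lo": self.t_lo,
            "t_hi": self.t_hi,
            "seed": self.seed,
            "percentile_rule": self.percentile_rule,
        }, indent=2))

    @classmethod
    def from_json(cls, path) -> "ThresholdCalibration":
        d = json.loads(Path(path).read_text())
        d["p_wild_sample"] = np.asarray(d["p_wild_sample"])
        return cls(**d)


def simulate_f1_sample(
    wild_pool: PopulationFrequencies,
    hatchery_pool: PopulationFrequencies,
    n_f1: int,
    wild_centroid: SimulatedCohort,
    hatchery_centroid: SimulatedCohort,
    config: AdmixtureConfig,
) -> np.ndarray:
    """p(wild) estimates for ``n_f1`` simulated wild x hatchery F1 crosses,
    each run against the centroids like any sampled fish."""
    if wild_pool.loci != hatchery_pool.loci:
        raise ValueError("pools must share loci")
    if wild_pool.loci != wild_centroid.table.loci:
        raise ValueError("pools and centroids must share loci")
    rng = np.random.SeedSequence(config.seed)
    sim_seed, assign_seed = [
        int(s.generate_state(1)[0]) & 0x7FFFFFFF for s in rng.spawn(2)
    ]
    f1 = simulate_random_mating(
        wild_pool, hatchery_pool, n_f1, seed=sim_seed, label="sim_f1"
    )
    results = batch_assign(
        f1.table, wild_centroid, hatchery_centroid,
        dataclasses.replace(config, seed=assign_seed),
    )
    return np.array([r.p_wild for r in results])


def calibrate_thresholds(
    wild_pool: PopulationFrequencies,
    hatchery_pool: PopulationFrequencies,
    n_f1: int,
    wild_centroid: SimulatedCohort,
    hatchery_centroid: SimulatedCohort,
    config: AdmixtureConfig,
    ranks: tuple[float, float] = (2.5, 97.5),
    p_wild_sample: np.ndarray | None = None,
) -> ThresholdCalibration:
    """Calibrate introgression cutoffs from simulated F1 crosses.

    ``ranks`` are percentile ranks of the F1 p(wild) sample; the derived
    cutoffs use linear interpolation between order statistics.  A
    precomputed ``p_wild_sample`` may be supplied to re-derive cutoffs at
    different ranks without rerunning the sampler.
    """
    lo, hi = ranks
    if not (0 <= lo <= hi <= 100):
        raise ValueError("ranks must satisfy 0 <= lower <= upper <= 100")
    if p_wild_sample is None:
        if n_f1 < 40:
            warnings.warn(
                f"n_f1 = {n_f1}: the {lo} and {hi} percentiles are extreme "
                "order statistics of a small sample"
            )
        p_wild_sample = simulate_f1_sample(
            wild_pool, hatchery_pool, n_f1, wild_centroid,
            hatchery_centroid, config,
        )
    p_wild_sample = np.asarray(p_wild_sample, dtype=float)
    t_lo, t_hi = np.percentile(p_wild_sample, [lo, hi], method=PERCENTILE_RULE)
    return ThresholdCalibration(
        p_wild_sample, lo, hi, float(t_lo), float(t_hi), seed=config.seed
    )


def classify_individuals(
    results: list[AssignmentResult],
    calibration: ThresholdCalibration,
    ranks: tuple[float, float] | None = None,
):
    """Label each assignment result wild / introgressed / hatchery.

    ``hatchery`` if p(wild) < t_lo, ``introgressed`` if
    t_lo <= p(wild) <= t_hi (boundary values inclusive), ``wild`` if
    p(wild) > t_hi.  Labels are written back onto the results; returns
    ``(per_individual_frame, per_population_summary)``.
    """
    t_lo, t_hi = calibration.recompute(ranks)
    rows = []
    for r in results:
        if r.p_wild < t_lo:
            r.label = "hatchery"
        elif r.p_wild <= t_hi:
            r.label = "introgressed"
        else:
            r.label = "wild"
        rows.append((r.individual, r.population, r.p_wild, r.label))
    frame = pd.DataFrame(
        rows, columns=["individual", "population", "p_wild", "label"]
    )
    summary = (
        frame.groupby("population", sort=False)
        .agg(
            n=("individual", "size"),
            mean_p_wild=("p_wild", "mean"),
            n_wild=("label", lambda s: int((s == "wild").sum())),
            n_introgressed=("label", lambda s: int((s == "introgressed").sum())),
            n_hatchery=("label", lambda s: int((s == "hatchery").sum())),
        )
    )
    return frame, summary


COARSE_TRUTH = {
    "wild": "wild",
    "hatchery": "hatchery",
    "F1": "introgressed",
    "F2": "introgressed",
    "BXwild": "introgressed",
    "BXhatchery": "introgressed",
    "post-F1": "introgressed",
    "postF1": "introgressed",
}


def evaluate_error_rate(
    truth_labels,
    results: list[AssignmentResult],
    calibration: ThresholdCalibration,
    ranks_list=((2.5, 97.5), (5.0, 95.0)),
) -> pd.DataFrame:
    """Misclassification rates at each percentile-rank pair.

    ``truth_labels`` maps individual id -> known ancestry (``wild``,
    ``hatchery``, ``F1`` or a post-F1 class); truly introgressed means any
    F1/F2/backcross truth.  For each rank pair the cutoffs are re-derived
    from the calibration's stored F1 sample and the fixed p(wild) estimates
    are re-classified.  Columns: ``missed_introgressed`` (truly introgressed
    not labelled introgressed), ``false_introgressed`` (pure fish labelled
    introgressed), ``overall_error`` (any label differing from the coarse
    truth).
    """
    truth = pd.Series(dict(truth_labels)).map(COARSE_TRUTH)
    if truth.isna().any():
        bad = truth.index[truth.isna()].tolist()
        raise ValueError(f"unknown truth labels for: {bad}")
    rows = []
    for ranks in ranks_list:
        frame, _ = classify_individuals(results, calibration, ranks=ranks)
        merged = frame.set_index("individual").join(truth.rename("truth"), how="inner")
        if len(merged) != len(frame):
            raise ValueError("truth labels do not cover all classified individuals")
        intro = merged["truth"] == "introgressed"
        pure = ~intro
        missed = (
            float((merged.loc[intro, "label"] != "introgressed").mean())
            if intro.any() else np.nan
        )
        false_pos = (
            float((merged.loc[pure, "label"] == "introgressed").mean())
            if pure.any() else np.nan
        )
        overall = float((merged["label"] != merged["truth"]).mean())
        rows.append(
            {
                "lower_rank": ranks[0],
                "upper_rank": ranks[1],
                "missed_introgressed": missed,
                "false_introgressed": false_pos,
                "overall_error": overall,
            }
        )
    return pd.DataFrame(rows)
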