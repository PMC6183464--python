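"""Synthetic microsatellite datasets with known truth labels.

Generates the statistical structure the introgression pipeline assumes: a
set of wild populations and hatchery strains of diploid multilocus
genotypes diverged under the Balding-Nichols model (population frequencies
drawn from Dirichlet(p (1-F)/F) around their group's frequencies, groups
likewise around an ancestral spectrum), plus planted hatchery-origin, F1
and post-F1 individuals built by gamete sampling, and a site covariate
table whose logistic effects (with a site random intercept) generate the
planted introgression flags.

Default divergence and diversity parameters emulate the brook trout study
system this package models: 30 wild populations and 5 hatchery strains at
12 loci, wild diversity around 6.6 alleles/locus and expected
heterozygosity 0.68, hatchery diversity around 4.6 and 0.60 (hatchery
strains carry a stronger drift branch), pooled wild vs hatchery
differentiation near FST 0.07, and among-population differentiation across
groups near 0.13.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable
from .popgen import allele_frequencies, pairwise_fst, summarize_diversity

__all__ = ["SyntheticScenario", "ScenarioData", "generate_scenario"]

#: per-copy probability that the gamete carries a wild-pool allele, for each
#: pedigree class (copy A, copy B)
_CLASS_GAMETES = {
    "wild": (1.0, 1.0),
    "hatchery": (0.0, 0.0),
    "F1": (1.0, 0.0),
    "F2": (0.5, 0.5),
    "BXwild": (1.0, 0.5),
    "BXhatchery": (0.0, 0.5),
}


@dataclass
class SyntheticScenario:
    """Generator settings; defaults are the emulated study conditions."""

    n_wild_populations: int = 30
    n_hatchery_strains: int = 5
    wild_sample_size: int = 50
    hatchery_sample_size: int = 50
    n_loci: int = 12
    ancestral_alleles: int = 12
    ancestral_concentration: float = 0.5
    #: ancestral alleles rarer than this are dropped (and the spectrum
    #: renormalized) so every divergence branch stays attainable
    min_ancestral_frequency: float = 0.015
    #: group-branch divergence from the ancestral pool
    f_wild_branch: float = 0.02
    f_hatchery_branch: float = 0.10
    #: population-branch divergence within each group; the hatchery entry
    #: may be a per-strain sequence — the default mirrors the emulated
    #: system's mix of two diverse and three strongly drifted strains.
    #: The shared hatchery branch carries enough divergence that even the
    #: diverse strains stay clearly attributable to the hatchery group,
    #: while the strain mix keeps the pooled hatchery panel allele-rich.
    f_within_wild: float = 0.075
    f_within_hatchery: float | tuple = (0.04, 0.04, 0.26, 0.26, 0.26)
    #: fraction of each hatchery frequency vector blended back from its
    #: parent pool, emulating the documented exchange of broodstock among
    #: hatcheries; keeps hatchery panels allele-complete (rare ancestral
    #: alleles retained at low frequency) while still drifted in frequency
    broodstock_exchange: float = 0.15
    #: which strains father planted hatchery/hybrid fish (1-based indices).
    #: None selects the strains with above-average drift — the production
    #: strains that are actually stocked in the emulated system; the
    #: diverse strains stay reference-panel-only.  With scalar strain
    #: drift, all strains are stocked.
    stocked_strains: tuple | None = None
    #: per-population pedigree-class fractions for planted individuals;
    #: remainder is pure wild.  ``None`` plants introgressed fish from the
    #: covariate model instead (see ``covariate_effects``).
    planted_fractions: dict | None = None
    #: logistic effects (on z-scored covariates) generating per-fish
    #: introgression flags; flagged fish become F1
    covariate_effects: dict = field(
        default_factory=lambda: {"temperature": 0.5, "pH": -0.5}
    )
    intercept: float = -2.9
    site_sd: float = 0.5
    covariate_names: tuple = (
        "temperature", "dissolved_oxygen", "conductivity", "hardness",
        "total_alkalinity", "pH", "stream_width", "adult_density",
        "watershed_area", "distance_to_stocking",
    )
    seed: int | None = None

    def __post_init__(self):
        if self.planted_fractions is not None:
            for pop, fr in self.planted_fractions.items():
                total = sum(fr.values())
                if total > 1 + 1e-9:
                    raise ValueError(
                        f"planted fractions for {pop!r} sum to {total} > 1"
                    )
                unknown = set(fr) - set(_CLASS_GAMETES)
                if unknown:
                    raise ValueError(f"unknown pedigree classes: {unknown}")


@dataclass
class ScenarioData:
    """A generated dataset bundle."""

    table: GenotypeTable
    truth: pd.Series                 # individual -> pedigree class
    covariates: pd.DataFrame         # one row per wild site (z-scored)
    manifest: dict

    def write(self, outdir) -> None:
        """Write genotypes (both formats), truth, covariates, manifest."""
        from .genotypes import write_genepop, write_structure

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genepop(self.table, outdir / "genotypes.gen")
        write_structure(self.table, outdir / "genotypes.str")
        self.truth.rename("truth").to_csv(outdir / "truth.csv")
        self.covariates.to_csv(outdir / "covariates.csv")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=float)
        )


def _balding_nichols(rng, parent: np.ndarray, F: float,
                     check: bool = False) -> np.ndarray:
    """Daughter frequency vector diverged F from ``parent``.

    With ``check`` (used for the top-level, user-controlled branches) an
    unattainably small Dirichlet concentration raises; deeper branches may
    legitimately carry near-lost alleles, whose concentrations are floored
    numerically (the allele simply stays near-lost).
    """
    if F <= 0:
        return parent.copy()
    conc = parent * (1 - F) / F
    if check and conc[conc > 0].min() < 0.01:
        raise ValueError(
            "unattainable divergence: Balding-Nichols concentration "
            f"below 0.01 (min parent frequency {parent[parent > 0].min():.4f} "
            f"at F={F}); reduce F or increase the minimum ancestral frequency"
        )
    g = rng.gamma(np.where(conc > 0, np.clip(conc, 1e-6, None), 0.0))
    s = g.sum()
    if s <= 0 or not np.isfinite(s):
        return parent.copy()
    return g / s


def _sample_pure(rng, freqs: np.ndarray, n: int) -> np.ndarray:
    """(n, L, 2) allele-index draws from per-locus frequencies (L, A)."""
    L = freqs.shape[0]
    out = np.empty((n, L, 2), dtype=np.int32)
    for l in range(L):
        out[:, l, :] = rng.choice(
            freqs.shape[1], size=(n, 2), p=freqs[l]
        )
    return out


def _sample_cross(rng, wild: np.ndarray, hatch: np.ndarray, n: int,
                  gamete_probs: tuple) -> np.ndarray:
    """Pedigree-class individuals: each copy comes from the wild pool with
    the class's per-copy probability, else from the hatchery pool."""
    L = wild.shape[0]
    out = np.empty((n, L, 2), dtype=np.int32)
    for c, p_wild in enumerate(gamete_probs):
        from_wild = rng.random((n, L)) < p_wild
        for l in range(L):
            w = rng.choice(wild.shape[1], size=n, p=wild[l])
            h = rng.choice(hatch.shape[1], size=n, p=hatch[l])
            out[:, l, c] = np.where(from_wild[:, l], w, h)
    return out


def generate_scenario(spec: SyntheticScenario | None = None) -> ScenarioData:
    """Generate a genotype table, truth labels, covariates and manifest.

    Reproducible under ``spec.seed``.  Allele indices are mapped to
    fragment-size-like codes ``101, 103, ...``; individuals are named
    ``<pop>_<i>``.  The manifest records the spec and realized summary
    statistics (diversity per group, pooled-group FST).
    """
    if spec is None:
        spec = SyntheticScenario()
    rng = np.random.default_rng(spec.seed)
    L, A = spec.n_loci, spec.ancestral_alleles
    loci = [f"locus{j + 1}" for j in range(L)]
    codes = 101 + 2 * np.arange(A)

    def _draw_ancestral():
        p = rng.dirichlet(np.full(A, spec.ancestral_concentration))
        keep = p >= spec.min_ancestral_frequency
        if keep.sum() < 2:
            keep = np.zeros(A, dtype=bool)
            keep[np.argsort(p)[-2:]] = True
        p = np.where(keep, p, 0.0)
        return p / p.sum()

    ancestral = np.stack([_draw_ancestral() for _ in range(L)])
    wild_group = np.stack([
        _balding_nichols(rng, ancestral[l], spec.f_wild_branch, check=True)
        for l in range(L)
    ])
    mix = spec.broodstock_exchange
    hatch_group = np.stack([
        (1 - mix) * _balding_nichols(
            rng, ancestral[l], spec.f_hatchery_branch, check=True
        ) + mix * ancestral[l]
        for l in range(L)
    ])
    wild_pops = {
        f"wild{p + 1:02d}": np.stack([
            _balding_nichols(rng, wild_group[l], spec.f_within_wild)
            for l in range(L)
        ])
        for p in range(spec.n_wild_populations)
    }
    fwh = spec.f_within_hatchery
    if np.isscalar(fwh):
        strain_drift = [float(fwh)] * spec.n_hatchery_strains
    else:
        # cycle the profile if more strains than entries are requested
        strain_drift = [
            float(fwh[s % len(fwh)]) for s in range(spec.n_hatchery_strains)
        ]
    strains = {
        f"strain{s + 1}": np.stack([
            (1 - mix) * _balding_nichols(rng, hatch_group[l], strain_drift[s])
            + mix * hatch_group[l]
            for l in range(L)
        ])
        for s in range(spec.n_hatchery_strains)
    }

    # covariates (z-scored columns) and introgression flags for wild sites
    sites = list(wild_pops)
    raw = rng.normal(size=(len(sites), len(spec.covariate_names)))
    raw = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=1)
    covariates = pd.DataFrame(raw, index=pd.Index(sites, name="site"),
                              columns=list(spec.covariate_names))
    site_effects = rng.normal(0.0, spec.site_sd, size=len(sites))

    tables, truth_rows = [], []
    if spec.stocked_strains is not None:
        strain_names = [f"strain{s}" for s in spec.stocked_strains]
        unknown = set(strain_names) - set(strains)
        if unknown:
            raise ValueError(f"stocked_strains not in scenario: {sorted(unknown)}")
    elif not np.isscalar(spec.f_within_hatchery):
        mean_drift = float(np.mean(strain_drift))
        strain_names = [
            name for name, F in zip(strains, strain_drift) if F >= mean_drift
        ] or list(strains)
    else:
        strain_names = list(strains)

    def _emit(pop, group, class_counts, wild_freqs):
        rows, labels, names = [], [], []
        idx = 0
        for cls, n_cls in class_counts.items():
            if n_cls == 0:
                continue
            if cls == "wild":
                drawn = _sample_pure(rng, wild_freqs, n_cls)
            else:
                strain = strains[strain_names[rng.integers(len(strain_names))]]
                if cls == "hatchery":
                    drawn = _sample_pure(rng, strain, n_cls)
                else:
                    drawn = _sample_cross(
                        rng, wild_freqs, strain, n_cls, _CLASS_GAMETES[cls]
                    )
            for k in range(n_cls):
                idx += 1
                names.append(f"{pop}_{idx}")
                labels.append(cls)
                rows.append(drawn[k])
        order = rng.permutation(len(names))
        calls = codes[np.stack(rows)][order]
        names = [names[i] for i in order]
        labels = [labels[i] for i in order]
        tables.append(GenotypeTable(
            names, loci, calls,
            np.array([pop] * len(names), dtype=object),
            np.array([group] * len(names), dtype=object),
        ))
        truth_rows.extend(zip(names, labels))

    flags = {}
    for j, (pop, freqs) in enumerate(wild_pops.items()):
        n = spec.wild_sample_size
        if spec.planted_fractions is not None:
            fr = spec.planted_fractions.get(pop, {})
            counts = {
                cls: int(np.ceil(fr.get(cls, 0.0) * n))
                for cls in _CLASS_GAMETES if cls != "wild"
            }
            counts["wild"] = n - sum(counts.values())
        else:
            eta = (
                spec.intercept
                + sum(
                    b * covariates.loc[pop, c]
                    for c, b in spec.covariate_effects.items()
                )
                + site_effects[j]
            )
            p = 1.0 / (1.0 + np.exp(-eta))
            intro = rng.random(n) < p
            counts = {"wild": int(n - intro.sum()), "F1": int(intro.sum())}
            flags[pop] = p
        _emit(pop, "wild", counts, freqs)
    for strain_name, freqs in strains.items():
        _emit(
            strain_name, "hatchery",
            {"hatchery": spec.hatchery_sample_size}, freqs,
        )

    table = GenotypeTable.concatenate(tables)
    truth = pd.Series(dict(truth_rows), name="truth").reindex(table.individuals)

    grouped = allele_frequencies(table, "by_group")
    div = summarize_diversity(table)
    by_group = div.groupby("group")[["N_A", "H_E"]].mean()
    pooled = table.subset(np.arange(len(table)))
    pooled.population = pooled.group.copy()
    fst, _ = pairwise_fst(pooled)
    manifest = {
        "spec": {
            k: v for k, v in asdict(spec).items()
            if k not in ("planted_fractions",)
        },
        "planted_fractions": spec.planted_fractions,
        "realized": {
            "wild_N_A": float(by_group.loc["wild", "N_A"]),
            "wild_H_E": float(by_group.loc["wild", "H_E"]),
            "hatchery_N_A": float(by_group.loc["hatchery", "N_A"]),
            "hatchery_H_E": float(by_group.loc["hatchery", "H_E"]),
            "pooled_group_fst": float(fst.loc["wild", "hatchery"]),
            "n_individuals": len(table),
            "truth_counts": truth.value_counts().to_dict(),
        },
    }
    return ScenarioData(table, truth, covariates, manifest)
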