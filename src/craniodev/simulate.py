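"""Synthetic data with planted truth for the comparative-development design.

The generator emulates a 4-taxa x 4-stage x 4-replicate bulk RNA-seq study:
gene-wise negative-binomial counts with a mean-dispersion trend, variable
library sizes, and differential expression planted as focal-taxon-vs-rest
shifts. A configurable fraction of each taxon's DE genes is constitutive
(same effect sign at every stage). Truth tables record every planted
effect, enabling recall/false-discovery measurement downstream.

Separate helpers build curated-gene-list fixtures for the enrichment
permutation test, and coverage/consensus fixtures for the supermatrix
procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import IntervalCatalog, joint_covered_regions

DEFAULT_TAXA = ("scale_biter", "durophage", "inland_omnivore", "marine_omnivore")
DEFAULT_STAGES = ("48hpf", "96hpf", "8dpf", "15dpf")


class ConfigurationError(ValueError):
    """Raised for invalid simulation settings."""


@dataclass
class SimulationConfig:
    """Study-design and generative parameters.

    Expression baselines are on the counts-per-million scale: a gene's mean
    cpm is lognormal with the given natural-log mean and sd. Dispersion
    follows the decreasing trend phi = intercept + slope / mean_cpm, giving
    both high- and low-information genes; the intercept default (0.02, a
    14% biological CV floor) reflects replicates that are pools of many
    siblings, each pool from a distinct parental pair. Effects are |log2FC| shifts of a
    focal taxon's samples against all other taxa; ``effect_size_log2``
    defaults to 0.4 (~1.3-fold), the magnitude typical of between-taxon
    expression divergence in closely related species.
    """

    n_taxa: int = 4
    n_stages: int = 4
    n_reps: int = 4
    n_genes: int = 10_000
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.8
    dispersion_intercept: float = 0.02
    dispersion_slope: float = 2.0
    lib_size_range: tuple[float, float] = (15e6, 20e6)
    de_fraction: float = 0.1
    effect_size_log2: float = 0.4
    constitutive_fraction: float = 0.2
    n_focal_taxa: int = 2
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_taxa, self.n_stages, self.n_genes) < 1:
            raise ConfigurationError("dimensions must be positive")
        if self.n_reps < 2:
            raise ConfigurationError("need at least 2 replicates")
        for name in ("de_fraction", "constitutive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.dispersion_intercept <= 0 or self.dispersion_slope < 0:
            raise ConfigurationError("dispersion trend must be positive")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError(
                f"lib_size_range must be positive and ordered, got {self.lib_size_range}"
            )
        if not 0 <= self.n_focal_taxa <= self.n_taxa:
            raise ConfigurationError("n_focal_taxa must not exceed n_taxa")
        if self.n_focal_taxa * round(self.de_fraction * self.n_genes) > self.n_genes:
            raise ConfigurationError(
                "de_fraction too large for disjoint per-taxon DE pools"
            )

    @property
    def taxa(self) -> list[str]:
        if self.n_taxa == len(DEFAULT_TAXA):
            return list(DEFAULT_TAXA)
        return [f"taxon{i + 1}" for i in range(self.n_taxa)]

    @property
    def stages(self) -> list[str]:
        if self.n_stages == len(DEFAULT_STAGES):
            return list(DEFAULT_STAGES)
        return [f"stage{i + 1}" for i in range(self.n_stages)]

    @property
    def focal_taxa(self) -> list[str]:
        return self.taxa[: self.n_focal_taxa]


@dataclass
class SimulationTruth:
    """Planted effects: log2FC per gene x (focal taxon, stage), plus flags.

    ``log2fc`` has a (taxon, stage) MultiIndex on columns; entries are 0
    where no effect was planted. ``de`` is the matching boolean flag table;
    ``constitutive`` marks genes whose planted effect keeps one sign at
    every stage. ``mean_cpm`` and ``dispersion`` record the generative
    per-gene parameters.
    """

    log2fc: pd.DataFrame
    de: pd.DataFrame
    constitutive: pd.Series
    mean_cpm: pd.Series
    dispersion: pd.Series
    de_taxon: pd.Series = field(default=None)  # type: ignore[assignment]

    def de_genes(self, taxon: str, stage: str) -> pd.Index:
        flags = self.de[(taxon, stage)]
        return flags.index[flags]

    def any_de_genes(self) -> pd.Index:
        return self.de.index[self.de.any(axis=1)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format truth table (gene_id, taxon, stage, log2fc, de)."""
        long = self.log2fc.stack(["taxon", "stage"], future_stack=True)
        out = long.rename("log2fc").reset_index()
        out.columns = ["gene_id", "taxon", "stage", "log2fc"]
        out["de"] = self.de.stack(
            ["taxon", "stage"], future_stack=True
        ).to_numpy()
        return out


def _plant_effects(cfg: SimulationConfig, genes: pd.Index, rng: np.random.Generator):
    taxa, stages = cfg.taxa, cfg.stages
    cols = pd.MultiIndex.from_product(
        [taxa, stages], names=["taxon", "stage"]
    )
    lfc = pd.DataFrame(0.0, index=genes, columns=cols)
    constitutive = pd.Series(False, index=genes)
    de_taxon = pd.Series("", index=genes, dtype=object)
    n_de = round(cfg.de_fraction * cfg.n_genes)
    if n_de == 0 or cfg.n_focal_taxa == 0:
        return lfc, constitutive, de_taxon
    pool = rng.permutation(cfg.n_genes)
    offset = 0
    for taxon in cfg.focal_taxa:
        idx = genes[pool[offset: offset + n_de]]
        offset += n_de
        de_taxon[idx] = taxon
        n_const = round(cfg.constitutive_fraction * n_de)
        const_idx, vary_idx = idx[:n_const], idx[n_const:]
        sign = rng.choice([-1.0, 1.0], size=len(const_idx))
        for st in stages:
            lfc.loc[const_idx, (taxon, st)] = sign * cfg.effect_size_log2
        constitutive[const_idx] = True
        # Non-constitutive genes are DE at every stage but with at least one
        # sign flip across stages, so the constitutive flag is decidable.
        signs = rng.choice([-1.0, 1.0], size=(len(vary_idx), len(stages)))
        if len(stages) > 1:
            uniform = np.abs(signs.sum(axis=1)) == len(stages)
            flip_at = rng.integers(0, len(stages), size=len(vary_idx))
            for i in np.flatnonzero(uniform):
                signs[i, flip_at[i]] *= -1.0
        for j, st in enumerate(stages):
            lfc.loc[vary_idx, (taxon, st)] = signs[:, j] * cfg.effect_size_log2
    return lfc, constitutive, de_taxon


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Draw a full count matrix, sample sheet and planted truth.

    Counts are NB with mean mu_g * (libsize / 1e6) * 2**log2FC and
    dispersion from the trend, drawn as gamma-Poisson mixtures. The same
    config and seed reproduce byte-identical output: the master seed is
    split into named substreams (gene parameters, planted effects, library
    sizes, counts) so partial regeneration stays stable.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_genes, rng_truth, rng_libs, rng_counts = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    width = len(str(config.n_genes))
    genes = pd.Index(
        [f"g{str(i + 1).zfill(width)}" for i in range(config.n_genes)],
        name="gene_id",
    )
    mean_cpm = pd.Series(
        np.exp(
            rng_genes.normal(
                config.baseline_log_mean, config.baseline_log_sd, config.n_genes
            )
        ),
        index=genes,
        name="mean_cpm",
    )
    dispersion = pd.Series(
        config.dispersion_intercept + config.dispersion_slope / mean_cpm,
        index=genes,
        name="dispersion",
    )

    lfc, constitutive, de_taxon = _plant_effects(config, genes, rng_truth)
    truth = SimulationTruth(
        log2fc=lfc,
        de=lfc != 0.0,
        constitutive=constitutive,
        mean_cpm=mean_cpm,
        dispersion=dispersion,
        de_taxon=de_taxon,
    )

    taxa, stages = config.taxa, config.stages
    sample_rows = []
    for stage in stages:
        for taxon in taxa:
            for rep in range(1, config.n_reps + 1):
                sample_rows.append(
                    {
                        "sample_id": f"{taxon}_{stage}_r{rep}",
                        "taxon": taxon,
                        "stage": stage,
                        "replicate": rep,
                        # one parental pair per taxon x stage x replicate
                        "parental_pair": f"{taxon}_p{rep}",
                    }
                )
    samples = pd.DataFrame(sample_rows)
    lo, hi = config.lib_size_range
    samples["lib_size_target"] = rng_libs.integers(
        int(lo), int(hi) + 1, size=len(samples)
    )

    counts = np.empty((config.n_genes, len(samples)), dtype=np.int64)
    phi = dispersion.to_numpy()
    base = mean_cpm.to_numpy()
    for j, row in samples.iterrows():
        shift = lfc[(row["taxon"], row["stage"])].to_numpy()
        mu = base * (row["lib_size_target"] / 1e6) * np.exp2(shift)
        lam = rng_counts.gamma(shape=1.0 / phi, scale=phi * mu)
        counts[:, j] = rng_counts.poisson(lam)
    counts_df = pd.DataFrame(
        counts, index=genes, columns=samples["sample_id"].to_list()
    )
    return counts_df, samples.drop(columns="lib_size_target"), truth


class PoolExhaustedError(ValueError):
    """A curated-list pool has fewer genes than requested."""


def simulate_curated_list(
    truth: SimulationTruth,
    universe: list[str],
    n_from_de: int,
    n_background: int,
    seed: int,
) -> list[str]:
    """Curated-list fixture mixing truly-DE and background genes.

    Emulates an externally curated annotation list (e.g. genes with known
    craniofacial/bone phenotypes) whose overlap with discovery output is
    then assessed by permutation.
    """
    rng = np.random.default_rng(seed)
    universe_idx = pd.Index(universe)
    de_pool = universe_idx.intersection(truth.any_de_genes())
    bg_pool = universe_idx.difference(de_pool)
    if n_from_de > len(de_pool):
        raise PoolExhaustedError(
            f"requested {n_from_de} DE genes but the DE pool holds {len(de_pool)}"
        )
    if n_background > len(bg_pool):
        raise PoolExhaustedError(
            f"requested {n_background} background genes but the background "
            f"pool holds {len(bg_pool)}"
        )
    picked = list(rng.choice(de_pool.to_numpy(), size=n_from_de, replace=False))
    picked += list(rng.choice(bg_pool.to_numpy(), size=n_background, replace=False))
    return sorted(picked)


def simulate_coverage_experiment(
    n_samples: int,
    n_scaffolds: int,
    scaffold_len: int,
    mean_depth: float,
    seed: int,
    min_depth: int = 10,
    gap_rate: float = 0.005,
    substitution_rate: float = 0.005,
) -> tuple[dict, dict, IntervalCatalog]:
    """Coverage tracks and consensus sequences with planted gaps.

    Per-base depths are Poisson around ``mean_depth`` with extra planted
    low-coverage gaps (short intervals forced below ``min_depth``) at rate
    ``gap_rate`` per base per sample. Consensus sequences share a random
    reference with per-sample substitutions. The returned truth catalog
    holds the maximal runs jointly covered at ``min_depth``.
    """
    if min(n_samples, n_scaffolds, scaffold_len) < 1:
        raise ConfigurationError("dimensions must be positive")
    if mean_depth < 0:
        raise ConfigurationError("mean_depth must be non-negative")
    rng = np.random.default_rng(seed)
    scaffolds = [f"scaffold{i + 1}" for i in range(n_scaffolds)]
    sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    reference = {
        sc: "".join(rng.choice(list("ACGT"), size=scaffold_len))
        for sc in scaffolds
    }
    tracks: dict[str, dict[str, np.ndarray]] = {}
    consensus: dict[str, dict[str, str]] = {}
    for s in sample_ids:
        tracks[s] = {}
        consensus[s] = {}
        for sc in scaffolds:
            depth = rng.poisson(mean_depth, size=scaffold_len)
            n_gaps = rng.poisson(gap_rate * scaffold_len)
            for _ in range(n_gaps):
                start = int(rng.integers(0, scaffold_len))
                width = int(rng.integers(1, 31))
                depth[start: start + width] = rng.integers(
                    0, min_depth, size=len(depth[start: start + width])
                )
            tracks[s][sc] = depth
            seq = np.frombuffer(reference[sc].encode(), dtype="S1").copy()
            n_subs = rng.poisson(substitution_rate * scaffold_len)
            pos = rng.choice(scaffold_len, size=min(n_subs, scaffold_len),
                             replace=False)
            seq[pos] = rng.choice(
                np.frombuffer(b"ACGT", dtype="S1"), size=len(pos)
            )
            consensus[s][sc] = seq.tobytes().decode()
    truth = joint_covered_regions(tracks, min_depth=min_depth)
    return tracks, consensus, truth
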