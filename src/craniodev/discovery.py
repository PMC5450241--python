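"""Candidate-gene discovery from pairwise DE results.

A focal taxon's *intersection set* at one stage holds the genes passing
the DE thresholds (FDR and |log2FC|) with a consistent sign in all three
pairwise comparisons of the focal taxon against each other taxon — split
into over- and underexpressed lists. Across stages, genes appearing in
sets at two or more stages are "multi-stage"; those whose mean log2FC
keeps one sign at every stage are "constitutively" differentially
expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class IntersectionSet:
    focal_taxon: str
    stage: str
    over: list[str]
    under: list[str]
    fdr_max: float = 0.1
    lfc_min: float = 0.2

    def __post_init__(self) -> None:
        if set(self.over) & set(self.under):
            raise ValueError("over and under lists overlap")

    @property
    def genes(self) -> list[str]:
        return self.over + self.under

    def direction(self, gene: str) -> str:
        if gene in set(self.over):
            return "over"
        if gene in set(self.under):
            return "under"
        raise KeyError(gene)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.over + self.under,
                "direction": ["over"] * len(self.over)
                + ["under"] * len(self.under),
            }
        )


def _check_universe(tables: list[pd.DataFrame]) -> pd.Index:
    universe = pd.Index(tables[0]["gene_id"])
    for t in tables[1:]:
        other = pd.Index(t["gene_id"])
        if not universe.sort_values().equals(other.sort_values()):
            diff = universe.symmetric_difference(other)
            raise ValueError(
                f"gene universes differ between comparisons; "
                f"{len(diff)} discordant, e.g. {list(diff[:5])}"
            )
    return universe


def build_intersection_set(
    results: list[pd.DataFrame],
    focal_taxon: str,
    stage: str,
    fdr_max: float = 0.1,
    lfc_min: float = 0.2,
) -> IntersectionSet:
    """Genes DE in ALL pairwise comparisons of the focal taxon.

    ``results`` holds one DE table per comparison (focal taxon as the
    log-fold-change numerator). A gene is overexpressed if every table has
    FDR <= fdr_max and log2FC >= lfc_min; underexpressed analogously with
    log2FC <= -lfc_min. Mixed signs are excluded.
    """
    if len(results) < 2:
        raise ValueError("need at least two comparisons to intersect")
    _check_universe(results)
    aligned = [t.set_index("gene_id") for t in results]
    idx = aligned[0].index
    aligned = [aligned[0]] + [t.reindex(idx) for t in aligned[1:]]
    sig = np.all([t["FDR"].to_numpy() <= fdr_max for t in aligned], axis=0)
    over = sig & np.all(
        [t["logFC"].to_numpy() >= lfc_min for t in aligned], axis=0
    )
    under = sig & np.all(
        [t["logFC"].to_numpy() <= -lfc_min for t in aligned], axis=0
    )
    return IntersectionSet(
        focal_taxon=focal_taxon,
        stage=stage,
        over=list(idx[over]),
        under=list(idx[under]),
        fdr_max=fdr_max,
        lfc_min=lfc_min,
    )


def shared_extreme_genes(
    set_a: IntersectionSet, set_b: IntersectionSet
) -> pd.DataFrame:
    """Genes present in the intersection sets of BOTH focal taxa.

    Returns one row per shared gene with its direction in each set, e.g. a
    gene overexpressed in one extreme taxon and underexpressed in the
    other.
    """
    if set_a.stage != set_b.stage:
        raise ValueError(
            f"stage mismatch: {set_a.stage!r} vs {set_b.stage!r}"
        )
    shared = sorted(set(set_a.genes) & set(set_b.genes))
    return pd.DataFrame(
        {
            "gene_id": shared,
            f"direction_{set_a.focal_taxon}": [
                set_a.direction(g) for g in shared
            ],
            f"direction_{set_b.focal_taxon}": [
                set_b.direction(g) for g in shared
            ],
        }
    )


@dataclass
class ConstitutiveReport:
    focal_taxon: str
    union: list[str]
    multi_stage: list[str]
    percent_multi_stage: float
    constitutive: list[str]
    missing_lfc: list[str] = field(default_factory=list)

    @property
    def n_union(self) -> int:
        return len(self.union)

    @property
    def n_multi_stage(self) -> int:
        return len(self.multi_stage)


def classify_constitutive(
    stage_sets: dict[str, IntersectionSet],
    mean_lfc: pd.DataFrame,
) -> ConstitutiveReport:
    """Multi-stage and constitutive classification for one focal taxon.

    ``stage_sets`` maps stage -> IntersectionSet (all same focal taxon);
    ``mean_lfc`` is genes x stages of the mean log2FC across the three
    comparisons at each stage (NaN where a gene was filtered out at that
    stage). The multi-stage subset holds union genes present in sets at
    two or more stages; the constitutive subset holds multi-stage genes
    whose mean log2FC has one strict sign at every stage. Genes lacking a
    log2FC at some stage stay in the multi-stage subset but are excluded
    from the constitutive subset and reported separately.
    """
    stages = list(stage_sets)
    taxa = {s.focal_taxon for s in stage_sets.values()}
    if len(taxa) != 1:
        raise ValueError(f"sets mix focal taxa: {sorted(taxa)}")
    missing_stages = [st for st in stages if st not in mean_lfc.columns]
    if missing_stages:
        raise ValueError(f"mean_lfc lacks stage column(s) {missing_stages}")

    membership: dict[str, int] = {}
    for st in stages:
        for g in stage_sets[st].genes:
            membership[g] = membership.get(g, 0) + 1
    union = sorted(membership)
    multi = [g for g in union if membership[g] >= 2]
    pct = 100.0 * len(multi) / len(union) if union else 0.0

    constitutive, missing = [], []
    for g in multi:
        if g not in mean_lfc.index:
            missing.append(g)
            continue
        vals = mean_lfc.loc[g, stages].to_numpy(dtype=float)
        if np.isnan(vals).any():
            missing.append(g)
            continue
        if np.all(vals > 0) or np.all(vals < 0):
            constitutive.append(g)
    return ConstitutiveReport(
        focal_taxon=taxa.pop(),
        union=union,
        multi_stage=multi,
        percent_multi_stage=pct,
        constitutive=constitutive,
        missing_lfc=missing,
    )
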