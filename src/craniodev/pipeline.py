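"""End-to-end orchestration: normalize -> DE -> discovery -> enrichment.

A single YAML config drives the run; every stage writes plain-text
outputs under the output directory and the run finishes with a manifest
(parameters, seeds, sha256 of every output) so reruns are verifiable
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import discovery, enrichment, io, normalize, ordination
from . import de as de_mod
from .intervals import build_supermatrix, filter_by_length, joint_covered_regions

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


class ValidationError(ValueError):
    """Fatal input-validation failure."""


@dataclass
class PipelineConfig:
    counts: str
    samples: str
    out_dir: str
    gene_annotation: str | None = None
    curated_list: str | None = None
    gmt: str | None = None
    stages: list[str] | None = None
    focal_taxa: list[str] = field(default_factory=list)
    fdr_max: float = 0.1
    lfc_min: float = 0.2
    gsea_fdr_report: float = 0.25
    n_perm: int = 1000
    pca_components: int = 4
    gsea_loading_components: int = 3
    seed: int = 0
    coverage_dir: str | None = None
    consensus_dir: str | None = None
    scaffold_lengths: str | None = None
    min_depth: int = 10
    min_len: int = 51
    max_len: int = 999

    def __post_init__(self) -> None:
        if not 0 < self.fdr_max <= 1 or not 0 < self.gsea_fdr_report <= 1:
            raise ValidationError("FDR thresholds must lie in (0, 1]")
        if self.lfc_min < 0:
            raise ValidationError("lfc_min must be non-negative")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def validate_inputs(counts_path: str, samples_path: str) -> list[dict]:
    """Consistency checks on the count matrix and sample sheet.

    Returns a list of findings ({severity, message}); fatal findings mean
    the pipeline must not run.
    """
    findings: list[dict] = []

    def fatal(msg: str) -> None:
        findings.append({"severity": "fatal", "message": msg})

    def warn(msg: str) -> None:
        findings.append({"severity": "warning", "message": msg})

    try:
        counts = io.read_counts_tsv(counts_path)
    except Exception as exc:  # pragma: no cover - message path
        raise ValidationError(f"unreadable counts file {counts_path}: {exc}")
    try:
        samples = io.read_sample_sheet(samples_path)
    except Exception as exc:  # pragma: no cover
        raise ValidationError(f"unreadable sample sheet {samples_path}: {exc}")

    if counts.index.has_duplicates:
        fatal("duplicate gene IDs in count matrix")
    if counts.columns.has_duplicates:
        fatal("duplicate sample IDs in count matrix")
    non_numeric = [
        c for c, dt in counts.dtypes.items()
        if not np.issubdtype(dt, np.number)
    ]
    if non_numeric:
        fatal(f"non-numeric counts in column(s) {non_numeric[:5]}")
    else:
        arr = counts.to_numpy(dtype=float)
        if (arr < 0).any():
            fatal("negative counts present")
        frac = arr - np.floor(arr)
        if np.any(frac != 0):
            g, s = np.argwhere(frac != 0)[0]
            fatal(
                f"non-integer count at gene {counts.index[g]!r}, "
                f"sample {counts.columns[s]!r}: {arr[g, s]}"
            )
    for col in ("sample_id", "taxon", "stage", "replicate"):
        if col not in samples.columns:
            fatal(f"sample sheet lacks column {col!r}")
    if "sample_id" in samples.columns:
        if samples["sample_id"].duplicated().any():
            fatal("duplicate sample IDs in sample sheet")
        sheet_only = set(samples["sample_id"]) - set(counts.columns)
        matrix_only = set(counts.columns) - set(samples["sample_id"])
        if sheet_only:
            fatal(f"samples in sheet missing from matrix: {sorted(sheet_only)[:5]}")
        if matrix_only:
            warn(f"matrix columns not in sheet (ignored): {sorted(matrix_only)[:5]}")
    return findings


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, **kw)
    return path


def run_stage_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    stage: str,
) -> tuple[pd.DataFrame, normalize.NormalizationFactors,
           de_mod.DispersionEstimates, dict[tuple[str, str], pd.DataFrame]]:
    """Filter, normalize and test all pairwise taxon contrasts for a stage."""
    sub_samples = samples[samples["stage"] == stage].reset_index(drop=True)
    sub = counts[sub_samples["sample_id"].to_list()]
    kept, _ = normalize.filter_low_expression(sub)
    factors = normalize.tmm_factors(kept)
    groups = pd.Series(
        sub_samples["taxon"].to_numpy(), index=sub_samples["sample_id"]
    )
    common = de_mod.estimate_common_dispersion(kept, groups, factors)
    disp = de_mod.estimate_tagwise_dispersions(kept, groups, factors, common)
    results: dict[tuple[str, str], pd.DataFrame] = {}
    taxa = list(pd.unique(sub_samples["taxon"]))
    for a, b in itertools.combinations(taxa, 2):
        results[(a, b)] = de_mod.test_pairwise(
            kept, sub_samples, a, b, factors, disp
        )
    return kept, factors, disp, results


def focal_tables(
    results: dict[tuple[str, str], pd.DataFrame], focal: str
) -> list[pd.DataFrame]:
    """The three focal-vs-other DE tables, sign-oriented focal-first."""
    out = []
    for (a, b), table in results.items():
        if focal == a:
            out.append(table)
        elif focal == b:
            flipped = table.copy()
            flipped["logFC"] = -flipped["logFC"]
            flipped.attrs["taxon_a"], flipped.attrs["taxon_b"] = b, a
            out.append(flipped)
    return out


def run_full(config: PipelineConfig) -> dict:
    """Execute the whole pipeline; return (and write) the run manifest."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    findings = validate_inputs(config.counts, config.samples)
    fatal = [f for f in findings if f["severity"] == "fatal"]
    if fatal:
        raise ValidationError("; ".join(f["message"] for f in fatal))
    for f in findings:
        logger.warning("validate: %s", f["message"])

    counts = io.read_counts_tsv(config.counts)
    samples = io.read_sample_sheet(config.samples)
    if config.gene_annotation:
        ann = pd.read_csv(config.gene_annotation, sep="\t", index_col=0)
        counts = normalize.remove_excluded_genes(counts, ann.astype(bool))
    stages = config.stages or list(pd.unique(samples["stage"]))
    focal_taxa = config.focal_taxa or list(pd.unique(samples["taxon"])[:2])
    curated = None
    if config.curated_list:
        curated = (
            pd.read_csv(config.curated_list, header=None)[0].astype(str).to_list()
        )
    collection = io.read_gmt(config.gmt) if config.gmt else None

    outputs: list[Path] = []
    sets_by_focal: dict[str, dict[str, discovery.IntersectionSet]] = {
        t: {} for t in focal_taxa
    }
    mean_lfc_by_focal: dict[str, dict[str, pd.Series]] = {
        t: {} for t in focal_taxa
    }
    enrich_rows = []
    for stage in stages:
        t_stage = time.time()
        kept, factors, disp, results = run_stage_de(counts, samples, stage)
        factors_df = pd.DataFrame(
            {
                "sample_id": factors.lib_size.index,
                "lib_size": factors.lib_size.to_numpy(),
                "tmm_factor": factors.factor.to_numpy(),
            }
        )
        outputs.append(_write(factors_df, out / f"factors_{stage}.tsv"))
        for (a, b), table in results.items():
            outputs.append(_write(table, out / f"de_{stage}_{a}_vs_{b}.tsv"))

        cpm = normalize.compute_cpm(kept, factors)
        logm = ordination.log_transform(cpm)
        model = ordination.pca_samples(logm, config.pca_components)
        outputs.append(
            _write(
                model.scores.rename_axis("sample_id").reset_index(),
                out / f"pca_scores_{stage}.tsv",
            )
        )
        outputs.append(
            _write(
                model.loadings.rename_axis("gene_id").reset_index(),
                out / f"pca_loadings_{stage}.tsv",
            )
        )
        outputs.append(
            _write(
                model.variance_fraction.rename("variance_fraction")
                .rename_axis("component")
                .reset_index(),
                out / f"pca_varfrac_{stage}.tsv",
            )
        )

        for fi, focal in enumerate(focal_taxa):
            tables = focal_tables(results, focal)
            iset = discovery.build_intersection_set(
                tables, focal, stage,
                fdr_max=config.fdr_max, lfc_min=config.lfc_min,
            )
            sets_by_focal[focal][stage] = iset
            outputs.append(
                _write(
                    iset.to_frame(), out / f"intersection_{stage}_{focal}.tsv"
                )
            )
            mean_lfc_by_focal[focal][stage] = (
                pd.concat(
                    [t.set_index("gene_id")["logFC"] for t in tables], axis=1
                ).mean(axis=1)
            )

            if curated is not None:
                res = enrichment.permutation_overlap_test(
                    iset.genes,
                    curated,
                    list(kept.index),
                    n_perm=config.n_perm,
                    seed=_substream(config.seed, f"curated|{stage}|{focal}"),
                )
                enrich_rows.append(
                    {
                        "stage": stage,
                        "focal_taxon": focal,
                        "set_size": len(iset.genes),
                        "observed": res.observed,
                        "null_mean": res.null_mean,
                        "p_empirical": res.p_empirical,
                        "p_hypergeom": res.p_hypergeom,
                    }
                )
            if collection is not None:
                ranked = enrichment.rank_by_mean_logfc(tables)
                io.write_rnk(ranked, out / f"rank_logfc_{stage}_{focal}.rnk")
                outputs.append(out / f"rank_logfc_{stage}_{focal}.rnk")
                gres = enrichment.gsea_preranked(
                    ranked,
                    collection,
                    n_perm=config.n_perm,
                    seed=_substream(config.seed, f"gsea|{stage}|{focal}"),
                )
                gres.insert(0, "stage", stage)
                gres.insert(1, "focal_taxon", focal)
                outputs.append(
                    _write(gres, out / f"gsea_logfc_{stage}_{focal}.tsv")
                )
        if collection is not None:
            for comp in range(
                1, min(config.gsea_loading_components, model.n_components) + 1
            ):
                ranked = ordination.loading_ranks(model, comp)
                gres = enrichment.gsea_preranked(
                    ranked,
                    collection,
                    n_perm=config.n_perm,
                    seed=_substream(config.seed, f"gsea_pc|{stage}|{comp}"),
                )
                gres.insert(0, "stage", stage)
                gres.insert(1, "component", comp)
                outputs.append(
                    _write(gres, out / f"gsea_pc{comp}_{stage}.tsv")
                )
        logger.info(
            "stage %s finished in %.1fs", stage, time.time() - t_stage
        )

    for focal in focal_taxa:
        lfc_table = pd.DataFrame(mean_lfc_by_focal[focal])
        report = discovery.classify_constitutive(
            sets_by_focal[focal], lfc_table
        )
        payload = {
            "focal_taxon": focal,
            "n_union": report.n_union,
            "n_multi_stage": report.n_multi_stage,
            "percent_multi_stage": round(report.percent_multi_stage, 4),
            "n_constitutive": len(report.constitutive),
            "multi_stage": report.multi_stage,
            "constitutive": report.constitutive,
            "missing_lfc": report.missing_lfc,
        }
        path = out / f"constitutive_{focal}.json"
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        outputs.append(path)
    if enrich_rows:
        outputs.append(
            _write(pd.DataFrame(enrich_rows), out / "curated_enrichment.tsv")
        )

    if config.coverage_dir and config.consensus_dir:
        outputs.extend(_run_intervals(config, out))

    manifest = {
        "config": asdict(config),
        "elapsed_seconds": round(time.time() - t0, 2),
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(outputs))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _substream(seed: int, label: str) -> int:
    """Stable per-task sub-seed derived from the master seed and a label."""
    h = hashlib.sha256(f"{seed}|{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _run_intervals(config: PipelineConfig, out: Path) -> list[Path]:
    lengths = (
        pd.read_csv(config.scaffold_lengths, sep="\t", header=None,
                    names=["scaffold", "length"], dtype={"scaffold": str})
        .set_index("scaffold")["length"]
        .to_dict()
    )
    tracks = {
        p.stem: io.read_bedgraph(p, lengths)
        for p in sorted(Path(config.coverage_dir).glob("*.bedgraph"))
    }
    consensus: dict[str, dict[str, str]] = {}
    for p in sorted(Path(config.consensus_dir).glob("*.fasta")):
        for name, seq in io.read_fasta(p).items():
            sample, scaffold = name.split("|", 1)
            consensus.setdefault(sample, {})[scaffold] = seq
    catalog = filter_by_length(
        joint_covered_regions(tracks, min_depth=config.min_depth),
        min_len=config.min_len,
        max_len=config.max_len,
    )
    sm = build_supermatrix(consensus, catalog)
    outputs = []
    outputs.append(
        _write(catalog.intervals, out / "interval_catalog.tsv")
    )
    outputs.append(_write(catalog.summary(), out / "interval_summary.tsv"))
    io.write_fasta(sm.sequences, out / "supermatrix.fasta")
    io.write_phylip(sm.sequences, out / "supermatrix.phy")
    sm.coordinate_map.to_csv(
        out / "coordinate_map.bed", sep="\t", index=False, header=False
    )
    outputs += [
        out / "supermatrix.fasta",
        out / "supermatrix.phy",
        out / "coordinate_map.bed",
    ]
    return outputs
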