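"""End-to-end study workflows: simulate -> discover -> profile -> (saturate)
-> community statistics -> consensus differential abundance.

Two scenarios mirror the study designs: ``angii`` (treatment with no planted
community effect — hypertension induction left the gut microbiome unchanged)
and ``fiber`` (a diet effect shifting host abundances, their prophages and
CAZyme gene content).  Each run writes stage outputs plus a machine-readable
JSON report embedding the resolved configuration and an input content hash.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

from . import io as dio
from .da import run_consensus
from .discovery import ViralCatalog, build_viral_catalog
from .profiling import build_feature_table, lifestyle_totals, profile_genes, scfa_totals, to_relative
from .saturation import DepthGrid, capture_fraction, detect_plateau, rarefaction_curve, thin_coverage_frame
from .simulate import (CommunityConfig, StudyDesign, build_community, emit_catalog_inputs,
                       simulate_coverage, simulate_gene_coverage)
from .stats import alpha_diversity, bray_curtis, group_compare, pcoa, permanova, procrustes_test

logger = logging.getLogger("dualvirome")

SCENARIOS = {
    "angii": {"groups": ("sham", "angii"), "effect_log2fc": 0.0},
    "fiber": {"groups": ("low_fiber", "high_fiber"), "effect_log2fc": 4.0},
}


@dataclass
class RunConfig:
    scenario: str = "fiber"
    seed: int = 0
    outdir: str | None = None
    n_permutations: int = 9999
    min_samples: int = 3
    lfc_threshold: float = 2.0
    alpha: float = 0.05
    plateau_epsilon: float = 0.02
    run_saturation: bool = False
    run_gene_profiling: bool = True
    community: CommunityConfig = field(default_factory=CommunityConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if isinstance(data.get("community"), dict):
            cknown = {f.name for f in dataclasses.fields(CommunityConfig)}
            cunknown = set(data["community"]) - cknown
            if cunknown:
                raise ValueError(f"unknown community config keys: {sorted(cunknown)}")
            data["community"] = CommunityConfig(**data["community"])
        return cls(**data)

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def format_pct(part: float, total: float) -> float:
    """Percentage to one decimal, half-up (671/816 -> 82.2)."""
    if total == 0:
        return 0.0
    pct = Decimal(part) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_catalog(catalog: ViralCatalog) -> dict:
    """Bookkeeping counts of a viral catalog: lifestyle partition, fraction
    family-assigned, fraction carrying auxiliary metabolic genes."""
    total = len(catalog)
    temperate = catalog.count("temperate")
    virulent = catalog.count("virulent")
    family = sum(1 for s in catalog.srgs if s.family_label)
    amg = sum(1 for s in catalog.srgs if s.amg_count > 0)
    return {
        "total": total, "temperate": temperate, "virulent": virulent,
        "family_assigned": family,
        "family_assigned_pct": format_pct(family, total),
        "amg_bearing": amg,
        "amg_bearing_pct": format_pct(amg, total),
    }


def summarize_bacterial_phyla(phylum_labels) -> dict:
    """Per-phylum genome counts; values sum to the number of genomes."""
    series = pd.Series(list(phylum_labels))
    return series.value_counts().to_dict()


def run_experiment(config: RunConfig) -> dict:
    """Execute a full scenario and return (and optionally write) the report."""
    if config.scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {config.scenario!r}; pick from {sorted(SCENARIOS)}")
    scen = SCENARIOS[config.scenario]
    community = dataclasses.replace(config.community, effect_log2fc=scen["effect_log2fc"])
    design = StudyDesign(groups=list(scen["groups"]), seed=config.seed)
    report: dict = {"config": config.resolved(), "scenario": config.scenario}

    # --- simulate ---------------------------------------------------------
    gt = build_community(community, seed=config.seed, design=design)
    coverage = simulate_coverage(gt, seed=config.seed)
    metadata = design.sample_frame()
    report["input_hash"] = gt.content_hash()
    report["ground_truth"] = {
        "n_bacteria": len(gt.bacteria),
        "n_temperate": sum(p.lifestyle_true == "temperate" for p in gt.phages),
        "n_virulent": sum(p.lifestyle_true == "virulent" for p in gt.phages),
        "true_da_features": sorted(gt.true_da_features),
    }

    # --- discover ---------------------------------------------------------
    contigs = emit_catalog_inputs(gt, seed=config.seed)
    catalog = build_viral_catalog(contigs)
    discard = pd.Series(list(catalog.rejected.values())).value_counts().to_dict()
    logger.info("viral validation discards: %s", discard)
    report["catalog"] = summarize_catalog(catalog)
    report["catalog"]["discards"] = discard
    report["bacterial_phyla"] = summarize_bacterial_phyla(
        b.phylum_label for b in gt.bacteria)

    # --- profile ----------------------------------------------------------
    viral_ids = [s.srg_id for s in catalog.srgs]
    bact_ids = [b.species_id for b in gt.bacteria]
    cov_bulk = coverage[coverage["assay"] == "bulk"]
    cov_vlp = coverage[coverage["assay"] == "vlp"]
    tables = {
        "bacterial_bulk": build_feature_table(
            cov_bulk, "bacterial", config.min_samples, metadata=metadata,
            feature_ids=bact_ids),
        "viral_bulk": build_feature_table(
            cov_bulk, "viral", config.min_samples, catalog=catalog, metadata=metadata,
            feature_ids=viral_ids),
        "viral_vlp": build_feature_table(
            cov_vlp, "viral", config.min_samples, catalog=catalog, metadata=metadata,
            feature_ids=viral_ids),
    }
    report["prevalence_discards"] = {}
    candidates = {"bacterial_bulk": len(bact_ids), "viral_bulk": len(viral_ids),
                  "viral_vlp": len(viral_ids)}
    for name, table in tables.items():
        dropped = candidates[name] - table.counts.shape[0]
        report["prevalence_discards"][name] = dropped
        logger.info("%s: %d features dropped by the prevalence rule", name, dropped)

    lifestyle = catalog.lifestyle_map()
    report["lifestyle_totals"] = {}
    for name in ("viral_bulk", "viral_vlp"):
        rel, _ = to_relative(tables[name])
        totals = lifestyle_totals(rel, lifestyle)
        report["lifestyle_totals"][name] = totals.mean(axis=1).to_dict()

    # --- saturate (optional) ---------------------------------------------
    if config.run_saturation:
        report["saturation"] = _saturation_stage(gt, coverage, viral_ids, config)

    # --- stats ------------------------------------------------------------
    report["stats"] = {}
    groups = metadata.set_index("sample_id")["group"]
    ordinations = {}
    for name, table in tables.items():
        if table.counts.empty or table.counts.shape[1] < 4:
            continue
        labels = groups.loc[table.samples]
        obs = alpha_diversity(table.counts, "observed")
        richness = group_compare(obs.values, labels.values)
        dm = bray_curtis(table.counts)
        perm = permanova(dm, labels.values, n_perm=config.n_permutations,
                         seed=config.seed)
        ordinations[name] = pcoa(dm)
        report["stats"][name] = {
            "richness_p": richness.p_value, "richness_method": richness.method,
            "permanova_p": perm.p_value, "permanova_r2": perm.effect,
            "permanova_f": perm.statistic, "n_permutations": perm.n_permutations,
        }
    if "bacterial_bulk" in ordinations and "viral_bulk" in ordinations:
        proc = procrustes_test(ordinations["bacterial_bulk"].coordinates,
                               ordinations["viral_bulk"].coordinates,
                               n_perm=config.n_permutations, seed=config.seed)
        report["stats"]["procrustes_bulk"] = {
            "m2": proc.statistic, "r": proc.effect, "p": proc.p_value,
        }

    # --- differential abundance ------------------------------------------
    report["differential_abundance"] = {}
    reference = design.groups[0]
    for name in ("bacterial_bulk", "viral_bulk"):
        table = tables[name]
        if table.counts.empty:
            continue
        labels = groups.loc[table.samples]
        result = run_consensus(table.counts, labels.values, reference=reference,
                               lfc_threshold=config.lfc_threshold, alpha=config.alpha)
        truth = set(gt.true_da_features)
        report["differential_abundance"][name] = {
            "consensus_features": sorted(result.consensus_features),
            "n_consensus": len(result.consensus_features),
            "confusion_vs_truth": result.confusion(truth),
        }

    # --- functional profiling --------------------------------------------
    if config.run_gene_profiling:
        orf_cov, orf_map = simulate_gene_coverage(gt, seed=config.seed)
        gene_table = profile_genes(orf_cov, orf_map, metadata=metadata)
        if not gene_table.counts.empty:
            rel_genes, _ = to_relative(gene_table)
            scfa = scfa_totals(rel_genes)
            report["scfa_totals"] = {acid: row.to_dict() for acid, row in scfa.iterrows()}

    if config.outdir:
        _write_outputs(Path(config.outdir), gt, coverage, metadata, catalog,
                       tables, report)
    return report


def _saturation_stage(gt, coverage: pd.DataFrame, viral_ids, config: RunConfig) -> dict:
    grid = DepthGrid()
    sample = coverage["sample_id"].iloc[0].rsplit("_", 1)[0]
    out: dict = {}
    native = {a: gt.design.reads_per_sample[a] for a in gt.design.assays}
    for assay, kind in (("bulk", "bacterial"), ("bulk", "viral"), ("vlp", "viral")):
        records = coverage[(coverage["assay"] == assay)
                           & (coverage["sample_id"] == f"{sample}_{assay}")]
        if kind == "viral":
            records = records[records["feature_id"].isin(viral_ids)]
        else:
            records = records[~records["feature_id"].isin(viral_ids)]
        depths = tuple(d for d in grid.depths(assay) if d <= native[assay])
        curve = rarefaction_curve(records, kind, depths, native[assay],
                                  replicates=grid.replicates, seed=config.seed)
        depth, saturated = detect_plateau(curve, config.plateau_epsilon)
        out[f"{assay}_{kind}"] = {
            "curve": curve.groupby("depth")["count"].mean().to_dict(),
            "plateau_depth": depth, "saturated": saturated,
        }
    # VLP-capture grid: which VLP-detected viral genomes the bulk assay sees
    vlp_records = coverage[(coverage["assay"] == "vlp")
                           & (coverage["sample_id"] == f"{sample}_vlp")
                           & (coverage["feature_id"].isin(viral_ids))]
    from .profiling import call_presence_frame
    vlp_detected = set(vlp_records.loc[call_presence_frame(vlp_records, "viral"),
                                       "feature_id"])
    bulk_records = coverage[(coverage["assay"] == "bulk")
                            & (coverage["sample_id"] == f"{sample}_bulk")
                            & (coverage["feature_id"].isin(viral_ids))]
    by_depth = {d: thin_coverage_frame(bulk_records, d / native["bulk"],
                                       seed=config.seed + 7)
                for d in grid.bulk_depths if d <= native["bulk"]}
    if vlp_detected and by_depth:
        cap = capture_fraction(by_depth, vlp_detected)
        out["capture_grid"] = {
            "thresholds": list(cap.breadth_thresholds),
            "depths": list(cap.depths),
            "capture_pct": cap.capture_pct.values.tolist(),
        }
    return out


def _write_outputs(outdir: Path, gt, coverage, metadata, catalog, tables, report) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "ground_truth.json").write_text(gt.to_json())
    dio.write_coverage_tsv(coverage, outdir / "coverage.tsv")
    dio.write_metadata_tsv(metadata, outdir / "metadata.tsv")
    dio.write_catalog_tsv(catalog, outdir / "viral_catalog.tsv")
    for name, table in tables.items():
        if not table.counts.empty:
            dio.write_feature_table(table, outdir / f"table_{name}.tsv")
    dio.write_json(report, outdir / "report.json")
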