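"""Synthetic gut community generator for paired bulk / VLP metagenomes.

The generator plants a ground-truth community of bacterial hosts, integrated
prophages (temperate phages) and free virulent phages, and converts it into the
per-sample, per-assay coverage summaries the profiling stages consume.  The
abundance model encodes the biology the dual-source design relies on:

* bacterial cell abundances are lognormal across mice, shifted per condition by
  a planted log2 fold change for differentially abundant taxa;
* a temperate phage rides its host — its bulk abundance is the host cell
  abundance times an integrated copy factor, while its VLP abundance is only
  the induced fraction (``induction_rate`` of host cells releasing virions);
* virulent phages contribute free virions to both assays;
* the VLP assay carries a small bacterial contamination fraction.

Coverage is generated from the Lander–Waterman expectation (breadth of
coverage ``1 - exp(-depth)``) with binomial thinning on covered positions,
which keeps the simulation at summary level instead of per-read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discovery import AnnotatedContig, GeneAnnotation
from .profiling import COVERAGE_COLUMNS

LN2 = math.log(2.0)

STRUCTURAL_VOCAB = (
    "terminase", "capsid", "tail", "amidase", "baseplate", "prohead", "coat", "virion",
)
LYSOGENY_VOCAB = ("integrase", "transposase", "recombinase", "cro_ci")

# Phylum labels drawn with roughly the composition observed in murine gut
# metagenome surveys (Bacillota-dominated, then Bacteroidota).
PHYLUM_LABELS = (
    "Bacillota", "Bacteroidota", "Actinomycetota", "Desulfobacteriota",
    "Pseudomonadota", "Deferribacterota", "Verrucomicrobiota",
)
PHYLUM_WEIGHTS = (75, 21, 3, 3, 2, 1, 1)

#: KEGG orthologs used when painting SCFA-production genes onto hosts.
SCFA_KO_POOL = (
    "K01034", "K01035", "K00634", "K00925", "K01895", "K01913",
    "K00128", "K00138", "K01026", "K00932", "K01908", "K20454",
)
CAZYME_POOL = ("GH43", "GH13", "GH2", "GH3", "GH29", "GH92", "PL1", "CE1")


class ConfigurationError(ValueError):
    """Raised for invalid community or design parameters."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BacterialSpecies:
    species_id: str
    genome_length: int
    phylum_label: str
    gene_complement: list[str]
    base_log_abundance: float
    effect_log2fc: float = 0.0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ConfigurationError(f"{self.species_id}: genome_length must be > 0")
        if not self.gene_complement:
            raise ConfigurationError(f"{self.species_id}: gene_complement is empty")


@dataclass
class PhageSpecies:
    phage_id: str
    genome_length: int
    lifestyle_true: str  # "temperate" | "virulent"
    host_id: str | None = None
    induction_rate: float = 0.0
    virion_abundance_log: float = 0.0
    structural_genes: list[str] = field(default_factory=list)
    lysogeny_markers: list[str] = field(default_factory=list)
    amg_flags: list[bool] = field(default_factory=list)
    completeness_pct: float = 100.0
    host_evidence: bool = False
    predictor_flags: dict[str, bool] = field(
        default_factory=lambda: {"virsorter_like": True, "vibrant_like": True}
    )

    def __post_init__(self) -> None:
        if self.lifestyle_true not in ("temperate", "virulent"):
            raise ConfigurationError(f"{self.phage_id}: bad lifestyle {self.lifestyle_true!r}")
        if not 0.0 <= self.induction_rate <= 1.0:
            raise ConfigurationError(f"{self.phage_id}: induction_rate outside [0, 1]")
        if self.lifestyle_true == "temperate":
            if self.host_id is None:
                raise ConfigurationError(f"{self.phage_id}: temperate phage lacks a host")
            if not self.lysogeny_markers and not self.host_evidence:
                raise ConfigurationError(
                    f"{self.phage_id}: temperate phage needs lysogeny markers or host evidence"
                )


@dataclass
class StudyDesign:
    groups: list[str]
    n_per_group: int = 4
    assays: tuple[str, ...] = ("bulk", "vlp")
    reads_per_sample: dict[str, int] = field(
        default_factory=lambda: {"bulk": 20_000_000, "vlp": 15_000_000}
    )
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        for assay in self.assays:
            if self.reads_per_sample.get(assay, 0) <= 0:
                raise ConfigurationError(f"reads_per_sample[{assay}] must be > 0")

    def total_bases(self, assay: str) -> float:
        # paired-end read pairs -> 2 * read_length bases each
        return float(self.reads_per_sample[assay]) * 2.0 * self.read_length

    def sample_frame(self) -> pd.DataFrame:
        rows = []
        for group in self.groups:
            for i in range(self.n_per_group):
                mouse = f"{group}_m{i + 1}"
                for assay in self.assays:
                    rows.append({
                        "sample_id": f"{mouse}_{assay}",
                        "mouse_id": mouse,
                        "group": group,
                        "assay": assay,
                    })
        return pd.DataFrame(rows)


@dataclass
class CommunityConfig:
    """Parameters of the planted community; defaults emulate the study design
    at desk scale (a Bacillota-dominated host community where temperate phage
    species outnumber virulent ones, and virions of virulent phages dominate
    the VLP fraction)."""

    n_bacteria: int = 40
    n_temperate: int = 60
    n_virulent: int = 25
    bacterial_length_range: tuple[int, int] = (1_500_000, 5_000_000)
    phage_length_range: tuple[int, int] = (20_000, 80_000)
    base_log_sd: float = 1.0
    lognormal_sigma: float = 0.8          # inter-mouse variation, natural-log scale
    prophage_copy_factor: float = 1.0     # integrated copies per host genome
    induction_rate_range: tuple[float, float] = (0.005, 0.05)
    virulent_log_mean: float = -1.5       # virion abundance relative to host cells
    virulent_log_sd: float = 1.0
    vlp_contamination: float = 0.005      # bacterial fraction of VLP bases
    # planted diet effect (fiber scenario): 6 enriched and 4 depleted hosts,
    # |log2FC| = 4; their prophages inherit the host shift.
    n_enriched: int = 6
    n_depleted: int = 4
    effect_log2fc: float = 4.0
    da_threshold: float = 2.0
    n_decoys: int = 10                    # junk contigs the validation cascade must drop
    genes_per_bacterium: int = 12

    def validate(self) -> None:
        if min(self.n_bacteria, self.n_temperate, self.n_virulent) < 1:
            raise ConfigurationError("species counts must be >= 1")
        if self.n_temperate <= 0 or self.n_virulent <= 0:
            raise ConfigurationError("temperate:virulent ratio must be finite and positive")
        if self.n_enriched + self.n_depleted > self.n_bacteria:
            raise ConfigurationError("more planted DA hosts than bacteria")
        if not 0.0 <= self.vlp_contamination < 1.0:
            raise ConfigurationError("vlp_contamination must be in [0, 1)")


@dataclass
class GroundTruth:
    bacteria: list[BacterialSpecies]
    phages: list[PhageSpecies]
    design: StudyDesign
    true_da_features: list[str] = field(default_factory=list)
    config: CommunityConfig | None = None

    def __post_init__(self) -> None:
        host_ids = {b.species_id for b in self.bacteria}
        for p in self.phages:
            if p.lifestyle_true == "temperate" and p.host_id not in host_ids:
                raise ConfigurationError(f"{p.phage_id}: host {p.host_id!r} not in community")
        ids = {b.species_id for b in self.bacteria} | {p.phage_id for p in self.phages}
        unknown = set(self.true_da_features) - ids
        if unknown:
            raise ConfigurationError(f"true_da_features not in community: {sorted(unknown)}")

    @property
    def feature_lengths(self) -> dict[str, int]:
        out = {b.species_id: b.genome_length for b in self.bacteria}
        out.update({p.phage_id: p.genome_length for p in self.phages})
        return out

    def lifestyle_map(self) -> dict[str, str]:
        return {p.phage_id: p.lifestyle_true for p in self.phages}

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj).__name__)
        return json.dumps(dataclasses.asdict(self), default=enc, indent=1, sort_keys=True)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


# ---------------------------------------------------------------------------
# community construction
# ---------------------------------------------------------------------------

def build_community(config: CommunityConfig | None = None, seed: int = 0,
                    groups: tuple[str, str] = ("control", "treated"),
                    design: StudyDesign | None = None) -> GroundTruth:
    """Draw a ground-truth community. Deterministic for a fixed (config, seed)."""
    config = config or CommunityConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    if design is None:
        design = StudyDesign(groups=list(groups), seed=seed)

    phylum_p = np.asarray(PHYLUM_WEIGHTS, float)
    phylum_p /= phylum_p.sum()

    bacteria: list[BacterialSpecies] = []
    effects = np.zeros(config.n_bacteria)
    effects[: config.n_enriched] = config.effect_log2fc
    effects[config.n_enriched: config.n_enriched + config.n_depleted] = -config.effect_log2fc
    for i in range(config.n_bacteria):
        genes = list(rng.choice(SCFA_KO_POOL, size=config.genes_per_bacterium // 2,
                                replace=False))
        # enriched (high-fiber analog) hosts carry extra fiber-degrading CAZymes
        n_caz = 4 if effects[i] > 0 else 1
        genes += list(rng.choice(CAZYME_POOL, size=n_caz, replace=True))
        if effects[i] > 0:
            genes.append("GH43")
        genes += ["none"] * max(0, config.genes_per_bacterium - len(genes))
        # diet responders sit symmetrically about the community mean (enriched
        # taxa start below it, depleted above), so the planted fold change is
        # realised on the relative scale the profiling observes instead of
        # being compressed by the community-wide mass shift
        base = rng.normal(0.0, config.base_log_sd) - effects[i] * LN2 / 2.0
        bacteria.append(BacterialSpecies(
            species_id=f"bact_{i:03d}",
            genome_length=int(rng.integers(*config.bacterial_length_range)),
            phylum_label=str(rng.choice(PHYLUM_LABELS, p=phylum_p)),
            gene_complement=genes,
            base_log_abundance=float(base),
            effect_log2fc=float(effects[i]),
        ))

    phages: list[PhageSpecies] = []
    # every bacterium listed as a host carries >= 1 prophage: assign the first
    # n_bacteria temperate phages round-robin, the rest at random
    host_assignment = [i % config.n_bacteria for i in range(config.n_temperate)]
    if config.n_temperate > config.n_bacteria:
        extra = rng.integers(0, config.n_bacteria, size=config.n_temperate - config.n_bacteria)
        host_assignment[config.n_bacteria:] = list(extra)
    for j in range(config.n_temperate):
        host = bacteria[host_assignment[j]]
        n_struct = int(rng.integers(2, 6))
        n_lys = int(rng.integers(1, 4))
        n_amg = int(rng.integers(0, 3))
        phages.append(PhageSpecies(
            phage_id=f"phage_t{j:03d}",
            genome_length=int(rng.integers(*config.phage_length_range)),
            lifestyle_true="temperate",
            host_id=host.species_id,
            induction_rate=float(rng.uniform(*config.induction_rate_range)),
            structural_genes=list(rng.choice(STRUCTURAL_VOCAB, size=n_struct, replace=False)),
            lysogeny_markers=list(rng.choice(LYSOGENY_VOCAB, size=n_lys, replace=False)),
            amg_flags=[True] * n_amg,
            completeness_pct=float(rng.uniform(55.0, 100.0)),
        ))
    for j in range(config.n_virulent):
        n_struct = int(rng.integers(2, 6))
        phages.append(PhageSpecies(
            phage_id=f"phage_v{j:03d}",
            genome_length=int(rng.integers(*config.phage_length_range)),
            lifestyle_true="virulent",
            virion_abundance_log=float(rng.normal(config.virulent_log_mean,
                                                  config.virulent_log_sd)),
            structural_genes=list(rng.choice(STRUCTURAL_VOCAB, size=n_struct, replace=False)),
            completeness_pct=float(rng.uniform(55.0, 100.0)),
        ))

    host_effect = {b.species_id: b.effect_log2fc for b in bacteria}
    true_da = [b.species_id for b in bacteria if abs(b.effect_log2fc) >= config.da_threshold]
    true_da += [p.phage_id for p in phages
                if p.lifestyle_true == "temperate"
                and abs(host_effect[p.host_id]) >= config.da_threshold]

    return GroundTruth(bacteria=bacteria, phages=phages, design=design,
                       true_da_features=true_da, config=config)


# ---------------------------------------------------------------------------
# abundance model
# ---------------------------------------------------------------------------

def simulate_relative_abundances(gt: GroundTruth, seed: int = 0,
                                 noise: bool = True) -> pd.DataFrame:
    """Per-sample, per-assay relative abundance (fraction of sequenced bases).

    Returns a tidy frame (feature_id, sample_id, assay, group, rel_abundance);
    each (sample, assay) vector sums to 1.  Treatment effects apply to the
    second group of the design (the first group is the reference).
    """
    config = gt.config or CommunityConfig()
    rng = np.random.default_rng(seed)
    samples = gt.design.sample_frame()
    mice = samples[["mouse_id", "group"]].drop_duplicates().reset_index(drop=True)
    reference = gt.design.groups[0]

    sigma = config.lognormal_sigma if noise else 0.0
    rows = []
    for _, mouse in mice.iterrows():
        treated = mouse["group"] != reference
        cell = {}
        for b in gt.bacteria:
            mu = b.base_log_abundance + (b.effect_log2fc * LN2 if treated else 0.0)
            cell[b.species_id] = math.exp(mu + (rng.normal(0.0, sigma) if sigma else 0.0))
        virion = {}
        for p in gt.phages:
            if p.lifestyle_true == "virulent":
                mu = p.virion_abundance_log
                virion[p.phage_id] = math.exp(mu + (rng.normal(0.0, sigma) if sigma else 0.0))

        # base-scale weights: cell/virion abundance x genome length
        bulk_w = {b.species_id: cell[b.species_id] * b.genome_length for b in gt.bacteria}
        vlp_w: dict[str, float] = {}
        for p in gt.phages:
            if p.lifestyle_true == "temperate":
                host_cells = cell[p.host_id]
                bulk_w[p.phage_id] = (host_cells * config.prophage_copy_factor
                                      * p.genome_length)
                vlp_w[p.phage_id] = p.induction_rate * host_cells * p.genome_length
            else:
                bulk_w[p.phage_id] = virion[p.phage_id] * p.genome_length
                vlp_w[p.phage_id] = virion[p.phage_id] * p.genome_length

        # bacterial carry-over into the VLP prep
        c = config.vlp_contamination
        if c > 0:
            phage_total = sum(vlp_w.values())
            bact_total = sum(cell[b.species_id] * b.genome_length for b in gt.bacteria)
            if phage_total > 0 and bact_total > 0:
                scale = (c / (1.0 - c)) * phage_total / bact_total
                for b in gt.bacteria:
                    vlp_w[b.species_id] = scale * cell[b.species_id] * b.genome_length

        for assay, weights in (("bulk", bulk_w), ("vlp", vlp_w)):
            if assay not in gt.design.assays:
                continue
            total = sum(weights.values())
            sid = f"{mouse['mouse_id']}_{assay}"
            for fid, w in weights.items():
                rows.append({
                    "feature_id": fid, "sample_id": sid, "assay": assay,
                    "group": mouse["group"],
                    "rel_abundance": w / total if total > 0 else 0.0,
                })
    return pd.DataFrame(rows)


def abundance_to_coverage(rel_abundance: float, total_bases_sequenced: float,
                          feature_length: int, seed: int | np.random.Generator = 0,
                          noise: bool = True, *, feature_id: str = "feature",
                          sample_id: str = "sample", assay: str = "bulk") -> dict:
    """Lander–Waterman coverage summary for one feature in one library.

    mean depth ``lambda = a * T / L``; expected breadth ``1 - exp(-lambda)``;
    with ``noise`` the covered-base count is binomially thinned around that
    expectation.  Returns a dict matching the coverage-record column set.
    """
    if rel_abundance < 0 or rel_abundance > 1:
        raise ValueError("rel_abundance must be in [0, 1]")
    if feature_length <= 0 or total_bases_sequenced < 0:
        raise ValueError("lengths and totals must be positive")
    lam = rel_abundance * total_bases_sequenced / feature_length
    expected = -math.expm1(-lam)
    if noise and 0.0 < expected < 1.0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        covered = int(rng.binomial(feature_length, expected))
    else:
        covered = int(round(expected * feature_length))
    return {
        "feature_id": feature_id, "sample_id": sample_id, "assay": assay,
        "length": int(feature_length), "covered_bases": covered,
        "breadth": covered / feature_length, "mean_depth": lam,
    }


def simulate_coverage(gt: GroundTruth, seed: int = 0, noise: bool = True) -> pd.DataFrame:
    """Full coverage-record table for every (feature, sample, assay) of a run."""
    rel = simulate_relative_abundances(gt, seed=seed, noise=noise)
    rng = np.random.default_rng(seed + 1 if isinstance(seed, int) else None)
    lengths = gt.feature_lengths
    records = []
    for row in rel.itertuples(index=False):
        records.append(abundance_to_coverage(
            row.rel_abundance, gt.design.total_bases(row.assay), lengths[row.feature_id],
            seed=rng, noise=noise, feature_id=row.feature_id,
            sample_id=row.sample_id, assay=row.assay,
        ))
    return pd.DataFrame(records, columns=COVERAGE_COLUMNS)


def simulate_gene_coverage(gt: GroundTruth, seed: int = 0, noise: bool = True,
                           gene_length: int = 1_000) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-ORF bulk coverage for bacterial gene profiling.

    Each host gene is modelled as a fixed-length ORF whose depth equals the
    host genome depth.  Returns (orf coverage records, orf_id -> gene_id map).
    """
    rel = simulate_relative_abundances(gt, seed=seed, noise=noise)
    rel = rel[rel["assay"] == "bulk"]
    rng = np.random.default_rng(seed + 2 if isinstance(seed, int) else None)
    records = []
    orf_to_gene: dict[str, str] = {}
    glen = {b.species_id: b.genome_length for b in gt.bacteria}
    genes = {b.species_id: b.gene_complement for b in gt.bacteria}
    for row in rel.itertuples(index=False):
        if row.feature_id not in genes:
            continue
        depth = row.rel_abundance * gt.design.total_bases("bulk") / glen[row.feature_id]
        for k, label in enumerate(genes[row.feature_id]):
            if label == "none":
                continue
            orf_id = f"{row.feature_id}_orf{k:03d}"
            orf_to_gene[orf_id] = label
            rel_orf = depth * gene_length / gt.design.total_bases("bulk")
            records.append(abundance_to_coverage(
                rel_orf, gt.design.total_bases("bulk"), gene_length, seed=rng,
                noise=noise, feature_id=orf_id, sample_id=row.sample_id, assay="bulk",
            ))
    return pd.DataFrame(records, columns=COVERAGE_COLUMNS), orf_to_gene


# ---------------------------------------------------------------------------
# catalog inputs (annotated contigs)
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(["A", "C", "G", "T"])[rng.integers(0, 4, size=length)])


def emit_catalog_inputs(gt: GroundTruth, seed: int = 0,
                        with_sequences: bool = False,
                        sequence_length: int = 2_000) -> list[AnnotatedContig]:
    """One annotated contig per phage, plus decoy contigs that the validation
    cascade must reject.  Sequences (random, ``sequence_length`` bases, used
    only by dereplication) are attached on request."""
    config = gt.config or CommunityConfig()
    rng = np.random.default_rng(seed)
    contigs = []
    for p in gt.phages:
        genes, pos = [], 1
        for g, label in enumerate(p.structural_genes):
            genes.append(GeneAnnotation(f"{p.phage_id}_g{len(genes)}", pos, pos + 899,
                                        "+", "structural", label))
            pos += 1000
        for label in p.lysogeny_markers:
            genes.append(GeneAnnotation(f"{p.phage_id}_g{len(genes)}", pos, pos + 899,
                                        "+", "lysogeny_marker", label))
            pos += 1000
        for _ in p.amg_flags:
            genes.append(GeneAnnotation(f"{p.phage_id}_g{len(genes)}", pos, pos + 899,
                                        "+", "metabolic", str(rng.choice(SCFA_KO_POOL))))
            pos += 1000
        contigs.append(AnnotatedContig(
            contig_id=p.phage_id, length=p.genome_length,
            sequence=_random_sequence(rng, sequence_length) if with_sequences else None,
            source="bin" if p.lifestyle_true == "temperate" else "vlp",
            genes=genes, completeness_pct=p.completeness_pct, contamination_pct=0.0,
            predictor_flags=dict(p.predictor_flags),
            host_homology_evidence=p.host_evidence,
            host_bin_id=p.host_id if p.lifestyle_true == "temperate" else None,
        ))
    for d in range(config.n_decoys):
        mode = d % 3
        genes = [GeneAnnotation(f"decoy_{d:02d}_g0", 1, 900, "+", "structural",
                                str(rng.choice(STRUCTURAL_VOCAB)))]
        contigs.append(AnnotatedContig(
            contig_id=f"decoy_{d:02d}", length=int(rng.integers(5_000, 30_000)),
            sequence=_random_sequence(rng, sequence_length) if with_sequences else None,
            source="bulk_unbinned",
            genes=[] if mode == 1 else genes,
            completeness_pct=float(rng.uniform(10.0, 45.0)) if mode == 0 else 80.0,
            contamination_pct=0.0,
            predictor_flags={"virsorter_like": mode != 2, "vibrant_like": False},
            host_homology_evidence=False,
        ))
    return contigs
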