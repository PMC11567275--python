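"""Presence calling and abundance profiling from coverage summaries.

Coverage summaries follow the `samtools coverage` column set (length, covered
bases, breadth, mean depth) per (feature, sample, assay).  A genome counts as
detected in a sample when enough of its length is covered — breadth >= 70% or
an absolute covered-length floor (5 kb for viral genomes, 100 kb for bacterial
ones).  Raw abundance is the rounded mean depth where detected; features seen
in fewer than three samples of an assay are dropped before any statistics.

Gene-level (functional) profiles use a stricter rule: an ORF is detected only
when its breadth exceeds 70% (strictly), and abundances of ORFs sharing a
gene identifier are summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COVERAGE_COLUMNS = [
    "feature_id", "sample_id", "assay", "length", "covered_bases", "breadth", "mean_depth",
]

PRESENCE_BREADTH = 0.70
VIRAL_MIN_COVERED_BP = 5_000
BACTERIAL_MIN_COVERED_BP = 100_000
GENE_MIN_BREADTH = 0.70  # strict >

#: KEGG orthologs whose products catalyse short-chain fatty acid production.
SCFA_GENE_GROUPS: dict[str, frozenset[str]] = {
    "acetate": frozenset({
        "K00128", "K00149", "K00138", "K14085", "K00129", "K24012", "K01905",
        "K22224", "K00925", "K19670", "K02576", "K02577", "K02578", "K18118",
        "K01026", "K01067", "K01895", "K01913", "K00467", "K00156", "K01512",
        "K10150", "K01738", "K13034", "K17069",
    }),
    "butyrate": frozenset({
        "K01034", "K01035", "K19709", "K23756", "K01896", "K01913", "K00929", "K00634",
    }),
    "propionate": frozenset({
        "K00925", "K00932", "K19697", "K01895", "K01908", "K20454",
    }),
}


def round_half_away(x) -> np.ndarray:
    """Round halves away from zero (2.5 -> 3), unlike banker's rounding."""
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, np.floor(x + 0.5), np.ceil(x - 0.5))


@dataclass
class FeatureTable:
    """Features x samples matrix of non-negative integer abundances."""

    counts: pd.DataFrame
    kind: str  # viral | bacterial | gene
    catalog: object | None = None
    metadata: pd.DataFrame | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("feature table contains negative abundances")

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def group_labels(self, column: str = "group") -> pd.Series:
        if self.metadata is None:
            raise ValueError("feature table carries no sample metadata")
        meta = self.metadata.set_index("sample_id")
        return meta.loc[self.samples, column]


# ---------------------------------------------------------------------------
# presence calling
# ---------------------------------------------------------------------------

def call_presence(record, kind: str) -> bool:
    """Detection rule for one coverage record (mapping or namedtuple-like)."""
    breadth = record["breadth"] if isinstance(record, (dict, pd.Series)) else record.breadth
    covered = (record["covered_bases"] if isinstance(record, (dict, pd.Series))
               else record.covered_bases)
    if kind == "viral":
        floor = VIRAL_MIN_COVERED_BP
    elif kind == "bacterial":
        floor = BACTERIAL_MIN_COVERED_BP
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    return bool(breadth >= PRESENCE_BREADTH or covered >= floor)


def call_presence_frame(records: pd.DataFrame, kind: str) -> pd.Series:
    """Vectorised presence call over a coverage-record frame."""
    if kind == "viral":
        floor = VIRAL_MIN_COVERED_BP
    elif kind == "bacterial":
        floor = BACTERIAL_MIN_COVERED_BP
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    return (records["breadth"] >= PRESENCE_BREADTH) | (records["covered_bases"] >= floor)


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def build_feature_table(records: pd.DataFrame, kind: str, min_samples: int = 3,
                        catalog=None, metadata: pd.DataFrame | None = None,
                        feature_ids: list[str] | None = None) -> FeatureTable:
    """Integer abundance table from one assay's coverage records.

    Abundance is the half-away-from-zero rounded mean depth where the feature
    is detected, 0 elsewhere; features detected in fewer than ``min_samples``
    samples are dropped.  ``feature_ids`` restricts the table (e.g. to a viral
    catalog) before the prevalence rule is applied.
    """
    if records.duplicated(["feature_id", "sample_id"]).any():
        dup = records[records.duplicated(["feature_id", "sample_id"])].iloc[0]
        raise ValueError(f"duplicate coverage record: {dup['feature_id']}/{dup['sample_id']}")
    if len(records) and records["assay"].nunique() > 1:
        raise ValueError("records span multiple assays; build per-assay tables")
    records = records.copy()
    if feature_ids is not None:
        records = records[records["feature_id"].isin(set(feature_ids))]
    if not len(records):
        return FeatureTable(counts=pd.DataFrame(), kind=kind, catalog=catalog,
                            metadata=metadata)
    present = call_presence_frame(records, kind)
    records["abundance"] = np.where(present, round_half_away(records["mean_depth"]), 0)
    wide = (records.pivot(index="feature_id", columns="sample_id", values="abundance")
            .fillna(0.0))
    prevalence = (records.assign(present=present)
                  .groupby("feature_id")["present"].sum())
    keep = prevalence[prevalence >= min_samples].index
    wide = wide.loc[wide.index.isin(keep)]
    wide = wide.sort_index().sort_index(axis=1).astype(np.int64)
    return FeatureTable(counts=wide, kind=kind, catalog=catalog, metadata=metadata)


def to_relative(table: FeatureTable | pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Column-normalised (per-sample) relative abundances.

    Returns (fractions, all-zero sample ids); all-zero columns stay zero.
    """
    counts = table.counts if isinstance(table, FeatureTable) else table
    sums = counts.sum(axis=0)
    zero_samples = list(sums.index[sums == 0])
    safe = sums.replace(0, 1)
    return counts.div(safe, axis=1).astype(float), zero_samples


def lifestyle_totals(rel_table: pd.DataFrame, catalog) -> pd.DataFrame:
    """Per-sample total relative abundance of temperate and virulent SRGs.

    ``catalog`` is a ViralCatalog or a feature_id -> lifestyle mapping.
    """
    lifestyle = catalog if isinstance(catalog, dict) else catalog.lifestyle_map()
    missing = [f for f in rel_table.index if f not in lifestyle]
    if missing:
        raise KeyError(f"features missing from catalog: {missing[:5]}")
    groups = pd.Series({f: lifestyle[f] for f in rel_table.index}, name="lifestyle")
    totals = rel_table.groupby(groups).sum()
    return totals.reindex(["temperate", "virulent"]).fillna(0.0)


# ---------------------------------------------------------------------------
# functional (gene) profiling
# ---------------------------------------------------------------------------

def profile_genes(orf_records: pd.DataFrame, annotations: dict[str, str],
                  min_breadth: float = GENE_MIN_BREADTH,
                  metadata: pd.DataFrame | None = None) -> FeatureTable:
    """Gene-level abundance table from per-ORF coverage.

    An ORF is detected iff its breadth strictly exceeds ``min_breadth``; its
    raw abundance is the mean depth.  Abundances of detected ORFs sharing a
    gene identifier are summed, then integerised half-away-from-zero.  ORFs
    without an annotation count under their own identifier.
    """
    records = orf_records[orf_records["breadth"] > min_breadth].copy()
    if not len(records):
        return FeatureTable(counts=pd.DataFrame(), kind="gene", metadata=metadata)
    records["gene_id"] = [annotations.get(f, f) for f in records["feature_id"]]
    summed = (records.groupby(["gene_id", "sample_id"])["mean_depth"].sum()
              .unstack(fill_value=0.0))
    counts = pd.DataFrame(round_half_away(summed.values), index=summed.index,
                          columns=summed.columns).astype(np.int64)
    counts = counts.sort_index().sort_index(axis=1)
    return FeatureTable(counts=counts, kind="gene", metadata=metadata)


def scfa_totals(rel_gene_table: pd.DataFrame,
                groups: dict[str, frozenset[str]] | None = None) -> pd.DataFrame:
    """Cumulative relative abundance of SCFA-production genes per sample.

    A gene listed under two acids (e.g. K01895) contributes to both totals.
    """
    groups = groups or SCFA_GENE_GROUPS
    out = {}
    for acid, kos in groups.items():
        hit = rel_gene_table.index.isin(kos)
        out[acid] = rel_gene_table.loc[hit].sum(axis=0)
    result = pd.DataFrame(out).T
    if rel_gene_table.shape[1]:
        result = result.reindex(columns=rel_gene_table.columns, fill_value=0.0)
    return result
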