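"""Readers and writers for the pipeline's plain-text interchange formats.

FASTA via Biopython; annotation/coverage/metadata/feature tables as TSV;
ground truth and run reports as JSON.  The annotation TSV carries one row per
gene plus one ``contig`` row per contig holding the contig-level fields
(length, source, completeness, contamination, predictor flags, host
evidence), so a contig with no genes still round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .discovery import AnnotatedContig, GeneAnnotation, ViralCatalog
from .profiling import COVERAGE_COLUMNS, FeatureTable

ANNOTATION_COLUMNS = [
    "contig_id", "gene_id", "start", "end", "strand", "category", "label",
]


def write_fasta(contigs, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.contig_id, description="")
        for c in contigs if c.sequence is not None
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_annotation_tsv(contigs, path: str | Path) -> None:
    rows = []
    for c in contigs:
        flags = ",".join(k for k, v in sorted(c.predictor_flags.items()) if v)
        meta = (f"length={c.length};source={c.source};"
                f"completeness={c.completeness_pct};contamination={c.contamination_pct};"
                f"predictors={flags};host_evidence={int(c.host_homology_evidence)};"
                f"host_bin={c.host_bin_id or ''};family={c.family_label or ''}")
        rows.append({"contig_id": c.contig_id, "gene_id": "__contig__", "start": 1,
                     "end": c.length, "strand": "+", "category": "contig", "label": meta})
        for g in c.genes:
            rows.append({"contig_id": c.contig_id, "gene_id": g.gene_id,
                         "start": g.start, "end": g.end, "strand": g.strand,
                         "category": g.category, "label": g.label})
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path,
                        sequences: dict[str, str] | None = None) -> list[AnnotatedContig]:
    frame = pd.read_csv(path, sep="\t", dtype={"label": str})
    contigs: dict[str, AnnotatedContig] = {}
    for row in frame.itertuples(index=False):
        if row.category == "contig":
            meta = dict(item.split("=", 1) for item in row.label.split(";"))
            contigs[row.contig_id] = AnnotatedContig(
                contig_id=row.contig_id,
                length=int(meta["length"]),
                sequence=(sequences or {}).get(row.contig_id),
                source=meta["source"],
                completeness_pct=float(meta["completeness"]),
                contamination_pct=float(meta["contamination"]),
                predictor_flags={k: True for k in meta["predictors"].split(",") if k},
                host_homology_evidence=bool(int(meta["host_evidence"])),
                host_bin_id=meta["host_bin"] or None,
                family_label=meta["family"] or None,
            )
        else:
            contigs[row.contig_id].genes.append(GeneAnnotation(
                gene_id=row.gene_id, start=int(row.start), end=int(row.end),
                strand=row.strand, category=row.category, label=row.label,
            ))
    return list(contigs.values())


def write_coverage_tsv(records: pd.DataFrame, path: str | Path) -> None:
    records[COVERAGE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(COVERAGE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"coverage TSV missing columns: {sorted(missing)}")
    return frame[COVERAGE_COLUMNS]


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Counts as TSV plus a sidecar JSON with kind/flags/metadata."""
    path = Path(path)
    table.counts.to_csv(path, sep="\t", index_label="feature_id")
    sidecar = {"kind": table.kind, "flags": table.flags,
               "metadata": (table.metadata.to_dict("records")
                            if table.metadata is not None else None)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    counts = pd.read_csv(path, sep="\t", index_col="feature_id")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    metadata = (pd.DataFrame(sidecar["metadata"])
                if sidecar.get("metadata") else None)
    return FeatureTable(counts=counts, kind=sidecar["kind"],
                        metadata=metadata, flags=sidecar.get("flags", {}))


def write_catalog_tsv(catalog: ViralCatalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable))


def _jsonable(obj):
    import numpy as np
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj).__name__}")
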