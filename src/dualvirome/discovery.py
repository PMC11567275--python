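"""Viral genome validation, dereplication and lifestyle classification.

Candidate viral contigs arrive from three sources (prophage predictions within
bacterial bins, VLP assemblies, and unbinned bulk contigs) already annotated
with completeness/contamination estimates, phage-predictor flags and per-gene
labels.  The cascade is:

1. quality filter — completeness >= 50%, contamination < 10%;
2. dereplication into species-level representative genomes (SRGs) at 99%
   identity over the full length of the shorter sequence;
3. validation — called by at least one phage predictor, at least one phage
   structural protein, and not a single-structural-gene giant (>100 ORFs);
4. lifestyle call — temperate if any lysogeny-cycle gene (integrase,
   transposase, recombinase, Cro/CI) is present or the contig shows homology
   to a bacterial genome with flanking bacterial regions; otherwise virulent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

try:
    import edlib
except ImportError:  # pragma: no cover
    edlib = None

STRUCTURAL_LABELS = frozenset(
    {"terminase", "capsid", "tail", "amidase", "baseplate", "prohead", "coat", "virion"}
)
LYSOGENY_LABELS = frozenset({"integrase", "transposase", "recombinase", "cro_ci"})

TEMPERATE = "temperate"
VIRULENT = "virulent"


@dataclass
class GeneAnnotation:
    gene_id: str
    start: int
    end: int
    strand: str
    category: str  # structural | lysogeny_marker | metabolic | other
    label: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.category == "structural" and self.label not in STRUCTURAL_LABELS:
            raise ValueError(f"{self.gene_id}: unknown structural label {self.label!r}")
        if self.category == "lysogeny_marker" and self.label not in LYSOGENY_LABELS:
            raise ValueError(f"{self.gene_id}: unknown lysogeny label {self.label!r}")


@dataclass
class AnnotatedContig:
    contig_id: str
    length: int
    sequence: str | None = None
    source: str = "bulk_unbinned"  # bulk_unbinned | bin | vlp
    genes: list[GeneAnnotation] = field(default_factory=list)
    completeness_pct: float | None = None
    contamination_pct: float | None = None
    predictor_flags: dict[str, bool] = field(default_factory=dict)
    host_homology_evidence: bool = False
    host_bin_id: str | None = None
    homology_srg_id: str | None = None
    family_label: str | None = None

    def genes_in(self, category: str) -> list[GeneAnnotation]:
        return [g for g in self.genes if g.category == category]

    @property
    def structural_count(self) -> int:
        return len(self.genes_in("structural"))

    @property
    def orf_count(self) -> int:
        # stand-in for predicted-ORF count: every annotated gene is one ORF
        return len(self.genes)


@dataclass
class ViralSRG:
    srg_id: str
    length: int
    lifestyle: str
    member_contigs: list[str]
    amg_count: int = 0
    host_id: str | None = None
    family_label: str | None = None

    def __post_init__(self) -> None:
        if self.lifestyle not in (TEMPERATE, VIRULENT):
            raise ValueError(f"{self.srg_id}: lifestyle must be temperate or virulent")
        if not self.member_contigs:
            raise ValueError(f"{self.srg_id}: member_contigs empty")


@dataclass
class ViralCatalog:
    srgs: list[ViralSRG]
    cluster_map: dict[str, str] = field(default_factory=dict)
    rejected: dict[str, str] = field(default_factory=dict)  # contig_id -> reason

    def __len__(self) -> int:
        return len(self.srgs)

    def lifestyle_map(self) -> dict[str, str]:
        return {s.srg_id: s.lifestyle for s in self.srgs}

    def count(self, lifestyle: str) -> int:
        return sum(1 for s in self.srgs if s.lifestyle == lifestyle)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "srg_id": s.srg_id, "length": s.length, "lifestyle": s.lifestyle,
            "host_id": s.host_id, "amg_count": s.amg_count,
            "family_label": s.family_label,
            "members": ",".join(s.member_contigs),
        } for s in self.srgs])


# ---------------------------------------------------------------------------
# validation cascade
# ---------------------------------------------------------------------------

def filter_completeness(contigs: list[AnnotatedContig], min_completeness: float = 50.0,
                        max_contamination: float = 10.0) -> list[AnnotatedContig]:
    """Keep contigs with completeness >= ``min_completeness`` percent and
    contamination strictly below ``max_contamination`` percent."""
    kept = []
    for c in contigs:
        if c.completeness_pct is None or c.contamination_pct is None:
            raise ValueError(f"contig {c.contig_id}: missing completeness/contamination")
        if c.completeness_pct >= min_completeness and c.contamination_pct < max_contamination:
            kept.append(c)
    return kept


def validate_viral(contig: AnnotatedContig) -> tuple[bool, str | None]:
    """Per-contig viral validation; returns (verdict, failure reason code)."""
    if not any(contig.predictor_flags.values()):
        return False, "no_predictor"
    n_struct = contig.structural_count
    if n_struct < 1:
        return False, "no_structural"
    if n_struct == 1 and contig.orf_count > 100:
        return False, "single_structural_large"
    return True, None


def classify_lifestyle(contig: AnnotatedContig) -> str:
    """Temperate iff the contig carries any lysogeny-cycle gene or shows
    host homology flanked by bacterial regions; otherwise virulent."""
    if contig.genes_in("lysogeny_marker") or contig.host_homology_evidence:
        return TEMPERATE
    return VIRULENT


# ---------------------------------------------------------------------------
# dereplication
# ---------------------------------------------------------------------------

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _kmer_hashes(sequence: str, k: int = 21) -> np.ndarray:
    """Distinct 2-bit-packed k-mer codes of a sequence (sorted uint64)."""
    codes = _CODE[np.frombuffer(sequence.upper().encode(), dtype=np.uint8)]
    if len(codes) < k or (codes < 0).any():
        codes = codes[codes >= 0]
        if len(codes) < k:
            return np.empty(0, dtype=np.uint64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = (4 ** np.arange(k, dtype=np.uint64)).astype(np.uint64)
    return np.unique((windows.astype(np.uint64) * powers).sum(axis=1, dtype=np.uint64))


def _containment_identity(short: str, long: str) -> float:
    """Identity of the best infix alignment of the shorter sequence inside the
    longer, as matches / shorter-length (edit distance counts mismatches and
    indels against the short sequence)."""
    if edlib is None:  # pragma: no cover
        raise RuntimeError("edlib is required for dereplication")
    res = edlib.align(short, long, mode="HW", task="distance")
    return max(0.0, 1.0 - res["editDistance"] / len(short))


def dereplicate(contigs: list[AnnotatedContig], min_identity: float = 0.99,
                min_short_coverage: float = 1.0, k: int = 21,
                prescreen_fraction: float = 0.5,
                ) -> tuple[list[AnnotatedContig], dict[str, str]]:
    """Greedy species-level dereplication.

    Contigs are visited in descending length (ties broken by contig_id); a
    contig joins the first representative whose sequence contains it at
    ``min_identity`` over its full length, else founds a new cluster.  A
    shared-k-mer prescreen skips alignment of clearly unrelated pairs.
    """
    if min_short_coverage != 1.0:
        raise NotImplementedError("only full-length containment (min_short_coverage=1.0)")
    if not contigs:
        return [], {}
    for c in contigs:
        if c.sequence is None:
            raise ValueError(f"contig {c.contig_id}: sequence required for dereplication")
    order = sorted(contigs, key=lambda c: (-c.length, c.contig_id))
    reps: list[AnnotatedContig] = []
    rep_kmers: list[np.ndarray] = []
    cluster_map: dict[str, str] = {}
    for c in order:
        km = _kmer_hashes(c.sequence, k)
        assigned = None
        for rep, rkm in zip(reps, rep_kmers):
            if len(km) and len(rkm):
                shared = np.isin(km, rkm, assume_unique=True).mean()
                if shared < prescreen_fraction:
                    continue
            short, long_ = ((c.sequence, rep.sequence)
                            if len(c.sequence) <= len(rep.sequence)
                            else (rep.sequence, c.sequence))
            if _containment_identity(short, long_) >= min_identity:
                assigned = rep
                break
        if assigned is None:
            reps.append(c)
            rep_kmers.append(km)
            cluster_map[c.contig_id] = c.contig_id
        else:
            cluster_map[c.contig_id] = assigned.contig_id
    return reps, cluster_map


# ---------------------------------------------------------------------------
# catalog assembly
# ---------------------------------------------------------------------------

def build_viral_catalog(contigs: list[AnnotatedContig], min_completeness: float = 50.0,
                        max_contamination: float = 10.0, min_identity: float = 0.99,
                        run_dereplication: bool | None = None) -> ViralCatalog:
    """Full cascade: completeness filter -> dereplicate -> validate -> classify.

    Dereplication needs sequences; by default it runs iff every retained
    contig carries one (pass ``run_dereplication`` to force either way).
    """
    rejected: dict[str, str] = {}
    retained = filter_completeness(contigs, min_completeness, max_contamination)
    kept_ids = {c.contig_id for c in retained}
    for c in contigs:
        if c.contig_id not in kept_ids:
            rejected[c.contig_id] = "completeness"

    if run_dereplication is None:
        run_dereplication = bool(retained) and all(c.sequence is not None for c in retained)
    if run_dereplication:
        reps, cluster_map = dereplicate(retained, min_identity=min_identity)
    else:
        reps = sorted(retained, key=lambda c: (-c.length, c.contig_id))
        cluster_map = {c.contig_id: c.contig_id for c in reps}

    members: dict[str, list[str]] = {}
    for member, rep in cluster_map.items():
        members.setdefault(rep, []).append(member)

    srgs = []
    for c in reps:
        ok, reason = validate_viral(c)
        if not ok:
            rejected[c.contig_id] = reason or "invalid"
            continue
        lifestyle = classify_lifestyle(c)
        host = None
        if lifestyle == TEMPERATE:
            host = c.host_bin_id or c.homology_srg_id
        srgs.append(ViralSRG(
            srg_id=c.contig_id, length=c.length, lifestyle=lifestyle,
            member_contigs=sorted(members.get(c.contig_id, [c.contig_id])),
            amg_count=len(c.genes_in("metabolic")), host_id=host,
            family_label=c.family_label,
        ))
    return ViralCatalog(srgs=srgs, cluster_map=cluster_map, rejected=rejected)
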