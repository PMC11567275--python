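"""Sequencing-depth saturation: rarefaction of genome recovery and the
breadth-threshold x depth capture grid.

Instead of re-subsampling reads and re-assembling, coverage summaries are
thinned analytically: at a fraction f of the native depth the mean depth
scales to f*lambda and the expected breadth follows the Lander-Waterman form
1 - exp(-f*lambda), with binomial noise on covered positions.  This keeps the
analysis at summary level while preserving the shape of the curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiling import call_presence_frame

#: default subsampling grids, in paired-end read counts
DEFAULT_BULK_DEPTHS = (1, 5, 10, 15, 20, 25)
DEFAULT_VLP_DEPTHS = (1, 5, 10, 15)
MILLION = 1_000_000


@dataclass
class DepthGrid:
    bulk_depths: tuple[int, ...] = tuple(d * MILLION for d in DEFAULT_BULK_DEPTHS)
    vlp_depths: tuple[int, ...] = tuple(d * MILLION for d in DEFAULT_VLP_DEPTHS)
    replicates: int = 3

    def __post_init__(self) -> None:
        for depths in (self.bulk_depths, self.vlp_depths):
            if any(b <= a for a, b in zip(depths, depths[1:])):
                raise ValueError("depth grids must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def depths(self, assay: str) -> tuple[int, ...]:
        return self.bulk_depths if assay == "bulk" else self.vlp_depths


@dataclass
class CaptureGrid:
    breadth_thresholds: tuple[float, ...]
    depths: tuple[int, ...]
    capture_pct: pd.DataFrame  # thresholds (rows) x depths (columns)
    n_catalog: int = 0

    def __post_init__(self) -> None:
        vals = self.capture_pct.values
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError("capture percentages must lie in [0, 100]")


DEFAULT_BREADTH_THRESHOLDS = (0.10, 0.25, 0.50, 0.70, 0.90)


# ---------------------------------------------------------------------------
# thinning
# ---------------------------------------------------------------------------

def thin_coverage(record: dict | pd.Series, fraction: float,
                  seed: int | np.random.Generator = 0, noise: bool = True) -> dict:
    """Coverage record re-expressed at ``fraction`` of the native depth."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    rec = dict(record)
    if fraction == 1.0:
        return rec
    lam = rec["mean_depth"] * fraction
    expected = -math.expm1(-lam)
    length = int(rec["length"])
    if noise and 0.0 < expected < 1.0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        covered = int(rng.binomial(length, expected))
    else:
        covered = int(round(expected * length))
    covered = min(covered, int(rec["covered_bases"]))  # thinning never uncovers new bases
    rec.update(mean_depth=lam, covered_bases=covered, breadth=covered / length)
    return rec


def thin_coverage_frame(records: pd.DataFrame, fraction: float,
                        seed: int | np.random.Generator = 0,
                        noise: bool = True) -> pd.DataFrame:
    """Vectorised :func:`thin_coverage` over a coverage-record frame."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0 or records.empty:
        return records.copy()
    out = records.copy()
    lam = out["mean_depth"].to_numpy() * fraction
    expected = -np.expm1(-lam)
    lengths = out["length"].to_numpy()
    if noise:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        covered = rng.binomial(lengths, np.clip(expected, 0.0, 1.0))
    else:
        covered = np.round(expected * lengths)
    covered = np.minimum(covered, out["covered_bases"].to_numpy()).astype(np.int64)
    out["mean_depth"] = lam
    out["covered_bases"] = covered
    out["breadth"] = covered / lengths
    return out


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefaction_curve(sample_records: pd.DataFrame, kind: str, depths: tuple[int, ...],
                      native_depth: int, replicates: int = 3,
                      seed: int = 0) -> pd.DataFrame:
    """Recovered-genome counts across a subsampling grid for one library.

    Returns a tidy frame (depth, replicate, count); depths above the native
    sequencing depth are an error (one cannot subsample upward).
    """
    if any(d > native_depth for d in depths):
        raise ValueError("requested depth exceeds the native sequencing depth")
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        for rep in range(1, replicates + 1):
            thinned = thin_coverage_frame(sample_records, depth / native_depth, seed=rng)
            count = 0 if not len(thinned) else int(call_presence_frame(thinned, kind).sum())
            rows.append({"depth": depth, "replicate": rep, "count": count})
    return pd.DataFrame(rows, columns=["depth", "replicate", "count"])


def detect_plateau(curve: pd.DataFrame | list[tuple[int, float]],
                   epsilon: float = 0.02) -> tuple[int, bool]:
    """Smallest grid depth after which every consecutive increase of the mean
    curve stays below ``epsilon`` x the final count.

    Returns (depth, saturated flag); an everywhere-steep curve returns the
    largest depth flagged unsaturated.
    """
    if isinstance(curve, pd.DataFrame):
        mean = curve.groupby("depth")["count"].mean().sort_index()
        depths, counts = list(mean.index), list(mean.values)
    else:
        depths = [d for d, _ in curve]
        counts = [c for _, c in curve]
    if len(depths) < 2:
        raise ValueError("plateau detection needs at least two grid points")
    tol = epsilon * counts[-1]
    increases = [counts[i + 1] - counts[i] for i in range(len(counts) - 1)]
    for i in range(len(depths) - 1):
        if all(inc < tol for inc in increases[i:]):
            return depths[i], True
    return depths[-1], False


# ---------------------------------------------------------------------------
# VLP-capture grid
# ---------------------------------------------------------------------------

def capture_fraction(bulk_records_by_depth: dict[int, pd.DataFrame],
                     vlp_catalog_ids: set[str] | list[str],
                     breadth_thresholds: tuple[float, ...] = DEFAULT_BREADTH_THRESHOLDS,
                     ) -> CaptureGrid:
    """Percentage of VLP-derived genomes captured in the bulk assay for each
    (breadth threshold, bulk sequencing depth) combination."""
    ids = set(vlp_catalog_ids)
    if not ids:
        raise ValueError("VLP catalog is empty")
    depths = tuple(sorted(bulk_records_by_depth))
    grid = np.zeros((len(breadth_thresholds), len(depths)))
    for j, depth in enumerate(depths):
        records = bulk_records_by_depth[depth]
        records = records[records["feature_id"].isin(ids)]
        breadth = records.set_index("feature_id")["breadth"]
        for i, t in enumerate(breadth_thresholds):
            grid[i, j] = 100.0 * (breadth >= t).sum() / len(ids)
    frame = pd.DataFrame(grid, index=list(breadth_thresholds), columns=list(depths))
    return CaptureGrid(breadth_thresholds=tuple(breadth_thresholds), depths=depths,
                       capture_pct=frame, n_catalog=len(ids))
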