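"""Consensus differential abundance over three independent engines.

Each engine re-implements the core model of one family of microbiome DA
tools: a negative-binomial Wald test on median-of-ratios-normalised counts
(DESeq family), an equal-variance linear model on log total-sum-scaled
relative abundances (MaAsLin family), and a moderated t-test on
cumulative-sum-scaled log counts (metagenomeSeq family).  A feature is
reported only when all three engines call it at BH-adjusted p < 0.05 and the
negative-binomial engine's |log2 fold change| exceeds 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

LFC_THRESHOLD = 2.0
ALPHA = 0.05


@dataclass
class DAResult:
    """Per-feature consensus record set (tidy frame + planted-truth helpers)."""

    table: pd.DataFrame  # feature_id-indexed: log2fc, p_*, q_*, consensus
    reference: str
    contrast: str

    @property
    def consensus_features(self) -> list[str]:
        return list(self.table.index[self.table["consensus"]])

    def confusion(self, truth: set[str]) -> dict[str, float]:
        called = set(self.consensus_features)
        truth = set(truth) & set(self.table.index)
        tp = len(called & truth)
        fp = len(called - truth)
        fn = len(truth - called)
        return {
            "tp": tp, "fp": fp, "fn": fn,
            "sensitivity": tp / (tp + fn) if truth else float("nan"),
            "fdr": fp / (tp + fp) if called else 0.0,
        }


def _check_two_groups(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("differential abundance engines expect exactly two groups")
    a, b = (labels == groups[0]), (labels == groups[1])
    if a.sum() < 2 or b.sum() < 2:
        raise ValueError("each group needs at least two samples")
    return a, b


# ---------------------------------------------------------------------------
# engine A: negative-binomial Wald on median-of-ratios normalised counts
# ---------------------------------------------------------------------------

def size_factors_median_ratio(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, scaled to geometric mean 1.

    Features with a zero in any sample are excluded from the reference
    geometric means; if none remain, positive-count geometric means are used
    and the result is flagged via the series name.
    """
    x = counts.to_numpy(dtype=float)
    all_positive = (x > 0).all(axis=1)
    flagged = False
    if all_positive.any():
        ref = np.exp(np.log(x[all_positive]).mean(axis=1))
        ratios = x[all_positive] / ref[:, None]
        factors = np.median(ratios, axis=0)
    else:
        flagged = True
        logs = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), np.nan)
        ref = np.exp(np.nanmean(logs, axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = np.where(x > 0, x / ref[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    factors = np.where(factors > 0, factors, 1.0)
    factors = factors / np.exp(np.log(factors).mean())
    return pd.Series(factors, index=counts.columns,
                     name="size_factor_fallback" if flagged else "size_factor")


def nb_wald(counts: pd.DataFrame, labels, pseudo_mean: float = 0.5,
            min_dispersion: float = 1e-8, dispersion_shrink: float = 0.5) -> pd.DataFrame:
    """Per-feature NB Wald test; returns log2fc, se, p (reference = first
    group in sorted label order).  Features zero everywhere are excluded."""
    labels = np.asarray(labels)
    a, b = _check_two_groups(labels)
    nonzero = counts.sum(axis=1) > 0
    excluded = list(counts.index[~nonzero])
    counts = counts.loc[nonzero]
    sf = size_factors_median_ratio(counts)
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]

    mu_a = norm[:, a].mean(axis=1) + pseudo_mean
    mu_b = norm[:, b].mean(axis=1) + pseudo_mean
    lfc = np.log2(mu_b / mu_a)

    # method-of-moments dispersion pooled across groups (Var = mu + alpha mu^2),
    # then shrunk toward the across-feature mean: the per-feature moment
    # estimate is extremely noisy at n=4/group and the empirical-Bayes pull
    # toward a common dispersion is the defining device of this model family
    resid_var = (norm[:, a].var(axis=1, ddof=1) + norm[:, b].var(axis=1, ddof=1)) / 2.0
    mu_bar = (mu_a + mu_b) / 2.0
    alpha = np.maximum((resid_var - mu_bar) / mu_bar ** 2, min_dispersion)
    if len(alpha) > 1 and 0.0 < dispersion_shrink <= 1.0:
        alpha = (1.0 - dispersion_shrink) * alpha + dispersion_shrink * alpha.mean()

    na, nb_ = a.sum(), b.sum()
    var_log = (1.0 / (na * mu_a) + alpha / na) + (1.0 / (nb_ * mu_b) + alpha / nb_)
    se = np.sqrt(var_log) / math.log(2.0)
    z = lfc / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    out = pd.DataFrame({"log2fc": lfc, "se": se, "p": np.clip(p, 1e-300, 1.0)},
                       index=counts.index)
    out.attrs["excluded_all_zero"] = excluded
    return out


# ---------------------------------------------------------------------------
# engine B: linear model on log TSS relative abundances
# ---------------------------------------------------------------------------

def lm_logtss(counts: pd.DataFrame, labels) -> pd.DataFrame:
    """Equal-variance two-group t-test on log2 total-sum-scaled abundances,
    with a pseudo-fraction of half the smallest positive relative abundance."""
    labels = np.asarray(labels)
    a, b = _check_two_groups(labels)
    x = counts.to_numpy(dtype=float)
    colsum = x.sum(axis=0)
    colsum[colsum == 0] = 1.0
    rel = x / colsum[None, :]
    positive = rel[rel > 0]
    pseudo = positive.min() / 2.0 if positive.size else 0.5
    y = np.log2(rel + pseudo)

    ya, yb = y[:, a], y[:, b]
    na, nb_ = a.sum(), b.sum()
    diff = yb.mean(axis=1) - ya.mean(axis=1)
    pooled = ((ya.var(axis=1, ddof=1) * (na - 1) + yb.var(axis=1, ddof=1) * (nb_ - 1))
              / (na + nb_ - 2))
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb_))
    df = na + nb_ - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2.0 * sps.t.sf(np.abs(t), df), 1.0)  # constant feature -> p=1
    return pd.DataFrame({"estimate": diff, "t": t, "p": p}, index=counts.index)


# ---------------------------------------------------------------------------
# engine C: CSS normalisation + moderated t
# ---------------------------------------------------------------------------

def css_scaling_factors(counts: pd.DataFrame) -> pd.Series:
    """Cumulative-sum scaling: per sample, the sum of counts at or below the
    median of its positive counts; samples with <2 positive counts fall back
    to their total (flagged in the series name)."""
    factors = {}
    flagged = False
    for sample in counts.columns:
        col = counts[sample].to_numpy(dtype=float)
        positive = col[col > 0]
        if len(positive) < 2:
            factors[sample] = max(col.sum(), 1.0)
            flagged = True
            continue
        q50 = np.quantile(positive, 0.5)
        factors[sample] = positive[positive <= q50].sum()
    s = pd.Series(factors, name="css_factor_fallback" if flagged else "css_factor")
    return s / s.median()


def css_moderated(counts: pd.DataFrame, labels,
                  shrink_weight: float = 0.5) -> pd.DataFrame:
    """Moderated two-group t on log2 CSS-scaled counts.

    Per-feature variances are shrunk toward the across-feature mean variance
    with the given weight; with weight 0.5 the prior carries as much
    information as the data, so the pooled df doubles (limma-style d0 = d).
    """
    labels = np.asarray(labels)
    a, b = _check_two_groups(labels)
    factors = css_scaling_factors(counts)
    y = np.log2(counts.to_numpy(dtype=float) / factors.to_numpy()[None, :] + 1.0)

    ya, yb = y[:, a], y[:, b]
    na, nb_ = a.sum(), b.sum()
    diff = yb.mean(axis=1) - ya.mean(axis=1)
    pooled = ((ya.var(axis=1, ddof=1) * (na - 1) + yb.var(axis=1, ddof=1) * (nb_ - 1))
              / (na + nb_ - 2))
    s2_mod = (1.0 - shrink_weight) * pooled + shrink_weight * pooled.mean()
    se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb_))
    base_df = na + nb_ - 2
    df = base_df / (1.0 - shrink_weight) if shrink_weight < 1.0 else np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2.0 * sps.t.sf(np.abs(t), df), 1.0)
    return pd.DataFrame({"estimate": diff, "t": t, "p": p}, index=counts.index)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def consensus(nb: pd.DataFrame, lm: pd.DataFrame, css: pd.DataFrame,
              lfc_threshold: float = LFC_THRESHOLD, alpha: float = ALPHA,
              reference: str = "", contrast: str = "") -> DAResult:
    """Intersect the three engines: consensus iff every BH-adjusted p < alpha
    and the NB engine's |log2FC| > ``lfc_threshold``."""
    features = nb.index
    for other, name in ((lm, "lm"), (css, "css")):
        if not features.equals(other.index):
            extra = set(features).symmetric_difference(other.index)
            raise ValueError(f"engine {name} ran on a different feature set "
                             f"({len(extra)} mismatches)")
    table = pd.DataFrame(index=features)
    table["log2fc"] = nb["log2fc"]
    table["p_nb"], table["p_lm"], table["p_zig"] = nb["p"], lm["p"], css["p"]
    for col in ("p_nb", "p_lm", "p_zig"):
        table["q" + col[1:]] = multipletests(table[col], method="fdr_bh")[1]
    table["consensus"] = ((table["q_nb"] < alpha) & (table["q_lm"] < alpha)
                          & (table["q_zig"] < alpha)
                          & (table["log2fc"].abs() > lfc_threshold))
    return DAResult(table=table, reference=reference, contrast=contrast)


def run_consensus(counts: pd.DataFrame, labels, reference: str | None = None,
                  lfc_threshold: float = LFC_THRESHOLD, alpha: float = ALPHA) -> DAResult:
    """Run all three engines on one table and intersect their calls.

    ``reference`` names the baseline group (positive log2FC = enriched in the
    other group); defaults to the first group in sorted order.
    """
    labels = pd.Series(np.asarray(labels))
    groups = sorted(labels.unique())
    if reference is None:
        reference = groups[0]
    if reference not in groups:
        raise ValueError(f"reference {reference!r} not among groups {groups}")
    contrast = [g for g in groups if g != reference][0]
    # recode so the reference is the first sorted label for every engine
    recoded = np.where(labels == reference, "0_ref", "1_alt")
    nonzero = counts.sum(axis=1) > 0
    counts_nz = counts.loc[nonzero]
    nb = nb_wald(counts_nz, recoded)
    lm = lm_logtss(counts_nz, recoded)
    css = css_moderated(counts_nz, recoded)
    return consensus(nb, lm, css, lfc_threshold, alpha,
                     reference=str(reference), contrast=str(contrast))
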