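"""Community statistics: alpha diversity, Bray-Curtis, PCoA, PERMANOVA,
Procrustes randomisation, batch correlations and gated two-group tests.

Permutation procedures report p = (exceedances + 1) / (n_perm + 1) so that a
permutation p-value is never zero; PERMANOVA additionally supports exhaustive
enumeration of all distinct label assignments, whose p-value floor at the
4-vs-4 design size is 1/35.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA_METRICS = ("observed", "chao1", "ace", "shannon", "simpson")


@dataclass
class DistanceMatrix:
    ids: list[str]
    data: np.ndarray
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.data = d


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues_dropped: int = 0


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    effect: float | None = None
    n_permutations: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def _chao1(counts: np.ndarray) -> float:
    s = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s + f1 * f1 / (2.0 * f2)
    return s + f1 * (f1 - 1) / 2.0  # bias-corrected form when no doubletons


def _ace(counts: np.ndarray, rare_threshold: int = 10) -> float:
    counts = counts[counts > 0]
    rare = counts[counts <= rare_threshold]
    abundant = counts[counts > rare_threshold]
    s_rare, s_abund = len(rare), len(abundant)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if n_rare == 0:
        return float(s_abund)
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:  # all rare species are singletons; fall back to Chao1
        return _chao1(counts)
    fi = np.array([(rare == i).sum() for i in range(1, rare_threshold + 1)])
    i = np.arange(1, rare_threshold + 1)
    gamma = max(
        (s_rare / c_ace) * (i * (i - 1) @ fi) / (n_rare * (n_rare - 1)) - 1.0, 0.0,
    ) if n_rare > 1 else 0.0
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma


def _shannon(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())  # natural log, as in vegan


def _simpson(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(1.0 - (p ** 2).sum())


def alpha_diversity(table: pd.DataFrame, metric: str) -> pd.Series:
    """Per-sample alpha diversity over a features x samples count table."""
    if metric not in ALPHA_METRICS:
        raise ValueError(f"unknown metric {metric!r}; pick from {ALPHA_METRICS}")
    out = {}
    for sample in table.columns:
        counts = table[sample].to_numpy(dtype=float)
        if counts.sum() == 0:
            out[sample] = 0.0
            continue
        if metric == "observed":
            out[sample] = float((counts > 0).sum())
        elif metric == "chao1":
            out[sample] = _chao1(counts)
        elif metric == "ace":
            out[sample] = _ace(counts)
        elif metric == "shannon":
            out[sample] = _shannon(counts)
        else:
            out[sample] = _simpson(counts)
    return pd.Series(out, name=metric)


# ---------------------------------------------------------------------------
# distances and ordination
# ---------------------------------------------------------------------------

def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns of a count table."""
    x = table.to_numpy(dtype=float).T  # samples x features
    n = x.shape[0]
    d = np.zeros((n, n))
    flags = {}
    for i in range(n):
        for j in range(i + 1, n):
            denom = (x[i] + x[j]).sum()
            if denom == 0:
                d[i, j] = d[j, i] = 0.0
                flags.setdefault("zero_sample_pairs", []).append(
                    (table.columns[i], table.columns[j]))
            else:
                d[i, j] = d[j, i] = np.abs(x[i] - x[j]).sum() / denom
    return DistanceMatrix(ids=list(table.columns), data=d, flags=flags)


def pcoa(dist: DistanceMatrix, eig_tol: float = 1e-10) -> OrdinationResult:
    """Principal coordinates analysis by Gower double-centering.

    Negative eigenvalues (non-Euclidean distance input) are dropped and
    counted; coordinates span the positive-eigenvalue axes only.
    """
    d = dist.data
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > eig_tol * max(eigval.max(), 1.0)
    n_neg = int((eigval < -eig_tol * max(abs(eigval).max(), 1.0)).sum())
    if not positive.any():  # degenerate all-zero distances
        coords = pd.DataFrame(np.zeros((n, 1)), index=dist.ids, columns=["PC1"])
        return OrdinationResult(coords, np.zeros(1), np.array([1.0]), n_neg)
    lam = eigval[positive]
    coords = eigvec[:, positive] * np.sqrt(lam)
    frame = pd.DataFrame(coords, index=dist.ids,
                         columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    return OrdinationResult(frame, lam, lam / lam.sum(), n_neg)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.where(labels == g)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total, ss_within = _permanova_ss(d2, labels)
    ss_between = ss_total - ss_within
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_between / ss_total


def permanova(dist: DistanceMatrix, labels, n_perm: int = 9999, seed: int = 0,
              exhaustive: bool = False) -> TestResult:
    """One-way PERMANOVA (Anderson pseudo-F) with label-permutation p.

    ``exhaustive=True`` enumerates every distinct assignment of the label
    multiset (at most 10,000), giving the exact permutation distribution; at
    the 4-vs-4 design this floors p at 1/35.
    """
    labels = np.asarray(pd.Series(labels).reindex(dist.ids).values
                        if isinstance(labels, (pd.Series, dict)) else labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        raise ValueError("each group needs at least two samples")
    d2 = dist.data ** 2
    f_obs, r2 = _pseudo_f(d2, labels, len(groups))

    if exhaustive:
        n_assign = math.factorial(len(labels))
        for c in counts:
            n_assign //= math.factorial(c)
        if n_assign > 10_000:
            raise ValueError(f"{n_assign} distinct assignments exceed the exhaustive cap")
        exceed = total = 0
        for perm in _multiset_permutations(labels):
            f_p, _ = _pseudo_f(d2, np.asarray(perm), len(groups))
            total += 1
            if f_p >= f_obs - 1e-12:
                exceed += 1
        p = exceed / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        n = len(labels)
        idx = np.argsort(rng.random((n_perm, n)), axis=1)  # one permutation per row
        perm_labels = labels[idx]
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = np.zeros(n_perm)
        for g in groups:
            mask = (perm_labels == g).astype(float)
            n_g = int((labels == g).sum())
            ss_within += np.einsum("pi,ij,pj->p", mask, d2, mask) / (2.0 * n_g)
        f_perm = ((ss_total - ss_within) / (len(groups) - 1)
                  / (ss_within / (n - len(groups))))
        exceed = int((f_perm >= f_obs - 1e-12).sum())
        p = (exceed + 1) / (n_perm + 1)
        n_used = n_perm
    return TestResult(statistic=f_obs, p_value=p, method="permanova", effect=r2,
                      n_permutations=n_used)


def _multiset_permutations(labels: np.ndarray):
    seen_first = labels.tolist()
    for perm in set(itertools.permutations(seen_first)):
        yield perm


def permanova_null_pvalues(n_per_group: int, n_features: int, n_reps: int,
                           n_perm: int = 999, seed: int = 0,
                           sigma: float = 0.8) -> np.ndarray:
    """Monte-Carlo null p-value sample for calibration checks: two groups of
    equal size drawn from one lognormal community, Bray-Curtis PERMANOVA."""
    rng = np.random.default_rng(seed)
    labels = np.array([0] * n_per_group + [1] * n_per_group)
    base = rng.normal(0.0, 1.0, size=n_features)
    out = np.empty(n_reps)
    for r in range(n_reps):
        counts = np.exp(base[:, None] + rng.normal(0.0, sigma, (n_features, 2 * n_per_group)))
        table = pd.DataFrame(np.round(counts * 20),
                             columns=[f"s{i}" for i in range(2 * n_per_group)])
        dm = bray_curtis(table)
        out[r] = permanova(dm, labels, n_perm=n_perm,
                           seed=int(rng.integers(2 ** 31))).p_value
    return out


# ---------------------------------------------------------------------------
# Procrustes randomisation (PROTEST)
# ---------------------------------------------------------------------------

def _procrustes_prepare(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    norm = np.sqrt((x ** 2).sum())
    if norm == 0:
        raise ValueError("configuration has zero spread")
    return x / norm


def _procrustes_m2(x: np.ndarray, y: np.ndarray) -> float:
    s = np.linalg.svd(x.T @ y, compute_uv=False)
    return max(0.0, 1.0 - s.sum() ** 2)


def procrustes_test(x: pd.DataFrame, y: pd.DataFrame, n_perm: int = 9999,
                    seed: int = 0) -> TestResult:
    """Least-squares superimposition of two ordinations with permutation p.

    Both configurations are centred and scaled to unit trace on their common
    first k axes (k = smaller positive rank); m2 is the residual after the
    optimal rotation/scaling, r = sqrt(1 - m2), and p comes from row
    permutations of the second configuration.
    """
    if list(x.index) != list(y.index):
        if set(x.index) != set(y.index):
            raise ValueError("sample ids of the two configurations differ")
        y = y.loc[x.index]
    if len(x) < 3:
        raise ValueError("Procrustes needs at least three samples")
    k = min(x.shape[1], y.shape[1])
    xm = _procrustes_prepare(x.to_numpy(dtype=float)[:, :k])
    ym = _procrustes_prepare(y.to_numpy(dtype=float)[:, :k])
    m2 = _procrustes_m2(xm, ym)
    r = math.sqrt(max(0.0, 1.0 - m2))
    rng = np.random.default_rng(seed)
    exceed = 0
    n = len(xm)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _procrustes_m2(xm, ym[perm]) <= m2 + 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return TestResult(statistic=m2, p_value=p, method="procrustes", effect=r,
                      n_permutations=n_perm)


# ---------------------------------------------------------------------------
# gated group comparisons
# ---------------------------------------------------------------------------

def _normality_gates(values: np.ndarray, labels: np.ndarray, alpha: float = 0.05) -> bool:
    """Shapiro-Wilk on group-mean residuals and Levene's test; True iff both pass."""
    groups = [values[labels == g] for g in np.unique(labels)]
    residuals = np.concatenate([g - g.mean() for g in groups])
    if np.ptp(residuals) == 0:
        return False  # constant data: Shapiro undefined, use the rank branch
    try:
        p_shapiro = sps.shapiro(residuals).pvalue
    except ValueError:
        return False
    p_levene = sps.levene(*groups).pvalue
    return p_shapiro > alpha and p_levene > alpha


def _dunn_posthoc(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Dunn's z-tests on mean ranks after Kruskal-Wallis, BH-adjusted."""
    n = len(values)
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    rows = []
    groups = np.unique(labels)
    for a, b in itertools.combinations(groups, 2):
        ra, rb = ranks[labels == a], ranks[labels == b]
        se = math.sqrt((n * (n + 1) / 12.0 - tie_term) * (1 / len(ra) + 1 / len(rb)))
        z = (ra.mean() - rb.mean()) / se if se > 0 else 0.0
        rows.append({"group_a": a, "group_b": b, "z": z,
                     "p": 2 * sps.norm.sf(abs(z))})
    frame = pd.DataFrame(rows)
    frame["p_adj"] = multipletests(frame["p"], method="fdr_bh")[1]
    return frame


def group_compare(values, labels, alpha_gate: float = 0.05) -> TestResult:
    """Two or more group comparison with the normality/homoscedasticity gate.

    Two groups: t-test when Shapiro-Wilk (residuals) and Levene both pass at
    ``alpha_gate``, otherwise two-sided Wilcoxon-Mann-Whitney (exact for small
    tie-free samples).  More groups: ANOVA + Tukey when the gates pass, else
    Kruskal-Wallis + Dunn.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    split = [values[labels == g] for g in groups]
    if any(len(g) < 2 for g in split):
        raise ValueError("each group needs at least two values")

    if all(np.array_equal(split[0], g) for g in split[1:]):
        return TestResult(statistic=0.0, p_value=1.0, method="identical_groups")

    parametric = _normality_gates(values, labels, alpha_gate)
    if len(groups) == 2:
        if parametric:
            stat, p = sps.ttest_ind(split[0], split[1], equal_var=True)
            return TestResult(float(stat), float(p), "t_test")
        a, b = split
        no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        method = "exact" if (no_ties and len(a) + len(b) <= 25) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return TestResult(float(res.statistic), float(res.pvalue),
                          f"wilcoxon_mann_whitney_{method}")
    if parametric:
        stat, p = sps.f_oneway(*split)
        tukey = sps.tukey_hsd(*split)
        extras = {"tukey_pvalues": np.asarray(tukey.pvalue).tolist(),
                  "groups": groups.tolist()}
        return TestResult(float(stat), float(p), "anova_tukey", extras=extras)
    stat, p = sps.kruskal(*split)
    dunn = _dunn_posthoc(values, labels)
    return TestResult(float(stat), float(p), "kruskal_dunn",
                      extras={"dunn": dunn.to_dict("records")})


# ---------------------------------------------------------------------------
# batch correlations with FDR
# ---------------------------------------------------------------------------

def correlate_fdr(pairs: dict[str, tuple], method: str = "spearman") -> pd.DataFrame:
    """Correlate each named (x, y) pair and BH-adjust the batch of p-values.

    Zero-variance vectors yield NaN correlations flagged in the output and
    are excluded from the adjustment.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be pearson or spearman")
    func = sps.pearsonr if method == "pearson" else sps.spearmanr
    rows = []
    for name, (x, y) in pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y) or len(x) < 3:
            raise ValueError(f"{name}: paired vectors of length >= 3 required")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"name": name, "r": np.nan, "p": np.nan, "df": len(x) - 2,
                         "flag": "zero_variance"})
            continue
        res = func(x, y)
        rows.append({"name": name, "r": float(res.statistic), "p": float(res.pvalue),
                     "df": len(x) - 2, "flag": ""})
    frame = pd.DataFrame(rows).set_index("name")
    ok = frame["p"].notna()
    frame["p_adj"] = np.nan
    if ok.any():
        frame.loc[ok, "p_adj"] = multipletests(frame.loc[ok, "p"], method="fdr_bh")[1]
    return frame
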