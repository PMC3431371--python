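"""Rarefaction, alpha diversity, rank-abundance tests, trees and ANOVA.

Implements the diversity side of the pipeline comparison: rarefy the OTU
table to a fixed depth, compute per-sample richness S, Shannon H (natural
log), Pielou evenness H/ln S, bias-corrected Chao1 and Faith's
phylogenetic diversity on a neighbor-joining tree of OTU representatives,
compare pooled rank-abundance distributions with a two-sample
Kolmogorov-Smirnov test, contrast the two arms with paired t tests and
rank-shift analysis, and test treatment effects with a two-factor
fixed-effects ANOVA using Type III sums of squares (sum-to-zero
contrasts), which tolerates the unbalanced design left after sample
exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .otu import DistanceMatrix

__all__ = [
    "RarefiedTable",
    "KSResult",
    "rarefy",
    "alpha_diversity",
    "pooled_evenness",
    "rank_abundance",
    "ks_two_sample",
    "build_nj_tree",
    "faith_pd",
    "paired_t",
    "rank_shift",
    "two_way_anova",
]


@dataclass
class RarefiedTable:
    """OTU table subsampled (without replacement) to a common depth."""

    table: pd.DataFrame
    depth: int
    seed: int
    excluded_samples: list[str]


def rarefy(table: pd.DataFrame, depth: int = 3000, seed: int = 0) -> RarefiedTable:
    """Subsample each sample (row) to exactly ``depth`` reads.

    Samples with fewer than ``depth`` reads are excluded and listed.
    Sampling is multivariate hypergeometric (without replacement) and
    deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    rows = {}
    excluded = []
    for sid, row in table.iterrows():
        counts = row.to_numpy(dtype=np.int64)
        total = int(counts.sum())
        if total < depth:
            excluded.append(sid)
            continue
        if total == depth:
            rows[sid] = counts
        else:
            rows[sid] = rng.multivariate_hypergeometric(counts, depth)
    out = pd.DataFrame(rows, index=table.columns).T
    if len(out):
        assert (out.sum(axis=1) == depth).all(), "rarefied rows must sum to depth"
    return RarefiedTable(table=out, depth=depth, seed=seed, excluded_samples=excluded)


def _chao1(counts: np.ndarray, bias_corrected: bool = True) -> float:
    s = int((counts > 0).sum())
    n1 = int((counts == 1).sum())
    n2 = int((counts == 2).sum())
    if bias_corrected:
        return s + n1 * (n1 - 1) / (2.0 * (n2 + 1))
    if n2 == 0:
        return s + n1 * (n1 - 1) / 2.0
    return s + n1 * n1 / (2.0 * n2)


def alpha_diversity(table: pd.DataFrame, bias_corrected_chao: bool = True) -> pd.DataFrame:
    """Per-sample S, Shannon H, Pielou evenness and Chao1.

    Evenness is undefined at S = 1 and reported as NaN; an all-zero
    sample is an explicit failure.
    """
    out = {}
    for sid, row in table.iterrows():
        counts = row.to_numpy(dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError(f"sample {sid} has no reads")
        p = counts[counts > 0] / total
        s = p.size
        h = float(-(p * np.log(p)).sum())
        out[sid] = {
            "richness": s,
            "shannon": h,
            "evenness": h / np.log(s) if s >= 2 else np.nan,
            "chao1": _chao1(row.to_numpy(dtype=np.int64), bias_corrected_chao),
        }
    return pd.DataFrame(out).T


def pooled_evenness(table: pd.DataFrame) -> tuple[float, float, int]:
    """(H, evenness, S) of the table pooled over all samples."""
    counts = table.sum(axis=0).to_numpy(dtype=float)
    counts = counts[counts > 0]
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    s = p.size
    return h, h / np.log(s) if s >= 2 else np.nan, s


def rank_abundance(counts: Sequence[float]) -> np.ndarray:
    """OTU counts sorted descending (rank 1 first)."""
    arr = np.asarray([c for c in counts if c > 0], dtype=float)
    return np.sort(arr)[::-1]


@dataclass(frozen=True)
class KSResult:
    d: float
    p_value: float


def ks_two_sample(ra1: Sequence[float], ra2: Sequence[float]) -> KSResult:
    """Two-sample KS test between two OTU abundance multisets.

    Each OTU contributes its count as one observation; D is the maximum
    ECDF difference over the pooled support, with the asymptotic
    two-sample p-value.
    """
    a, b = np.asarray(ra1, dtype=float), np.asarray(ra2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both rank-abundance inputs must be non-empty")
    res = _stats.ks_2samp(a, b, method="asymp")
    return KSResult(d=float(res.statistic), p_value=float(res.pvalue))


# ---------------------------------------------------------------------------
# trees and phylogenetic diversity
# ---------------------------------------------------------------------------


def build_nj_tree(dm: DistanceMatrix):
    """Neighbor joining on a distance matrix; returns an unrooted
    (trifurcating-root) skbio TreeNode with branch lengths.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch.  A non-symmetric matrix is an explicit failure
    (checked by DistanceMatrix itself).
    """
    from skbio import TreeNode

    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("neighbor joining needs at least two taxa")
    nodes = [TreeNode(name=name) for name in ids]
    if n == 2:
        a, b = nodes
        a.length = dm.data[0, 1] / 2.0
        b.length = dm.data[0, 1] / 2.0
        root = TreeNode(children=[a, b])
        return root
    d = dm.data.astype(float).copy()
    active = list(range(n))
    store = {i: nodes[i] for i in range(n)}
    next_id = n
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        di = 0.5 * sub[i_, j_] + (r[i_] - r[j_]) / (2.0 * (m - 2))
        dj = sub[i_, j_] - di
        di, dj = _clamp_pair(di, dj)
        a, b = store[active[i_]], store[active[j_]]
        a.length, b.length = di, dj
        parent = TreeNode(children=[a, b])
        new_row = 0.5 * (sub[i_, :] + sub[j_, :] - sub[i_, j_])
        # grow the matrix with the new node
        d = np.pad(d, ((0, 1), (0, 1)))
        for k, idx in enumerate(active):
            d[next_id, idx] = d[idx, next_id] = new_row[k]
        store[next_id] = parent
        active = [x for k, x in enumerate(active) if k not in (i_, j_)] + [next_id]
        next_id += 1
    # closed-form three-point finish
    x, y, z = active
    lx = 0.5 * (d[x, y] + d[x, z] - d[y, z])
    ly = 0.5 * (d[x, y] + d[y, z] - d[x, z])
    lz = 0.5 * (d[x, z] + d[y, z] - d[x, y])
    lx, ly = _clamp_pair(lx, ly)
    lz = max(lz, 0.0)
    store[x].length, store[y].length, store[z].length = lx, ly, lz
    return TreeNode(children=[store[x], store[y], store[z]])


def _clamp_pair(a: float, b: float) -> tuple[float, float]:
    if a < 0:
        b = max(b + a, 0.0)
        a = 0.0
    elif b < 0:
        a = max(a + b, 0.0)
        b = 0.0
    return a, b


def faith_pd(tree, taxa: Sequence[str]) -> float:
    """Total branch length of the minimal subtree spanning ``taxa``.

    Unrooted convention: an edge contributes iff it separates selected
    taxa from selected taxa, so a single taxon has PD 0 and selecting all
    leaves sums every branch length.
    """
    taxa = set(taxa)
    leaf_names = {t.name for t in tree.tips()}
    unknown = taxa - leaf_names
    if unknown:
        raise ValueError(f"taxa absent from tree: {sorted(unknown)[:5]}")
    k = len(taxa)
    if k <= 1:
        return 0.0
    pd_total = 0.0
    below: dict[int, int] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            cnt = 1 if node.name in taxa else 0
        else:
            cnt = sum(below[id(c)] for c in node.children)
        below[id(node)] = cnt
        if node.parent is not None and node.length and 0 < cnt < k:
            pd_total += node.length
    return float(pd_total)


# ---------------------------------------------------------------------------
# paired contrasts and ANOVA
# ---------------------------------------------------------------------------


def paired_t(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Classical paired t on per-sample differences (two-sided).

    Requires >= 2 complete pairs with nonzero difference variance."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired_t requires >= 2 complete pairs")
    diff = a - b
    if np.allclose(diff.var(ddof=1), 0.0):
        raise ValueError("difference variance is zero; paired t is undefined")
    res = _stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def rank_shift(values_a: Mapping[str, float], values_b: Mapping[str, float]) -> tuple[pd.DataFrame, float]:
    """Per-sample diversity-rank changes between two arms.

    Ranks are descending (rank 1 = most diverse) with average ties.
    Returns the per-sample table (rank_a, rank_b, delta) and the Spearman
    rank correlation between the two rankings.
    """
    if set(values_a) != set(values_b):
        raise ValueError("rank_shift requires the same sample set in both arms")
    sids = sorted(values_a)
    a = np.array([values_a[s] for s in sids], dtype=float)
    b = np.array([values_b[s] for s in sids], dtype=float)
    ra = _stats.rankdata(-a, method="average")
    rb = _stats.rankdata(-b, method="average")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        rho = 1.0
    else:
        rho = float(_stats.spearmanr(a, b).statistic)
    df = pd.DataFrame({"rank_a": ra, "rank_b": rb, "delta": rb - ra}, index=sids)
    return df, rho


@dataclass
class AnovaTable:
    """Two-factor fixed-effects ANOVA with Type III sums of squares."""

    table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def two_way_anova(
    data: pd.DataFrame,
    response: str = "shannon",
    factor_a: str = "plant_richness",
    factor_b: str = "host_species",
) -> AnovaTable:
    """``response ~ factor_a * factor_b`` with Type III SS via sum-to-zero
    contrasts, suitable for the unbalanced design left after sample
    exclusion.

    Raises ValueError when a factor has < 2 levels, residual DF is zero,
    or empty factorial cells make the interaction inestimable (the empty
    cells are named).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data[[response, factor_a, factor_b]].dropna().copy()
    df.columns = ["y", "fa", "fb"]
    for col, name in (("fa", factor_a), ("fb", factor_b)):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {name} has fewer than 2 levels")
    cells = df.groupby(["fa", "fb"]).size().unstack(fill_value=0)
    empty = [(str(i), str(c)) for i in cells.index for c in cells.columns if cells.loc[i, c] == 0]
    if empty:
        raise ValueError(f"interaction inestimable; empty cells: {empty}")
    warnings = []
    if np.ptp(df["y"].to_numpy()) == 0:
        warnings.append("constant response: all F undefined")
    model = smf.ols("y ~ C(fa, Sum) * C(fb, Sum)", data=df).fit()
    if model.df_resid <= 0:
        raise ValueError("residual DF is zero; no error term")
    aov = sm.stats.anova_lm(model, typ=3)
    aov = aov.drop(index="Intercept")
    aov.index = [factor_a, factor_b, f"{factor_a}:{factor_b}", "Residual"]
    aov["mean_sq"] = aov["sum_sq"] / aov["df"]
    total = pd.DataFrame(
        {"sum_sq": [((df.y - df.y.mean()) ** 2).sum()], "df": [len(df) - 1]},
        index=["Corrected Total"],
    )
    out = pd.concat([aov, total])[["df", "sum_sq", "mean_sq", "F", "PR(>F)"]]
    return AnovaTable(table=out, warnings=warnings)
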