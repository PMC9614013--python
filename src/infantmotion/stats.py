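"""Statistical machinery: Brunner-Munzel test, feature selection with
correlation lumping, exact contingency tests, and Yule's Q.

The Brunner-Munzel test compares two unpaired samples through the relative
effect p = P(X < Y) + 0.5 P(X = Y) without assuming equal variances; the
studentised midrank statistic is referred to a t distribution with
Satterthwaite-type degrees of freedom.  Feature selection retains features
whose two-group Brunner-Munzel p-value falls below a lenient threshold and
then merges clusters of highly correlated retained features (connected
components of the |r| >= threshold graph) into single averaged predictors.

The Fisher exact test is implemented for general r x c tables by full
enumeration of margin-fixed tables (the Freeman-Halton rule: sum the
probabilities of all tables no more probable than the observed one), with
a seeded Monte-Carlo fallback for tables too large to enumerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln


@dataclass(frozen=True)
class BMResult:
    W: float      # studentised statistic; positive when y tends larger
    df: float     # Satterthwaite-type degrees of freedom
    p: float      # two-sided p-value from the t distribution
    p_hat: float  # relative effect P(X < Y) + 0.5 P(X = Y)


def _bm_core(rx, ry, rx_in, ry_in, nx, ny):
    """Studentised statistic pieces from combined and internal midranks.

    Works on 1-D samples or on batches with the sample along the last
    axis.  Returns (W, df, p_hat); W is +/-inf under complete separation
    with zero rank variance, 0 when both samples are entirely tied.
    """
    N = nx + ny
    mx = rx.mean(axis=-1)
    my = ry.mean(axis=-1)
    p_hat = (my - (ny + 1) / 2.0) / nx
    sx2 = np.sum((rx - rx_in - mx[..., None] + (nx + 1) / 2.0) ** 2,
                 axis=-1) / (nx - 1)
    sy2 = np.sum((ry - ry_in - my[..., None] + (ny + 1) / 2.0) ** 2,
                 axis=-1) / (ny - 1)
    pooled = nx * sx2 + ny * sy2
    num = nx * ny * (my - mx)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = num / (N * np.sqrt(pooled))
        df = pooled ** 2 / ((nx * sx2) ** 2 / (nx - 1)
                            + (ny * sy2) ** 2 / (ny - 1))
    degenerate = pooled <= 0
    if np.any(degenerate):
        with np.errstate(invalid="ignore"):
            sep = np.sign(num) * np.inf
        sep = np.where(np.sign(num) == 0, 0.0, sep)
        W = np.where(degenerate, sep, W)
    return W, df, p_hat


def _bm_stat_batch(values, idx, nx):
    """Batched BM statistic for label permutations of one pooled sample.

    ``idx`` is a (B, N) matrix of permutations; the first nx columns form
    sample x.  Combined midranks are permutation-invariant, so they are
    ranked once and gathered.
    """
    rank_all = st.rankdata(values)
    rc = rank_all[idx]
    x = values[idx[:, :nx]]
    y = values[idx[:, nx:]]
    W, _, _ = _bm_core(rc[:, :nx], rc[:, nx:],
                       st.rankdata(x, axis=-1), st.rankdata(y, axis=-1),
                       nx, idx.shape[1] - nx)
    return W


def brunner_munzel(x, y, method: str = "t", n_perm: int = 10_000,
                   seed: int = 0) -> BMResult:
    """Two-sided Brunner-Munzel test of two unpaired samples.

    ``method="t"`` refers the studentised midrank statistic to a t
    distribution with Satterthwaite-type degrees of freedom (the standard
    large-sample formulation, known to be somewhat liberal for small
    unbalanced samples).  ``method="permutation"`` keeps the same
    statistic but takes the p-value from ``n_perm`` seeded random label
    permutations, which holds the level for tiny samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 observations")
    N = nx + ny
    rank_all = st.rankdata(np.concatenate([x, y]))
    W, df, p_hat = _bm_core(rank_all[:nx], rank_all[nx:],
                            st.rankdata(x), st.rankdata(y), nx, ny)
    W, df, p_hat = float(W), float(df), float(p_hat)
    if np.isinf(W):
        df, p = np.nan, 0.0
    elif W == 0.0 and not np.isfinite(df):
        warnings.warn("zero rank variance in both samples; W = 0, p = 1")
        p = 1.0
    elif method == "t":
        p = 2.0 * st.t.sf(abs(W), df)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        values = np.concatenate([x, y])
        idx = np.argsort(rng.random((n_perm, N)), axis=1)
        Wb = _bm_stat_batch(values, idx, nx)
        exceed = np.abs(Wb) >= abs(W) - 1e-12
        p = (1.0 + np.count_nonzero(exceed)) / (n_perm + 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return BMResult(W=W, df=df, p=float(p), p_hat=p_hat)


@dataclass
class SelectionOutcome:
    bm: dict[str, BMResult]            # per-feature test result
    retained: list[str]                # p < alpha, original order
    groups: list[list[str]]            # lumped clusters (incl. singletons)
    predictors: pd.DataFrame           # final predictor matrix
    dropped_constant: list[str] = field(default_factory=list)
    alpha: float = 0.10
    lump_r: float = 0.7

    @property
    def predictor_names(self) -> list[str]:
        return list(self.predictors.columns)


def select_features(X: pd.DataFrame, labels, alpha: float = 0.10
                    ) -> tuple[dict[str, BMResult], list[str]]:
    """Per-feature Brunner-Munzel screening; keep features with p < alpha."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("labels must contain exactly two groups")
    g0, g1 = labels == uniq[0], labels == uniq[1]
    if g0.sum() == 0 or g1.sum() == 0:
        raise ValueError("a group is empty")
    results: dict[str, BMResult] = {}
    retained: list[str] = []
    for name in X.columns:
        col = X[name].to_numpy(dtype=float)
        res = brunner_munzel(col[g0], col[g1])
        results[name] = res
        if res.p < alpha:
            retained.append(name)
    return results, retained


def lump_correlated(X: pd.DataFrame, threshold: float = 0.7
                    ) -> tuple[list[list[str]], pd.DataFrame, list[str]]:
    """Merge clusters of correlated features into averaged predictors.

    Features are z-scored, an edge is drawn between every pair with
    |Pearson r| >= threshold, and each connected component is replaced by
    the mean of its z-scored members (singletons pass through z-scored).
    Zero-variance features are excluded with a warning.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one retained feature")
    dropped = [c for c in X.columns if np.std(X[c].to_numpy(float)) == 0]
    if dropped:
        warnings.warn(f"constant features excluded from lumping: {dropped}")
    cols = [c for c in X.columns if c not in dropped]
    Z = X[cols].apply(lambda c: (c - c.mean()) / c.std(ddof=0))
    r = np.corrcoef(Z.to_numpy(float), rowvar=False)
    r = np.atleast_2d(r)
    adj = (np.abs(r) >= threshold)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups: list[list[str]] = [[] for _ in range(n_comp)]
    for col, lab in zip(cols, labels):
        groups[lab].append(col)
    groups.sort(key=lambda g: cols.index(g[0]))
    pred = {}
    for g in groups:
        name = g[0] if len(g) == 1 else "mean(" + "+".join(g) + ")"
        pred[name] = Z[g].mean(axis=1)
    return groups, pd.DataFrame(pred, index=X.index), dropped


def run_selection(X: pd.DataFrame, labels, alpha: float = 0.10,
                  lump_r: float = 0.7) -> SelectionOutcome:
    """Full selection stage: screening followed by correlation lumping."""
    bm, retained = select_features(X, labels, alpha)
    if not retained:
        return SelectionOutcome(bm=bm, retained=[], groups=[],
                                predictors=pd.DataFrame(index=X.index),
                                alpha=alpha, lump_r=lump_r)
    groups, predictors, dropped = lump_correlated(X[retained], lump_r)
    return SelectionOutcome(bm=bm, retained=retained, groups=groups,
                            predictors=predictors, dropped_constant=dropped,
                            alpha=alpha, lump_r=lump_r)


def _table_logprob(table: np.ndarray, logfact_margin: float) -> float:
    return logfact_margin - gammaln(table + 1.0).sum()


def _enumerate_tables(row_sums, col_sums):
    """Yield all nonnegative integer tables with the given margins."""
    if len(row_sums) == 1:
        yield [list(col_sums)]
        return
    for row in _compositions(row_sums[0], list(col_sums)):
        rest_cols = [c - v for c, v in zip(col_sums, row)]
        for tail in _enumerate_tables(row_sums[1:], rest_cols):
            yield [list(row)] + tail


def _compositions(total, caps):
    """All ways to split `total` over cells with per-cell caps."""
    if len(caps) == 1:
        if 0 <= total <= caps[0]:
            yield (total,)
        return
    hi = min(total, caps[0])
    lo = max(0, total - sum(caps[1:]))
    for v in range(lo, hi + 1):
        for rest in _compositions(total - v, caps[1:]):
            yield (v,) + rest


def fisher_exact(table, max_total: int = 200, mc_draws: int = 200_000,
                 seed: int = 0) -> float:
    """Two-sided Fisher exact test for an r x c contingency table.

    Uses the Freeman-Halton rule: the p-value is the total probability of
    all margin-fixed tables whose probability does not exceed that of the
    observed table.  Tables with more than ``max_total`` entries or more
    than 4 columns fall back to seeded Monte-Carlo sampling of
    margin-fixed tables.
    """
    table = np.asarray(table)
    if table.ndim != 2:
        raise ValueError("table must be 2-D")
    if not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)):
            raise ValueError("table cells must be integers")
        table = np.round(table).astype(int)
    if (table < 0).any():
        raise ValueError("table cells must be nonnegative")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    total = int(table.sum())
    if total == 0 or (row_sums > 0).sum() < 2 or (col_sums > 0).sum() < 2:
        return 1.0
    logfact_margin = (gammaln(row_sums + 1.0).sum()
                      + gammaln(col_sums + 1.0).sum()
                      - gammaln(total + 1.0))
    obs_lp = _table_logprob(table, logfact_margin)
    tol = 1e-9
    if total <= max_total and table.shape[1] <= 4 and table.shape[0] <= 4:
        p = 0.0
        for t in _enumerate_tables(list(row_sums), list(col_sums)):
            lp = _table_logprob(np.asarray(t), logfact_margin)
            if lp <= obs_lp + tol:
                p += np.exp(lp)
        return float(min(p, 1.0))
    rng = np.random.default_rng(seed)
    dist = st.random_table(row_sums, col_sums)
    draws = dist.rvs(mc_draws, random_state=rng)
    lps = logfact_margin - gammaln(draws + 1.0).sum(axis=(-2, -1))
    return float(np.mean(lps <= obs_lp + tol))


def yules_q(table) -> float:
    """Yule's Q association coefficient of a 2x2 table [[a, b], [c, d]]."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("Yule's Q needs a 2x2 table")
    (a, b), (c, d) = table
    denom = a * d + b * c
    if denom == 0:
        raise ValueError("Yule's Q undefined: ad + bc = 0")
    return float((a * d - b * c) / denom)
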