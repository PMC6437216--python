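"""Hallmark statistics for kindling cohorts.

The incidence test is an exact Fisher-Freeman-Halton test on an r x 2
contingency table (animals with / without seizures per group), implemented
from the hypergeometric enumeration with the point-probability two-sided
rule.  Trend and group comparisons wrap the standard scipy tests behind one
result type, adding exact permutation p-values at small n where the
asymptotic approximations are unreliable.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult", "ContingencyTable", "fisher_freeman_halton", "rank_trend",
    "linear_corr", "group_tests", "circadian_correlation", "holm_adjust",
]


@dataclass
class StatResult:
    name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str          # "exact" | "asymptotic" | "permutation"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class ContingencyTable:
    """r x 2 table: per-group counts of (with event, without event)."""

    groups: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[1] != 2:
            raise ValueError("counts must be r x 2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.groups) != self.counts.shape[0]:
            raise ValueError("one label per row required")


def _log_comb(n: int, k: int) -> float:
    return (math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1))


def _table_logprob(row_tot: np.ndarray, k: np.ndarray, col1: int) -> float:
    n = int(row_tot.sum())
    lp = -_log_comb(n, col1)
    for r, ki in zip(row_tot, k):
        lp += _log_comb(int(r), int(ki))
    return lp


def fisher_freeman_halton(table: ContingencyTable) -> StatResult:
    """Exact two-sided test of independence for an r x 2 table.

    p = sum of probabilities, over all tables with the observed margins, of
    tables no more probable than the observed one (the point-probability
    criterion, as in standard exact-test software).  Rows with zero total
    are dropped (flagged in ``extra``).
    """
    counts = table.counts
    nonzero = counts.sum(axis=1) > 0
    dropped = int((~nonzero).sum())
    counts = counts[nonzero]
    if counts.shape[0] < 2:
        return StatResult("fisher_freeman_halton", 0.0, 1.0,
                          tuple(int(v) for v in counts.sum(axis=1)),
                          "exact", {"dropped_empty_rows": dropped})
    row_tot = counts.sum(axis=1)
    col1 = int(counts[:, 0].sum())
    log_denom = _log_comb(int(row_tot.sum()), col1)
    # log "numerator" of the observed table: sum_i log C(r_i, k_i)
    obs_num = float(sum(_log_comb(int(r), int(k))
                        for r, k in zip(row_tot, counts[:, 0])))

    total = 0.0
    tol = 1e-10

    def rec(i: int, remaining: int, num_acc: float) -> None:
        nonlocal total
        if i == len(row_tot) - 1:
            if 0 <= remaining <= row_tot[i]:
                num = num_acc + _log_comb(int(row_tot[i]), remaining)
                if num <= obs_num + tol:
                    total += math.exp(num - log_denom)
            return
        lo = max(0, remaining - int(row_tot[i + 1:].sum()))
        hi = min(int(row_tot[i]), remaining)
        for k in range(lo, hi + 1):
            rec(i + 1, remaining - k,
                num_acc + _log_comb(int(row_tot[i]), k))

    rec(0, col1, 0.0)
    p = min(total, 1.0)
    point_prob = math.exp(obs_num - log_denom)
    return StatResult("fisher_freeman_halton", point_prob, p,
                      tuple(int(v) for v in row_tot), "exact",
                      {"dropped_empty_rows": dropped})


# ---------------------------------------------------------------------------
# correlations

def _midranks(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = _midranks(x), _midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def rank_trend(x, y, *, exact_max_n: int = 8) -> StatResult:
    """Spearman rank correlation with mid-rank ties.

    The p-value is an exhaustive two-sided permutation p for n <= 8 and the
    t-approximation above that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        warnings.warn("constant input: rho undefined", stacklevel=2)
        return StatResult("spearman_rho", float("nan"), 1.0,
                          (x.size,), "exact", {"degenerate": True})
    rho = _spearman_rho(x, y)
    n = x.size
    if n <= exact_max_n:
        rx = _midranks(x)
        ry = _midranks(y)
        rxc = (rx - rx.mean()) / (rx.std() * math.sqrt(n))
        ryc = (ry - ry.mean()) / (ry.std() * math.sqrt(n))
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = ryc[perms] @ rxc
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return StatResult("spearman_rho", rho, p, (n,), "exact")
    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return StatResult("spearman_rho", rho, min(p, 1.0), (n,), "asymptotic")


def linear_corr(x, y) -> StatResult:
    """Pearson product-moment correlation with the t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return StatResult("pearson_r", float(r), float(p), (x.size,),
                      "asymptotic")


# ---------------------------------------------------------------------------
# group tests

_KNOWN_TESTS = ("paired_t", "one_sample_t", "mann_whitney", "kruskal",
                "anova", "friedman")


def _perm_mann_whitney(x: np.ndarray, y: np.ndarray,
                       u_obs: float) -> float:
    pooled = np.concatenate([x, y])
    n, m = x.size, y.size
    mu = n * m / 2.0
    count = total = 0
    for comb in itertools.combinations(range(n + m), n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(comb)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = _midranks(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def _kruskal_h(groups: list[np.ndarray]) -> float:
    pooled = np.concatenate(groups)
    ranks = _midranks(pooled)
    n = pooled.size
    h = 0.0
    i = 0
    for g in groups:
        r = ranks[i:i + g.size]
        h += r.sum() ** 2 / g.size
        i += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, cnt = np.unique(pooled, return_counts=True)
    corr = 1.0 - ((cnt ** 3 - cnt).sum() / (n ** 3 - n))
    return h / corr if corr > 0 else 0.0


def _perm_kruskal(groups: list[np.ndarray], h_obs: float) -> float:
    pooled = np.concatenate(groups)
    sizes = [g.size for g in groups]
    count = total = 0
    for perm in itertools.permutations(range(pooled.size)):
        i = 0
        gs = []
        for s in sizes:
            gs.append(pooled[list(perm[i:i + s])])
            i += s
        if _kruskal_h(gs) >= h_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def _friedman_chi2(data: np.ndarray) -> float:
    b, k = data.shape
    ranks = np.vstack([_midranks(row) for row in data])
    rj = ranks.sum(axis=0)
    return float(12.0 / (b * k * (k + 1)) * (rj ** 2).sum() - 3 * b * (k + 1))


def _perm_friedman(data: np.ndarray, chi_obs: float) -> float:
    b, k = data.shape
    count = total = 0
    for perms in itertools.product(itertools.permutations(range(k)),
                                   repeat=b):
        arr = np.vstack([data[i, list(p)] for i, p in enumerate(perms)])
        if _friedman_chi2(arr) >= chi_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def group_tests(data, design: str, *, method: str = "auto") -> StatResult:
    """Dispatch the cohort comparison named by ``design``.

    designs: ``paired_t`` (two paired samples), ``one_sample_t`` (sample vs
    0), ``mann_whitney``, ``kruskal``, ``anova``, ``friedman`` (blocks x
    treatments matrix).  ``method="permutation"`` requests an exhaustive
    permutation p (rank tests, small n only).
    """
    if design not in _KNOWN_TESTS:
        raise ValueError(f"unknown design {design!r}; expected one of "
                         f"{_KNOWN_TESTS}")
    if design == "paired_t":
        x, y = (np.asarray(v, dtype=float) for v in data)
        if x.size != y.size or x.size < 2:
            raise ValueError("paired test needs equal-length samples, n >= 2")
        d = x - y
        if np.all(d == 0.0):
            # identical pairs: no evidence of any difference
            return StatResult("paired_t", 0.0, 1.0, (x.size,), "asymptotic")
        t, p = sps.ttest_rel(x, y)
        return StatResult("paired_t", float(t), float(p), (x.size,),
                          "asymptotic")
    if design == "one_sample_t":
        x = np.asarray(data, dtype=float)
        t, p = sps.ttest_1samp(x, 0.0)
        return StatResult("one_sample_t", float(t), float(p), (x.size,),
                          "asymptotic")
    if design == "mann_whitney":
        x, y = (np.asarray(v, dtype=float) for v in data)
        u = _u_statistic(x, y)
        if method == "permutation":
            p = _perm_mann_whitney(x, y, u)
            return StatResult("mann_whitney_u", u, p, (x.size, y.size),
                              "permutation")
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="exact" if method == "exact" else "auto")
        how = "exact" if method == "exact" else "asymptotic"
        return StatResult("mann_whitney_u", float(res.statistic),
                          float(res.pvalue), (x.size, y.size), how)
    if design == "kruskal":
        groups = [np.asarray(g, dtype=float) for g in data]
        h = _kruskal_h(groups)
        if method == "permutation":
            p = _perm_kruskal(groups, h)
            return StatResult("kruskal_h", h, p,
                              tuple(g.size for g in groups), "permutation")
        stat, p = sps.kruskal(*groups)
        return StatResult("kruskal_h", float(stat), float(p),
                          tuple(g.size for g in groups), "asymptotic")
    if design == "anova":
        groups = [np.asarray(g, dtype=float) for g in data]
        f, p = sps.f_oneway(*groups)
        return StatResult("anova_f", float(f), float(p),
                          tuple(g.size for g in groups), "asymptotic")
    # friedman
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise ValueError("friedman needs a blocks x treatments matrix, "
                         ">= 3 treatments")
    chi = _friedman_chi2(arr)
    if method == "permutation":
        p = _perm_friedman(arr, chi)
        return StatResult("friedman_chi2", chi, p, arr.shape, "permutation")
    stat, p = sps.friedmanchisquare(*[arr[:, j] for j in range(arr.shape[1])])
    return StatResult("friedman_chi2", float(stat), float(p), arr.shape,
                      "asymptotic")


# ---------------------------------------------------------------------------

def circadian_correlation(times_h, values, *, mode: str = "linear",
                          ) -> StatResult:
    """Association between a per-event metric and clock time-of-day.

    ``mode="linear"`` is a plain Pearson correlation of metric vs clock
    hour; ``mode="circular"`` regresses the metric on (sin, cos) of the
    clock angle and reports the multiple correlation R with an F-test p.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size or t.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.any((t < 0) | (t >= 24)):
        raise ValueError("clock times must lie in [0, 24)")
    if mode == "linear":
        res = linear_corr(t, v)
        return StatResult("circadian_linear_r", res.statistic, res.p_value,
                          res.n, res.method)
    if mode != "circular":
        raise ValueError("mode must be 'linear' or 'circular'")
    if t.size < 4:
        raise ValueError("circular mode needs n >= 4")
    theta = 2.0 * np.pi * t / 24.0
    X = np.column_stack([np.ones_like(theta), np.sin(theta), np.cos(theta)])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    fit = X @ beta
    ss_res = float(((v - fit) ** 2).sum())
    ss_tot = float(((v - v.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero variance metric")
    r2 = max(0.0, 1.0 - ss_res / ss_tot)
    dfn, dfd = 2, t.size - 3
    if dfd < 1 or r2 >= 1.0:
        p = 0.0 if r2 >= 1.0 else 1.0
    else:
        f = (r2 / dfn) / ((1 - r2) / dfd)
        p = float(sps.f.sf(f, dfn, dfd))
    return StatResult("circadian_circular_R", math.sqrt(r2), p, (t.size,),
                      "asymptotic")


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; reporting defaults to
    unadjusted per-comparison tests)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
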