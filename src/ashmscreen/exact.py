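"""Exact conditional tests for allele-count tables.

The centrepiece is :func:`rxc_fisher_exact`, an exact test of independence
for an r x c contingency table conditional on both margins, computed with
a network (stage-wise dynamic-programming) algorithm.  Conditional on the
margins, columns with equal totals are exchangeable, so the algorithm
processes *groups* of equal-margin columns as stages and enumerates
multisets of column allocations (orbits under column permutation) with a
combinatorial multiplicity, rather than individual tables.  A backward
pass supplies, for every (stage, remaining-row-margins) node, the minimum
and maximum attainable log-probability of any completion together with
the total conditional probability mass of all completions; a forward
traversal then sums the probability of every table at most as probable as
the observed one (the usual two-sided definition), resolving whole
subtrees in one step whenever the bounds decide them.

When the table is too large for the node budget a Pearson chi-square
p-value is returned and flagged approximate: plain Monte Carlo cannot
resolve p-values near 1e-7, and near-threshold calls must not rest on
approximations silently.

Also here: the exact Hardy-Weinberg equilibrium test (sum of
probabilities of heterozygote counts no more probable than observed,
conditional on allele counts) and the symmetric two-sided binomial test
against 0.5 used by the per-modification and expression imbalance
callers.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import binom
from scipy.stats import chi2 as chi2_dist

#: relative slack when comparing table probabilities (log scale); the
#: conventional 1 + 1e-7 factor, so ties with the observed table count.
_LOG_EPS = 1e-7


def _logfact(n):
    return gammaln(np.asarray(n, dtype=float) + 1.0)


@dataclass(frozen=True)
class ExactResult:
    p_value: float
    exact: bool
    method: str          # "network" | "chi2" | "degenerate"
    testable: bool = True


def _compositions(total: int, caps: tuple[int, ...]):
    """Non-negative integer vectors summing to `total` with x_i <= caps_i."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    lo = max(0, total - sum(caps[1:]))
    hi = min(caps[0], total)
    for x in range(lo, hi + 1):
        for rest in _compositions(total - x, caps[1:]):
            yield (x,) + rest


def pearson_chi2_p(table: np.ndarray) -> float:
    """Pearson chi-square independence p (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    n = table.sum()
    expected = row @ col / n
    stat = ((table - expected) ** 2 / expected).sum()
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return float(chi2_dist.sf(stat, df))


class _BudgetExceeded(Exception):
    pass


class _Budget:
    def __init__(self, limit: int):
        self.limit = limit
        self.used = 0

    def spend(self, k: int = 1) -> None:
        self.used += k
        if self.used > self.limit:
            raise _BudgetExceeded


def _stage_allocations(col_margin: int, group_size: int,
                       row_margins: tuple[int, ...], lf: np.ndarray,
                       budget: _Budget):
    """Orbits of allocations for a group of equal-margin columns.

    Yields ``(row_sums, weight, log_multiplicity)`` for every multiset of
    ``group_size`` column vectors, each a composition of ``col_margin``
    over the rows: ``row_sums`` is the total the orbit removes from each
    row margin, ``weight`` the summed log multinomial column weights of
    one member, and ``log_multiplicity`` the log number of distinct
    column orderings in the orbit.
    """
    vecs = []
    for v in _compositions(col_margin, row_margins):
        budget.spend()
        w = float(lf[col_margin] - lf[list(v)].sum())
        vecs.append((v, w))
    log_g_fact = math.lgamma(group_size + 1)
    out = []

    def rec(start, remaining, sums, weight, log_denom):
        if remaining == 0:
            budget.spend()
            out.append((tuple(sums), weight, log_g_fact - log_denom))
            return
        for i in range(start, len(vecs)):
            v, w = vecs[i]
            if any(s + x > r for s, x, r in zip(sums, v, row_margins)):
                continue
            for k in range(1, remaining + 1):
                new_sums = [s + k * x for s, x in zip(sums, v)]
                if any(s > r for s, r in zip(new_sums, row_margins)):
                    break
                budget.spend()
                rec(i + 1, remaining - k, new_sums,
                    weight + k * w, log_denom + math.lgamma(k + 1))

    rec(0, group_size, [0] * len(row_margins), 0.0, 0.0)
    return out


def _exact_network(tab: np.ndarray, node_budget: int) -> float:
    row_margins = tuple(int(x) for x in tab.sum(axis=1))
    col_margins = [int(x) for x in tab.sum(axis=0)]
    n_rows = len(row_margins)
    total = sum(row_margins)
    lf = _logfact(np.arange(total + 1))
    const = float(lf[list(row_margins)].sum() - lf[total])
    w_obs = sum(float(lf[c] - lf[list(tab[:, j])].sum())
                for j, c in enumerate(col_margins))
    threshold = w_obs + _LOG_EPS

    budget = _Budget(node_budget)
    # stages: groups of equal-margin columns, large margins first (their
    # weights discriminate most, so bounds resolve subtrees early)
    groups = sorted(Counter(col_margins).items(), key=lambda kv: -kv[0])
    allocations = [
        _stage_allocations(c, g, row_margins, lf, budget)
        for c, g in groups]

    # ---- backward DP over (stage, remaining row margins) -------------
    n_stages = len(groups)
    suffix = [0] * (n_stages + 1)
    for j in range(n_stages - 1, -1, -1):
        suffix[j] = suffix[j + 1] + groups[j][0] * groups[j][1]
    terminal = tuple([0] * n_rows)
    stages: list[dict] = [None] * n_stages + [{terminal: (0.0, 0.0, 0.0)}]
    for j in range(n_stages - 1, -1, -1):
        nxt = stages[j + 1]
        cur: dict[tuple, tuple] = {}
        for state in _compositions(suffix[j], row_margins):
            best_min, best_max, terms = math.inf, -math.inf, []
            for svec, w, lm in allocations[j]:
                child = tuple(s - x for s, x in zip(state, svec))
                if any(x < 0 for x in child):
                    continue
                cinfo = nxt.get(child)
                if cinfo is None:
                    continue
                budget.spend()
                cmin, cmax, csum = cinfo
                best_min = min(best_min, w + cmin)
                best_max = max(best_max, w + cmax)
                terms.append(w + lm + csum)
            if terms:
                cur[state] = (best_min, best_max, float(logsumexp(terms)))
        stages[j] = cur

    # ---- forward traversal with bound-based resolution ---------------
    # frontier: state -> (accumulated log weights, log path multiplicities)
    hits: list[float] = []
    frontier: dict[tuple, tuple[np.ndarray, np.ndarray]] = {
        tuple(row_margins): (np.zeros(1), np.zeros(1))}
    for j in range(n_stages):
        chunks: dict[tuple, list] = {}
        for state, (acc, logmult) in frontier.items():
            info = stages[j].get(state)
            if info is None:
                continue
            minw, maxw, logsum = info
            all_in = acc + maxw <= threshold
            if all_in.any():
                # every completion at most as probable as observed
                hits.append(float(logsumexp(acc[all_in] + logmult[all_in]))
                            + logsum)
            alive = ~all_in & (acc + minw <= threshold)
            if not alive.any():
                continue
            acc, logmult = acc[alive], logmult[alive]
            budget.spend(acc.size * len(allocations[j]))
            for svec, w, lm in allocations[j]:
                child = tuple(s - x for s, x in zip(state, svec))
                if any(x < 0 for x in child) or child not in stages[j + 1]:
                    continue
                chunks.setdefault(child, []).append(
                    (acc + w, logmult + lm))
        frontier = {}
        for child, parts in chunks.items():
            acc = np.concatenate([a for a, _ in parts])
            logmult = np.concatenate([m for _, m in parts])
            # merge paths that reached the same accumulated weight
            uniq, inverse = np.unique(acc, return_inverse=True)
            if uniq.size < acc.size:
                merged = np.full(uniq.size, -np.inf)
                np.logaddexp.at(merged, inverse, logmult)
                acc, logmult = uniq, merged
            frontier[child] = (acc, logmult)
    for acc, logmult in frontier.values():     # terminal state
        take = acc <= threshold
        if take.any():
            hits.append(float(logsumexp(acc[take] + logmult[take])))
    if not hits:
        return 0.0
    return min(1.0, math.exp(const + float(logsumexp(hits))))


def _enumeration_bound(col_margins, n_rows) -> float:
    """Crude upper bound on the number of tables with the given margins."""
    total = 1.0
    for c in col_margins:
        total *= math.comb(c + n_rows - 1, n_rows - 1)
        if total > 1e12:
            return total
    return total


def rxc_fisher_exact(table, node_budget: int = 3_000_000,
                     screen_p: float = 1e-3) -> ExactResult:
    """Two-sided exact (or flagged-approximate) independence test.

    Parameters
    ----------
    table
        Non-negative integer matrix.  All-zero rows and columns are
        removed first; tables left with fewer than 2 rows or columns are
        untestable and return p = 1.
    node_budget
        Bound on backward-DP plus forward-traversal work before falling
        back to the Pearson chi-square approximation.
    screen_p
        Large tables whose Pearson p-value exceeds this are reported with
        the flagged chi-square approximation without attempting the exact
        computation: the network traversal prunes well only when the
        observed table is improbable, and a p-value this far above any
        calling threshold makes the approximation immaterial.  Small
        tables are always computed exactly regardless of the screen.
    """
    tab = np.asarray(table, dtype=int)
    if tab.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (tab < 0).any():
        raise ValueError("table entries must be non-negative")
    tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
    if tab.size == 0 or tab.shape[0] < 2 or tab.shape[1] < 2:
        return ExactResult(1.0, True, "degenerate", testable=False)
    if tab.shape[0] > tab.shape[1]:   # fewer rows -> smaller state space
        tab = tab.T
    if (tab.sum() > 40
            and _enumeration_bound(tab.sum(axis=0), tab.shape[0]) > node_budget
            and pearson_chi2_p(tab) > screen_p):
        return ExactResult(pearson_chi2_p(tab), False, "chi2")
    try:
        p = _exact_network(tab, node_budget)
    except _BudgetExceeded:
        return ExactResult(pearson_chi2_p(tab), False, "chi2")
    return ExactResult(p, True, "network")


def binomial_two_sided(k: int, n: int) -> float:
    """Two-sided binomial test of k successes in n trials against 0.5.

    For the symmetric null the minimum-likelihood summation reduces to
    the closed form ``min(1, 2 P(X <= min(k, n-k)))``; when both alleles
    are equally frequent the p-value is 1 by symmetry.
    """
    if n < 1:
        raise ValueError("binomial test needs at least one trial")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    m = min(k, n - k)
    if m == n - m:
        return 1.0
    return float(min(1.0, 2.0 * binom.cdf(m, n, 0.5)))


def binomial_two_sided_vec(k, n):
    """Vectorised :func:`binomial_two_sided`; n = 0 entries yield p = 1."""
    k = np.asarray(k, dtype=int)
    n = np.asarray(n, dtype=int)
    m = np.minimum(k, n - k)
    with np.errstate(invalid="ignore"):
        p = np.minimum(1.0, 2.0 * binom.cdf(m, np.maximum(n, 1), 0.5))
    return np.where((m == n - m) | (n == 0), 1.0, p)


def hwe_exact_test(genotype_counts) -> float:
    """Exact HWE test on (hom_a, het, hom_b) genotype counts.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts no more probable than the observed one.
    Monomorphic samples return p = 1.
    """
    hom_a, het, hom_b = (int(x) for x in genotype_counts)
    if min(hom_a, het, hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = hom_a + het + hom_b
    if n == 0:
        raise ValueError("genotype counts are all zero")
    n_a = 2 * hom_a + het
    n_b = 2 * hom_b + het
    if n_a == 0 or n_b == 0:
        return 1.0
    lf = _logfact(np.arange(2 * n + 1))
    base = float(lf[n] + lf[n_a] + lf[n_b] - lf[2 * n])

    def logp(h):
        ha = (n_a - h) // 2
        hb = (n_b - h) // 2
        return base + h * math.log(2.0) - float(lf[ha] + lf[h] + lf[hb])

    h_values = range(n_a % 2, min(n_a, n_b) + 1, 2)
    logps = {h: logp(h) for h in h_values}
    obs = logps[het]
    total = logsumexp(list(logps.values()))
    keep = [lp for lp in logps.values() if lp <= obs + _LOG_EPS]
    return float(min(1.0, math.exp(logsumexp(keep) - total)))


def enumerate_tables_2x2(row_margins, col_margins):
    """All 2x2 tables with the given margins (oracle helper)."""
    r1, r2 = row_margins
    c1, _ = col_margins
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        yield np.array([[a, r1 - a], [c1 - a, r2 - (c1 - a)]], dtype=int)
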