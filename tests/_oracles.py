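"""Independent brute-force reference implementations used only by tests.

These deliberately re-derive each quantity with plain loops and textbook
formulas so that agreement with the package is a two-route check, not a
tautology.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import stats


def tmm_factors_oracle(values, lib, trim_m=0.30, trim_a=0.05):
    """Loop implementation of trimmed-mean-of-M normalization factors."""
    values = np.asarray(values, dtype=float)
    lib = np.asarray(lib, dtype=float)
    n_samples = values.shape[1]
    uq = [np.quantile(values[:, j], 0.75) / lib[j] for j in range(n_samples)]
    ref = int(np.argmin([abs(u - np.mean(uq)) for u in uq]))
    logf = []
    for j in range(n_samples):
        if j == ref:
            logf.append(0.0)
            continue
        ms, as_, ws = [], [], []
        for i in range(values.shape[0]):
            yk, yr = values[i, j], values[i, ref]
            if yk > 0 and yr > 0:
                pk, pr = yk / lib[j], yr / lib[ref]
                ms.append(np.log2(pk / pr))
                as_.append(0.5 * np.log2(pk * pr))
                ws.append((lib[j] - yk) / (lib[j] * yk) + (lib[ref] - yr) / (lib[ref] * yr))
        ms, as_, ws = np.array(ms), np.array(as_), np.array(ws)
        n = len(ms)
        rm = stats.rankdata(ms, method="ordinal")
        ra = stats.rankdata(as_, method="ordinal")
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        logf.append(np.sum(ms[keep] / ws[keep]) / np.sum(1.0 / ws[keep]))
    logf = np.array(logf)
    logf -= logf.mean()
    return 2.0 ** logf


def bh_adjust_oracle(pvals):
    """Textbook Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def exact_signed_rank_p(deltas):
    """Exact two-sided Wilcoxon signed-rank p by enumerating all sign flips."""
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    count = 0
    total = 2 ** n
    obs_dev = abs(w_obs - mu)
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= obs_dev - 1e-12:
            count += 1
    return count / total


def hypergeom_overlap_tail(n_universe, n_tissue, cf_size, observed):
    """Exact P(overlap >= observed) for uniform draws without replacement."""
    return float(stats.hypergeom(n_universe, n_tissue, cf_size).sf(observed - 1))


def moderated_t_limit_oracle(case, ctrl):
    """Ordinary pooled-variance two-sample t (the d0 -> 0 limit)."""
    res = stats.ttest_ind(case, ctrl, axis=1, equal_var=True)
    return res.statistic, res.pvalue
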