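"""Differential methylation between case and control cfDNA.

Counts at background-depleted windows are filtered for minimal presence,
TMM-normalized, transformed to log2 counts-per-million, and tested per window
with an empirical-Bayes moderated two-group t statistic. Hyper-/hypomethylated
regions are called at a BH-adjusted p threshold combined with a minimum
absolute log2 fold-change (defaults 0.1 and 1, the discovery settings).

The moderated test shrinks per-window residual variances toward a pooled prior
estimated from the whole matrix: with per-window residual variance s^2 on d
degrees of freedom and prior (d0, s0^2) fitted by the method of moments on
log s^2, the posterior variance is s~^2 = (d0*s0^2 + d*s^2) / (d0 + d) and the
moderated t has d0 + d degrees of freedom. Setting d0 = 0 recovers the
ordinary equal-variance two-sample t.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .windows import CountMatrix

DEFAULT_ALPHA = 0.1
DEFAULT_MIN_ABS_LFC = 1.0
DEFAULT_MIN_SAMPLE_FRAC = 0.2
DEFAULT_TRIM_M = 0.30
DEFAULT_TRIM_A = 0.05
DEFAULT_PRIOR_COUNT = 0.5


def filter_low_count(cm: CountMatrix, min_sample_frac: float = DEFAULT_MIN_SAMPLE_FRAC) -> pd.Series:
    """Keep windows with a nonzero count in >= ceil(frac * n_samples) samples.

    Interprets the low-count exclusion as a presence rule — a window must be
    observed in at least 20% of samples by default — which is the only reading
    that is invariant to sequencing depth. The boundary (exactly the required
    number of samples) is kept.
    """
    if not 0 < min_sample_frac <= 1:
        raise ValueError("min_sample_frac must be in (0, 1]")
    need = math.ceil(min_sample_frac * cm.values.shape[1])
    present = (cm.values > 0).sum(axis=1)
    return (present >= need).rename("keep")


def _choose_reference(values: np.ndarray, lib: np.ndarray) -> int:
    # sample whose upper-quartile count fraction is closest to the mean
    with np.errstate(divide="ignore", invalid="ignore"):
        uq = np.array(
            [np.quantile(values[:, j], 0.75) / lib[j] for j in range(values.shape[1])]
        )
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_factors(
    cm: CountMatrix,
    trim_m: float = DEFAULT_TRIM_M,
    trim_a: float = DEFAULT_TRIM_A,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (geometric mean 1).

    For each sample against the reference (the sample whose upper-quartile
    count is closest to the cohort mean upper-quartile), M and A statistics
    are computed over windows nonzero in both; the top and bottom ``trim_m``
    of M and ``trim_a`` of A are discarded (rank-based double trimming) and
    the factor is 2**(precision-weighted mean of the retained M), with inverse
    asymptotic binomial variances as weights.
    """
    values = cm.values.values.astype(float)
    lib = cm.library_size.values.astype(float)
    n_samples = values.shape[1]
    if (values.sum(axis=0) <= 0).any():
        raise ValueError("every sample needs at least one nonzero count")
    ref = _choose_reference(values, lib)
    yr, nr = values[:, ref], lib[ref]
    log_factors = np.zeros(n_samples)
    for j in range(n_samples):
        if j == ref:
            continue
        yk, nk = values[:, j], lib[j]
        both = (yk > 0) & (yr > 0)
        if not both.any():
            warnings.warn(f"sample {cm.samples[j]!r} shares no nonzero window with reference")
            continue
        pk, pr = yk[both] / nk, yr[both] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        w = (nk - yk[both]) / (nk * yk[both]) + (nr - yr[both]) / (nr * yr[both])
        n = m.size
        rm = stats.rankdata(m, method="ordinal")
        ra = stats.rankdata(a, method="ordinal")
        lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any() or w[keep].sum() <= 0:
            warnings.warn(f"sample {cm.samples[j]!r}: trimming removed all windows")
            continue
        log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    log_factors -= log_factors.mean()  # geometric mean of 2**lf equals 1
    return pd.Series(2.0 ** log_factors, index=cm.samples, name="tmm_factor")


def log_cpm(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    prior_count: float = DEFAULT_PRIOR_COUNT,
) -> pd.DataFrame:
    """log2 counts-per-million with a depth-proportional prior.

    ``log2((c + p_s) / (eff_s + 2 * p_s) * 1e6)`` with effective library
    ``eff_s = lib_s * factor_s`` and per-sample prior ``p_s = prior_count *
    eff_s * 1e-6``, i.e. the prior is specified on the CPM scale (default 0.5
    CPM). Tying the prior to depth makes the transform exactly invariant to
    jointly scaling one sample's counts and library size.
    """
    if factors is None:
        factors = pd.Series(1.0, index=cm.samples)
    factors = factors.reindex(cm.samples)
    if (factors <= 0).any():
        raise ValueError("normalization factors must be positive")
    eff = cm.library_size.astype(float) * factors
    prior = prior_count * eff * 1e-6
    num = cm.values.astype(float).add(prior, axis=1)
    den = eff + 2.0 * prior
    return np.log2(num.div(den, axis=1) * 1e6)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/y scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moments fit of (d0, s0^2) from observed residual variances.

    Works on z = log s^2: under the scaled-F model, E[z] and Var[z] involve
    digamma/trigamma terms of d/2 and d0/2; matching the sample moments gives
    the prior degrees of freedom d0 (possibly infinite) and prior variance.
    Zero variances are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if not pos.any():
        raise ValueError("all residual variances are zero; degenerate input")
    z = np.log(s2[pos])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    if e.size < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


@dataclass
class DesignSpec:
    """Two-group design: sample -> {case, control}."""

    groups: pd.Series

    def __post_init__(self) -> None:
        counts = self.groups.value_counts()
        for g in ("case", "control"):
            if counts.get(g, 0) < 2:
                raise ValueError(f"need >=2 samples in group {g!r}")
        extra = set(self.groups.unique()) - {"case", "control"}
        if extra:
            raise ValueError(f"unknown group labels {sorted(extra)}")

    @property
    def case_samples(self) -> list:
        return list(self.groups.index[self.groups == "case"])

    @property
    def control_samples(self) -> list:
        return list(self.groups.index[self.groups == "control"])


def moderated_two_group_test(
    logcpm: pd.DataFrame,
    design: DesignSpec,
    d0: float | None = None,
) -> pd.DataFrame:
    """Per-window moderated t test of case minus control on log2 CPM.

    Returns a table with log2FC (case - control), moderated t, raw p,
    BH-adjusted p and mean log-CPM, plus the fitted prior in ``attrs``
    ("d0", "s0_2"). Pass ``d0=0`` to disable moderation (ordinary
    equal-variance t) or a positive value to override the fitted prior.
    """
    case = logcpm[design.case_samples].values
    ctrl = logcpm[design.control_samples].values
    n1, n2 = case.shape[1], ctrl.shape[1]
    d = n1 + n2 - 2
    mean1, mean2 = case.mean(axis=1), ctrl.mean(axis=1)
    lfc = mean1 - mean2
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d

    if d0 is None:
        d0_fit, s0_2 = fit_variance_prior(s2, d)
    else:
        d0_fit = float(d0)
        s0_2 = float(fit_variance_prior(s2, d)[1]) if d0_fit > 0 else 0.0
    if np.isinf(d0_fit):
        s2_tilde = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_tilde = (d0_fit * s0_2 + d * s2) / (d0_fit + d)
        df_total = d0_fit + d
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "log2FC": lfc,
            "t": t,
            "p": p,
            "adj_p": adj,
            "mean_logcpm": logcpm.values.mean(axis=1),
        },
        index=logcpm.index,
    )
    out.attrs["d0"] = float(d0_fit)
    out.attrs["s0_2"] = float(s0_2)
    out.attrs["residual_df"] = float(d)
    return out


@dataclass
class DMRSet:
    """Called differentially methylated regions, split by direction."""

    hyper: set
    hypo: set
    alpha: float
    min_abs_lfc: float

    def __post_init__(self) -> None:
        if self.hyper & self.hypo:
            raise ValueError("a window cannot be both hyper- and hypomethylated")


def call_dmrs(
    stats_table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_abs_lfc: float = DEFAULT_MIN_ABS_LFC,
) -> DMRSet:
    """Call DMRs at adjusted p < alpha and |log2FC| > min_abs_lfc."""
    sig = stats_table["adj_p"] < alpha
    hyper = set(stats_table.index[sig & (stats_table["log2FC"] > min_abs_lfc)])
    hypo = set(stats_table.index[sig & (stats_table["log2FC"] < -min_abs_lfc)])
    return DMRSet(hyper=hyper, hypo=hypo, alpha=alpha, min_abs_lfc=min_abs_lfc)
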