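"""Chromosomal instability from binned coverage: log2 ratios and t-MAD.

Fragment midpoints are counted into fixed 1-Mb bins, converted to proportions
of the sample total, and normalized against the per-bin median proportion of a
healthy (copy-number-neutral) panel. The t-MAD score is the trimmed median
absolute deviation of the usable log2 ratios from 0 — deviation is measured
from copy-number neutrality, not from the sample's own median, so a genome
that is mostly altered still scores high.

This is a deliberately simple panel-normalization scheme (no HMM segmentation,
no GC/mappability correction); the score works on both sWGS-like and
cfMeDIP-like fragment sets because platform-specific bin biases cancel when
each platform is normalized against its own panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .windows import WindowSet, count_fragments, downsample_fragments

DEFAULT_BIN_SIZE = 1_000_000
DEFAULT_TRIM_FRAC = 0.02
DEFAULT_CV_BLACKLIST_FRAC = 0.01
DEFAULT_EPSILON = 1e-9
MIN_USABLE_BINS = 100


def make_bins(chrom_sizes: Mapping[str, int], bin_size: int = DEFAULT_BIN_SIZE) -> WindowSet:
    """Tile each chromosome with fixed-width bins (last bin truncated)."""
    rows = []
    for chrom in sorted(chrom_sizes):
        size = int(chrom_sizes[chrom])
        for i, start in enumerate(range(0, size, bin_size)):
            end = min(start + bin_size, size)
            rows.append((chrom, start, end, f"{chrom}:{i}", 0))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "window_id", "n_cpg"])
    return WindowSet(df, provenance=f"bins({bin_size} bp)")


def bin_counts(fragments: pd.DataFrame, bins: WindowSet) -> pd.Series:
    """Midpoint-assign fragments into bins; same rule as window counting."""
    return count_fragments(fragments, bins).counts


@dataclass
class Log2RatioProfile:
    """Per-bin log2 ratio versus the panel reference, with usability flags."""

    log2r: pd.Series  # NaN at blacklisted bins
    usable: pd.Series  # boolean

    @property
    def usable_values(self) -> np.ndarray:
        return self.log2r[self.usable].values


def normalize_to_panel(
    sample_counts: pd.Series,
    panel_counts: pd.DataFrame,
    cv_blacklist_frac: float = DEFAULT_CV_BLACKLIST_FRAC,
    epsilon: float = DEFAULT_EPSILON,
) -> Log2RatioProfile:
    """Proportion-normalize a sample's bin counts against a healthy panel.

    All count vectors are scaled to proportions of their totals; the reference
    is the per-bin median panel proportion. ``log2r = log2((p + eps) /
    (ref + eps))``. Bins with zero reference, or within the top
    ``cv_blacklist_frac`` of panel coefficient-of-variation, are blacklisted.
    """
    if panel_counts.shape[1] < 2:
        raise ValueError("panel needs >=2 samples")
    if not sample_counts.index.equals(panel_counts.index):
        raise ValueError("sample and panel must share one bin index")
    total = float(sample_counts.sum())
    if total <= 0:
        raise ValueError("empty sample: no fragments in bins")
    p = sample_counts.values / total
    panel_p = panel_counts.values / panel_counts.values.sum(axis=0, keepdims=True)
    ref = np.median(panel_p, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = panel_p.std(axis=1, ddof=1) / np.where(ref > 0, panel_p.mean(axis=1), np.nan)
    usable = ref > 0
    if np.isfinite(cv[usable]).any() and cv_blacklist_frac > 0:
        cut = np.nanquantile(cv[usable], 1.0 - cv_blacklist_frac)
        usable &= ~(cv > cut)
    log2r = np.full(p.shape, np.nan)
    log2r[usable] = np.log2((p[usable] + epsilon) / (ref[usable] + epsilon))
    idx = sample_counts.index
    return Log2RatioProfile(
        log2r=pd.Series(log2r, index=idx, name="log2r"),
        usable=pd.Series(usable, index=idx, name="usable"),
    )


def tmad(profile: Log2RatioProfile, trim_frac: float = DEFAULT_TRIM_FRAC) -> float:
    """Trimmed median absolute deviation of log2 ratios from neutrality.

    Removes the ``trim_frac`` most extreme |log2r| bins, then takes the median
    of |log2r| over the remaining usable bins. Zero for a flat profile; a CNA
    must affect more than half the (untrimmed) usable genome to move the
    median by its full amplitude.
    """
    vals = np.abs(profile.usable_values)
    vals = vals[np.isfinite(vals)]
    if vals.size < MIN_USABLE_BINS:
        raise ValueError(f"only {vals.size} usable bins; need >= {MIN_USABLE_BINS}")
    n_trim = int(np.floor(trim_frac * vals.size))
    if n_trim > 0:
        vals = np.sort(vals)[: vals.size - n_trim]
    return float(np.median(vals))


@dataclass
class PlatformConcordance:
    tmad_a: pd.Series
    tmad_b: pd.Series
    pearson_r: float
    p_value: float


def dual_platform_concordance(
    fragments_a: Mapping[str, pd.DataFrame],
    fragments_b: Mapping[str, pd.DataFrame],
    bins: WindowSet,
    panel_a: pd.DataFrame,
    panel_b: pd.DataFrame,
    common_depth: int,
    seed: int = 0,
    trim_frac: float = DEFAULT_TRIM_FRAC,
) -> PlatformConcordance:
    """t-MAD agreement between two platforms at a common downsampled depth.

    Paired samples (shared keys) are downsampled to ``common_depth``, binned,
    normalized against the platform-matched panel, and scored; the Pearson r
    across the paired cohort is reported. Unpaired samples are excluded with a
    warning; a constant cohort makes r undefined (NaN, with a warning).
    """
    shared = sorted(set(fragments_a) & set(fragments_b))
    unpaired = (set(fragments_a) | set(fragments_b)) - set(shared)
    if unpaired:
        warnings.warn(f"excluding unpaired samples: {sorted(unpaired)}")
    if not shared:
        raise ValueError("no paired samples")
    rng = np.random.default_rng(seed)
    scores = {"a": {}, "b": {}}
    for sid in shared:
        # one seed per sample, shared by both platforms, so identical inputs
        # are downsampled identically
        sub_seed = int(rng.integers(0, 2**31 - 1))
        for key, frags, panel in (("a", fragments_a[sid], panel_a), ("b", fragments_b[sid], panel_b)):
            sub = downsample_fragments(frags, common_depth, sub_seed)
            counts = bin_counts(sub, bins)
            profile = normalize_to_panel(counts, panel)
            scores[key][sid] = tmad(profile, trim_frac=trim_frac)
    a = pd.Series(scores["a"]).loc[shared]
    b = pd.Series(scores["b"]).loc[shared]
    if np.ptp(a.values) == 0 or np.ptp(b.values) == 0:
        warnings.warn("constant t-MAD cohort; Pearson r undefined")
        return PlatformConcordance(a, b, float("nan"), float("nan"))
    r = stats.pearsonr(a.values, b.values)
    return PlatformConcordance(a, b, float(r.statistic), float(r.pvalue))
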