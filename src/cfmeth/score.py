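"""Per-sample 5-mC score, detection thresholds and the multi-marker matrix.

The 5-mC score summarizes tumor-derived methylation in one number per sample:
the median absolute RPKM deviation from a pooled healthy baseline over a fixed
set of hypermethylated DMRs. The baseline is built by downsampling each
healthy sample to a common depth and merging the pools into one pseudo-sample.
Detection thresholds are set as the maximum marker value observed across the
healthy cohort, so healthy samples used to set a threshold can never be called
positive under the strict-greater rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Collection, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .windows import CountMatrix, CountResult, WindowSet, count_fragments, downsample_fragments


@dataclass
class BaselineProfile:
    """Pooled healthy reference RPKM per window."""

    rpkm: pd.Series
    target_depth: int
    sample_ids: list
    seed: int

    def __post_init__(self) -> None:
        if (self.rpkm < 0).any():
            raise ValueError("negative baseline RPKM")


def build_healthy_baseline(
    healthy_fragments: Mapping[str, pd.DataFrame],
    ws: WindowSet,
    target_depth: int,
    seed: int = 0,
) -> BaselineProfile:
    """Downsample each healthy sample to a common depth, merge, compute RPKM.

    Each of the n healthy fragment sets is downsampled to target_depth // n
    fragments so the merged pool totals about ``target_depth``; the pooled
    fragments are counted once and converted to RPKM. If a sample holds fewer
    fragments than its share, all of its fragments are used (with a warning).
    """
    if not healthy_fragments:
        raise ValueError("need at least one healthy sample")
    n = len(healthy_fragments)
    per_sample = target_depth // n
    rng = np.random.default_rng(seed)
    pools = []
    for sid in sorted(healthy_fragments):
        frags = healthy_fragments[sid]
        if len(frags) < per_sample:
            warnings.warn(f"sample {sid!r} has {len(frags)} < {per_sample} fragments; using all")
        sub_seed = int(rng.integers(0, 2**31 - 1))
        pools.append(downsample_fragments(frags, per_sample, sub_seed))
    pooled = pd.concat(pools, ignore_index=True)
    res: CountResult = count_fragments(pooled, ws)
    if res.library_size == 0:
        raise ValueError("pooled healthy fragments hit no window")
    lengths = ws.lengths
    rpkm = res.counts.astype(float) * 1e9 / (lengths * float(res.library_size))
    return BaselineProfile(
        rpkm=rpkm.rename("baseline_rpkm"),
        target_depth=target_depth,
        sample_ids=sorted(healthy_fragments),
        seed=seed,
    )


def build_baseline_from_counts(
    cm: CountMatrix,
    ws: WindowSet,
    healthy_samples: Collection[str],
    target_depth: int,
    seed: int = 0,
) -> BaselineProfile:
    """Baseline from a count matrix: binomially thin each healthy sample to a
    common depth, pool the thinned counts, and compute RPKM of the pool.

    Thinning each window count with probability share/library_size is the
    count-level equivalent of uniform fragment downsampling.
    """
    healthy = sorted(healthy_samples)
    if not healthy:
        raise ValueError("need at least one healthy sample")
    per_sample = target_depth // len(healthy)
    rng = np.random.default_rng(seed)
    pooled = np.zeros(cm.values.shape[0], dtype=np.int64)
    for sid in healthy:
        counts = cm.values[sid].values
        lib = int(cm.library_size[sid])
        if lib <= per_sample:
            if lib < per_sample:
                warnings.warn(f"sample {sid!r} has {lib} < {per_sample} fragments; using all")
            pooled += counts
        else:
            pooled += rng.binomial(counts, per_sample / lib)
    lib_pool = int(pooled.sum())
    if lib_pool == 0:
        raise ValueError("pooled healthy counts are all zero")
    lengths = ws.lengths.reindex(cm.values.index)
    rpkm = pd.Series(pooled, index=cm.values.index, dtype=float) * 1e9 / (
        lengths * float(lib_pool)
    )
    return BaselineProfile(
        rpkm=rpkm.rename("baseline_rpkm"),
        target_depth=target_depth,
        sample_ids=healthy,
        seed=seed,
    )


def five_mc_score(
    sample_rpkm: pd.Series,
    baseline: BaselineProfile,
    dmr_windows: Collection[str],
) -> float:
    """Median absolute RPKM deviation from the healthy baseline at hyper-DMRs.

    The median is the midpoint of the two central order statistics for even
    window counts. Invariant to window order and to windows outside the DMR
    set; zero exactly when the sample equals the baseline on the set.
    """
    ids = sorted(set(dmr_windows))
    if not ids:
        raise ValueError("dmr_windows is empty")
    s = sample_rpkm.reindex(ids)
    b = baseline.rpkm.reindex(ids)
    if s.isna().any() or b.isna().any():
        raise KeyError("DMR windows missing from sample or baseline RPKM")
    return float(np.median(np.abs(s.values - b.values)))


def detection_threshold(healthy_scores) -> float:
    """Marker positivity threshold: the maximum value in the healthy cohort."""
    arr = np.asarray(list(healthy_scores), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one healthy score")
    return float(arr.max())


def classify_positive(value, threshold: float, rule: str = "greater"):
    """Classify a marker value against a threshold.

    rule='greater' (the 5-mC convention: a sample must *exceed* the healthy
    maximum) or rule='greater_equal' (the t-MAD convention). Missing values
    (None/NaN) are not evaluable and return None.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if rule == "greater":
        return bool(value > threshold)
    if rule == "greater_equal":
        return bool(value >= threshold)
    raise ValueError(f"unknown rule {rule!r}")


#: default per-marker decision rules; VAF-like markers use a fixed floor with >=
DEFAULT_RULES = {"score_5mc": "greater", "tmad": "greater_equal"}


@dataclass
class DetectionMatrix:
    """Per-sample marker positivity with per-marker and combined fractions."""

    calls: pd.DataFrame  # boolean with NA for not-evaluable; samples x markers
    sample_fractions: pd.Series
    combined_sample_fraction: float
    patient_fractions: pd.Series = field(default=None)
    combined_patient_fraction: float = float("nan")


def build_detection_matrix(
    markers: pd.DataFrame,
    thresholds: Mapping[str, float],
    rules: Mapping[str, str] | None = None,
    patient_col: str | None = "patient_id",
) -> DetectionMatrix:
    """Threshold each marker column of a per-sample table into a call matrix.

    ``markers`` has one row per sample; every column named in ``thresholds``
    is classified with its rule (default: strict greater, t-MAD >=). Missing
    values stay not-evaluable and drop out of denominators. Fractions are
    reported per sample and — when ``patient_col`` is present — per patient
    (a patient is positive on a marker iff any of their samples is).
    """
    rules = {**DEFAULT_RULES, **(rules or {})}
    marker_cols = [c for c in thresholds if c not in (patient_col,)]
    missing = [c for c in marker_cols if c not in markers.columns]
    if missing:
        raise KeyError(f"marker columns absent from table: {missing}")
    calls = pd.DataFrame(index=markers.index, columns=marker_cols, dtype=object)
    for col in marker_cols:
        rule = rules.get(col, "greater")
        calls[col] = [
            classify_positive(v, thresholds[col], rule) for v in markers[col]
        ]
    evaluable = calls.notna()
    positive = calls.eq(True)
    with np.errstate(invalid="ignore"):
        sample_fractions = positive.sum() / evaluable.sum().replace(0, np.nan)
    any_eval = evaluable.any(axis=1)
    any_pos = positive.any(axis=1)
    combined = float(any_pos[any_eval].mean()) if any_eval.any() else float("nan")

    patient_fractions, combined_patient = None, float("nan")
    if patient_col and patient_col in markers.columns:
        grouped_pos = positive.groupby(markers[patient_col]).any()
        grouped_eval = evaluable.groupby(markers[patient_col]).any()
        with np.errstate(invalid="ignore"):
            patient_fractions = grouped_pos.sum() / grouped_eval.sum().replace(0, np.nan)
        p_any_eval = grouped_eval.any(axis=1)
        p_any_pos = grouped_pos.any(axis=1)
        combined_patient = (
            float(p_any_pos[p_any_eval].mean()) if p_any_eval.any() else float("nan")
        )
    return DetectionMatrix(
        calls=calls,
        sample_fractions=sample_fractions.rename("positive_fraction"),
        combined_sample_fraction=combined,
        patient_fractions=patient_fractions,
        combined_patient_fraction=combined_patient,
    )


def score_concordance(x, y, method: str = "spearman") -> tuple[float, float]:
    """Correlation between two paired marker vectors over complete pairs."""
    x = pd.Series(list(x), dtype=float)
    y = pd.Series(list(y), dtype=float)
    ok = x.notna() & y.notna()
    if ok.sum() < 3:
        raise ValueError("need >=3 complete pairs")
    xv, yv = x[ok].values, y[ok].values
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        warnings.warn("constant marker vector; correlation undefined")
        return float("nan"), float("nan")
    if method == "spearman":
        r = stats.spearmanr(xv, yv)
    elif method == "pearson":
        r = stats.pearsonr(xv, yv)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)
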