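"""End-to-end orchestration of the discovery and monitoring analysis.

Chains the modules in the published order: window filtering, background
combination and masking, low-count filtering, TMM + log-CPM, moderated
differential methylation, tissue validation with a permutation overlap test,
healthy-baseline 5-mC scoring, detection thresholds, and longitudinal
progression calls. Mostly used by the acceptance script, the CLI and the
end-to-end tests; each step is equally callable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import json
import numpy as np
import pandas as pd

from . import background, dmr, monitor, score, validation, windows
from .simulate import SimulatedCohort


@dataclass
class DiscoveryResult:
    stats_cf: pd.DataFrame
    stats_tissue: pd.DataFrame
    cf_dmrs: dmr.DMRSet
    tissue_dmrs: dmr.DMRSet
    validated_hyper: set
    permutation: validation.PermutationResult
    tested_universe: list
    mask_kept: pd.Series


def _two_group_dmrs(
    cm: windows.CountMatrix,
    case_samples: list,
    control_samples: list,
    keep_windows: pd.Index,
    alpha: float,
    min_abs_lfc: float,
) -> tuple[pd.DataFrame, dmr.DMRSet, list]:
    sub = windows.CountMatrix(
        cm.values.loc[keep_windows, case_samples + control_samples],
        cm.library_size,
        cm.provenance,
    )
    low_keep = dmr.filter_low_count(sub)
    sub = windows.CountMatrix(sub.values.loc[low_keep], sub.library_size, sub.provenance)
    factors = dmr.tmm_factors(sub)
    logcpm = dmr.log_cpm(sub, factors)
    design = dmr.DesignSpec(
        pd.Series(
            ["case"] * len(case_samples) + ["control"] * len(control_samples),
            index=case_samples + control_samples,
        )
    )
    stats = dmr.moderated_two_group_test(logcpm, design)
    called = dmr.call_dmrs(stats, alpha=alpha, min_abs_lfc=min_abs_lfc)
    return stats, called, list(stats.index)


def run_discovery(
    cohort: SimulatedCohort,
    tau: float = background.DEFAULT_TAU,
    alpha: float = dmr.DEFAULT_ALPHA,
    min_abs_lfc: float = dmr.DEFAULT_MIN_ABS_LFC,
    n_perm: int = 10_000,
    seed: int = 0,
    apply_mask: bool = True,
) -> DiscoveryResult:
    """Discovery analysis on a simulated cohort: cfDNA DMRs, tissue validation.

    cfDNA DMRs (case vs control plasma) are called at background-depleted
    windows; tissue DMRs (tumor vs normal tissue) are called without the
    background mask. The hyper-DMR overlap is tested by permutation over the
    cfDNA tested universe.
    """
    ws = windows.filter_windows(cohort.window_set)
    combined = cohort.panel.combined().reindex(ws.window_ids)
    if apply_mask:
        keep = background.apply_background_mask(combined, tau)
        kept_windows = keep.index[keep]
    else:
        keep = pd.Series(True, index=ws.window_ids)
        kept_windows = ws.window_ids

    sheet = cohort.sample_sheet
    groups = sheet.set_index("sample_id")["group"]
    cases = list(groups.index[groups == "case"])
    controls = list(groups.index[groups == "control"])
    tumor_t = list(groups.index[groups == "tumor_tissue"])
    normal_t = list(groups.index[groups == "normal_tissue"])

    stats_cf, cf_dmrs, universe = _two_group_dmrs(
        cohort.counts, cases, controls, kept_windows, alpha, min_abs_lfc
    )
    stats_tissue, tissue_dmrs, _ = _two_group_dmrs(
        cohort.counts, tumor_t, normal_t, ws.window_ids, alpha, min_abs_lfc
    )
    validated = validation.intersect_dmrs(cf_dmrs, tissue_dmrs, "hyper")
    tissue_in_universe = tissue_dmrs.hyper & set(universe)
    if cf_dmrs.hyper:
        perm = validation.permutation_overlap_test(
            cf_size=len(cf_dmrs.hyper),
            observed_overlap=len(cf_dmrs.hyper & tissue_in_universe),
            tissue=tissue_in_universe,
            universe=universe,
            n_perm=n_perm,
            seed=seed,
        )
    else:
        perm = validation.PermutationResult(0, np.zeros(n_perm, dtype=np.int64), 1.0, n_perm, seed)
    return DiscoveryResult(
        stats_cf=stats_cf,
        stats_tissue=stats_tissue,
        cf_dmrs=cf_dmrs,
        tissue_dmrs=tissue_dmrs,
        validated_hyper=validated,
        permutation=perm,
        tested_universe=universe,
        mask_kept=keep,
    )


@dataclass
class ScoringResult:
    baseline: score.BaselineProfile
    scores: pd.Series  # per sample over discovery + longitudinal cohorts
    threshold: float
    scoring_windows: list


def run_scoring(
    cohort: SimulatedCohort,
    discovery: DiscoveryResult,
    seed: int = 0,
    use_validated: bool = True,
) -> ScoringResult:
    """Baseline construction and per-sample 5-mC scores.

    Scores are computed over the tissue-validated hyper-DMRs (falling back to
    the full cfDNA hyper set when validation is empty or disabled). The
    baseline pools the healthy plasma samples at the cohort's median library
    size; the detection threshold is the healthy maximum.
    """
    ws = cohort.window_set
    sheet = cohort.sample_sheet.set_index("sample_id")
    healthy = list(sheet.index[sheet["group"] == "control"])
    dmr_set = discovery.validated_hyper if use_validated else discovery.cf_dmrs.hyper
    if not dmr_set:
        dmr_set = discovery.cf_dmrs.hyper
    if not dmr_set:
        raise ValueError("no hyper-DMRs available for scoring")
    scoring_windows = sorted(dmr_set)

    if len(cohort.longitudinal_counts.samples):
        all_counts = windows.CountMatrix(
            pd.concat([cohort.counts.values, cohort.longitudinal_counts.values], axis=1),
            pd.concat([cohort.counts.library_size, cohort.longitudinal_counts.library_size]),
            "discovery+longitudinal",
        )
    else:
        all_counts = cohort.counts
    # common per-sample depth must not exceed the shallowest healthy library
    target_depth = int(cohort.counts.library_size.loc[healthy].min()) * len(healthy)
    baseline = score.build_baseline_from_counts(
        cohort.counts, ws, healthy, target_depth, seed=seed
    )
    rpkm = windows.compute_rpkm(all_counts, ws)
    scores = pd.Series(
        {
            sid: score.five_mc_score(rpkm[sid], baseline, scoring_windows)
            for sid in all_counts.samples
        },
        name="score_5mc",
    )
    threshold = score.detection_threshold(scores.loc[healthy])
    return ScoringResult(
        baseline=baseline,
        scores=scores,
        threshold=threshold,
        scoring_windows=scoring_windows,
    )


@dataclass
class MonitoringResult:
    timepoints: pd.DataFrame
    paired: monitor.PairedPDResult | None
    lead_times: pd.DataFrame


def run_monitoring(
    cohort: SimulatedCohort,
    scoring: ScoringResult,
    rise_frac: float = monitor.DEFAULT_RISE_FRAC,
) -> MonitoringResult:
    """Longitudinal analysis on the cohort's serial samples."""
    sheet = cohort.longitudinal_sheet.copy()
    sheet["score_5mc"] = scoring.scores.reindex(sheet["sample_id"]).values
    lines = monitor.segment_therapy_lines(sheet)
    try:
        paired = monitor.paired_start_vs_pd(lines)
    except ValueError:
        paired = None
    leads = monitor.cohort_lead_times(lines, rise_frac=rise_frac)
    return MonitoringResult(timepoints=sheet, paired=paired, lead_times=leads)


def write_results(
    outdir: str | Path,
    discovery: DiscoveryResult,
    scoring: ScoringResult,
    monitoring: MonitoringResult,
) -> None:
    """Write the pipeline's tables and summary JSON under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    discovery.stats_cf.to_csv(out / "dmr_stats_cfdna.tsv", sep="\t", index_label="window_id")
    discovery.stats_tissue.to_csv(out / "dmr_stats_tissue.tsv", sep="\t", index_label="window_id")
    pd.Series(sorted(discovery.cf_dmrs.hyper)).to_csv(
        out / "hyper_dmrs_cfdna.txt", index=False, header=False
    )
    pd.Series(sorted(discovery.validated_hyper)).to_csv(
        out / "hyper_dmrs_validated.txt", index=False, header=False
    )
    scoring.scores.to_csv(out / "scores_5mc.tsv", sep="\t", index_label="sample_id")
    monitoring.lead_times.to_csv(out / "lead_times.tsv", sep="\t", index=False)
    summary = {
        "n_hyper_dmrs": len(discovery.cf_dmrs.hyper),
        "n_hypo_dmrs": len(discovery.cf_dmrs.hypo),
        "n_validated_hyper": len(discovery.validated_hyper),
        "permutation_p": discovery.permutation.p_value,
        "permutation_p_display": discovery.permutation.display_p,
        "detection_threshold_5mc": scoring.threshold,
        "n_paired_increased": None if monitoring.paired is None else monitoring.paired.n_increased,
        "n_pairs": None if monitoring.paired is None else monitoring.paired.n_pairs,
        "paired_p": None if monitoring.paired is None else monitoring.paired.p_value,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
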