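"""Hematopoietic methylation background: combination, masking, threshold scan.

Plasma cfDNA is dominated by DNA released from blood cells, so windows that
are methylated in the hematopoietic compartment carry background rather than
tumor signal. Cell-type WGBS beta profiles, weighted by each cell type's
predicted contribution to healthy cfDNA, are summed into a combined background
methylation per window; windows whose combined beta exceeds an exclusion
threshold tau are masked out before differential analysis.

The threshold itself can be tuned by a split-reference scan: case cfDNA and
case tissue log2 fold-changes are computed against two disjoint halves of the
healthy cohort, and the tau maximizing their Spearman correlation over kept
windows is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

DEFAULT_TAU = 0.15


@dataclass
class CellTypeBetaPanel:
    """Cell-type WGBS beta matrix (window x cell type) plus cfDNA weights."""

    beta: pd.DataFrame
    weights: pd.Series

    def combined(self) -> pd.Series:
        return combine_background(self.beta, self.weights)


#: pseudocount (RPKM units) for fold-change computation
DEFAULT_EPSILON = 0.5
#: minimum kept windows for a tau to be eligible in the scan
MIN_SCAN_WINDOWS = 10


def combine_background(beta: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Weighted sum of cell-type beta values per window.

    Parameters
    ----------
    beta : window x cell-type matrix, values in [0, 1]. NaN marks a cell type
        not evaluable at a window; such windows get a NaN combined beta and are
        treated as not evaluable by :func:`apply_background_mask`.
    weights : non-negative per cell type; normalized to sum to 1.
    """
    weights = weights.reindex(beta.columns)
    if weights.isna().any():
        missing = weights.index[weights.isna()].tolist()
        raise KeyError(f"no weight for cell types {missing}")
    if (weights < 0).any():
        raise ValueError("negative cell-type weight")
    total = float(weights.sum())
    if total <= 0:
        raise ValueError("cell-type weights sum to zero")
    w = weights / total
    vals = beta.values.astype(float)
    if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
        raise ValueError("beta values outside [0, 1]")
    combined = beta.mul(w, axis=1).sum(axis=1, skipna=False)
    return combined.rename("combined_beta")


def apply_background_mask(combined_beta: pd.Series, tau: float = DEFAULT_TAU) -> pd.Series:
    """Boolean keep-mask: keep iff combined beta <= tau.

    The discovery analysis excluded windows with combined beta above 0.15; the
    boundary beta == tau is kept by convention. Windows with NaN combined beta
    (not evaluable) are never kept. The kept set is nested (monotone
    non-decreasing) in tau.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    keep = combined_beta <= tau
    keep[combined_beta.isna()] = False
    return keep.rename("keep")


@dataclass
class ThresholdScanResult:
    """Outcome of the split-reference exclusion-threshold scan."""

    table: pd.DataFrame  # columns: tau, n_kept, spearman_rho
    selected_tau: float
    half_a: list
    half_b: list
    dropped: list


def _log2fc(case_mean: np.ndarray, ref_mean: np.ndarray, eps: float) -> np.ndarray:
    return np.log2((case_mean + eps) / (ref_mean + eps))


def scan_exclusion_threshold(
    case_cf_abund: pd.DataFrame,
    case_tissue_abund: pd.DataFrame,
    healthy_abund: pd.DataFrame,
    combined_beta: pd.Series,
    tau_grid: Sequence[float],
    split_seed: int = 0,
    epsilon: float = DEFAULT_EPSILON,
) -> ThresholdScanResult:
    """Scan tau over a grid, scoring cfDNA-vs-tissue fold-change concordance.

    Healthy samples are split at random (under ``split_seed``) into two
    disjoint halves (an odd sample is dropped). Per window,
    ``lfc_cf = log2((mean case cfDNA RPKM + eps) / (mean half-A RPKM + eps))``
    and ``lfc_tissue`` analogously against half B. For every tau the Spearman
    correlation of the two fold-change vectors over kept windows is recorded;
    the selected tau attains the maximum correlation (ties broken toward the
    smallest tau). A tau keeping fewer than 10 windows gets an undefined
    correlation and is never selected.
    """
    healthy = list(healthy_abund.columns)
    if len(healthy) < 2:
        raise ValueError("need at least 2 healthy samples to split")
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(len(healthy))
    half = len(healthy) // 2
    half_a = [healthy[i] for i in order[:half]]
    half_b = [healthy[i] for i in order[half : 2 * half]]
    dropped = [healthy[i] for i in order[2 * half :]]

    idx = case_cf_abund.index
    if not (case_tissue_abund.index.equals(idx) and healthy_abund.index.equals(idx)):
        raise ValueError("abundance matrices must share one window index")
    beta = combined_beta.reindex(idx)

    lfc_cf = _log2fc(
        case_cf_abund.mean(axis=1).values, healthy_abund[half_a].mean(axis=1).values, epsilon
    )
    lfc_tissue = _log2fc(
        case_tissue_abund.mean(axis=1).values,
        healthy_abund[half_b].mean(axis=1).values,
        epsilon,
    )

    rows = []
    for tau in tau_grid:
        keep = apply_background_mask(beta, float(tau)).values
        n_kept = int(keep.sum())
        if n_kept < MIN_SCAN_WINDOWS:
            rho = np.nan
        else:
            rho = spearmanr(lfc_cf[keep], lfc_tissue[keep]).statistic
        rows.append((float(tau), n_kept, rho))
    table = pd.DataFrame(rows, columns=["tau", "n_kept", "spearman_rho"])
    if table["spearman_rho"].isna().all():
        raise ValueError("no tau in the grid keeps enough windows")
    best = table["spearman_rho"].max()
    selected = float(table.loc[table["spearman_rho"] >= best, "tau"].min())
    if table["spearman_rho"].isna().any():
        warnings.warn("some tau values kept too few windows; recorded as undefined")
    return ThresholdScanResult(table, selected, half_a, half_b, dropped)
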