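"""Tissue validation of cfDNA DMRs: directional intersection and permutation test.

cfDNA-derived DMRs are validated by intersecting them with DMRs called from
tumor-versus-normal tissue on the same window universe, and the significance
of the overlap is assessed by resampling random window sets of the same size
from the tested universe. Because the null draws windows uniformly without
replacement, the null overlap distribution is exactly hypergeometric, which
small instances can verify in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Iterable

import numpy as np
import pandas as pd

from .dmr import DMRSet


def intersect_dmrs(cf: DMRSet, tissue: DMRSet, direction: str) -> set:
    """Same-direction window intersection of two DMR sets."""
    if direction not in ("hyper", "hypo"):
        raise ValueError("direction must be 'hyper' or 'hypo'")
    return getattr(cf, direction) & getattr(tissue, direction)


@dataclass
class PermutationResult:
    observed_overlap: int
    null_overlaps: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    @property
    def display_p(self) -> str:
        """p floored at the test's resolution, e.g. '< 1e-04' at 10,000 draws."""
        if self.p_value == 0.0:
            return f"< {1.0 / self.n_perm:.0e}"
        return f"{self.p_value:.4g}"


def permutation_overlap_test(
    cf_size: int,
    observed_overlap: int,
    tissue: Collection,
    universe: Iterable,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of window-set overlap against uniform resampling.

    Each permutation draws ``cf_size`` windows uniformly without replacement
    from ``universe`` and records the overlap with ``tissue``;
    ``p = #(null >= observed) / n_perm`` with no +1 correction (display floors
    at 1/n_perm). The universe should be the set actually tested, i.e. the
    background-depleted, low-count-filtered windows.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    universe = pd.Index(universe)
    if universe.has_duplicates:
        raise ValueError("universe contains duplicate window ids")
    n_universe = len(universe)
    if cf_size > n_universe:
        raise ValueError("cf_size exceeds universe size")
    tissue = set(tissue)
    if not tissue <= set(universe):
        raise ValueError("tissue set not contained in universe")
    if observed_overlap > min(cf_size, len(tissue)):
        raise ValueError("observed overlap exceeds the smaller set")

    tissue_mask = universe.isin(tissue).astype(np.float32)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    # chunked Gumbel-top-k sampling without replacement, vectorized per chunk
    chunk = max(1, int(2e7 // max(n_universe, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n_universe))
        idx = np.argpartition(keys, cf_size - 1, axis=1)[:, :cf_size]
        null[done : done + m] = tissue_mask[idx.ravel()].reshape(m, cf_size).sum(axis=1)
        done += m
    p = float((null >= observed_overlap).sum()) / n_perm
    return PermutationResult(
        observed_overlap=int(observed_overlap),
        null_overlaps=null,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )
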