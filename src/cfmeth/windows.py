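"""Genomic window universe, fragment counting and RPKM abundances.

The analysis interrogates methylation-proportional coverage at a fixed set of
non-overlapping genomic windows (methylation blocks: runs of adjacent CpGs with
concordant methylation status). Everything downstream — background masking,
differential methylation, 5-mC scoring — is indexed by these windows, so this
module owns the coordinate conventions: 0-based half-open (BED) coordinates,
windows sorted by (chrom, start), unique window identifiers.

Fragments arrive as intervals (alignment and deduplication are upstream) and
are assigned to windows by their midpoint, which guarantees that a fragment is
counted at most once over a non-overlapping universe.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

WINDOW_COLUMNS = ["chrom", "start", "end", "window_id", "n_cpg"]
FRAGMENT_COLUMNS = ["chrom", "start", "end"]

DEFAULT_MIN_CPG = 3
DEFAULT_EXCLUDED_CHROMS = frozenset({"chrX", "chrY", "chrM"})


class WindowValidationError(ValueError):
    """Raised when a window universe violates its invariants."""


@dataclass
class WindowSet:
    """An ordered, validated universe of non-overlapping genomic windows.

    Parameters
    ----------
    df : DataFrame with columns (chrom, start, end, window_id, n_cpg).
    provenance : free-text note on origin and filters applied.
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in WINDOW_COLUMNS if c not in df.columns]
        if missing:
            raise WindowValidationError(f"window table lacks columns {missing}")
        df = df.loc[:, WINDOW_COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["n_cpg"] = df["n_cpg"].astype(np.int64)
        if (df["end"] <= df["start"]).any():
            bad = df.loc[df["end"] <= df["start"], "window_id"].iloc[0]
            raise WindowValidationError(f"window {bad!r} has end <= start")
        if (df["n_cpg"] < 0).any():
            raise WindowValidationError("negative CpG count")
        if df["window_id"].duplicated().any():
            dup = df.loc[df["window_id"].duplicated(), "window_id"].iloc[0]
            raise WindowValidationError(f"duplicate window_id {dup!r}")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        # overlap check within chromosome on the sorted frame
        same_chrom = df["chrom"].values[1:] == df["chrom"].values[:-1]
        overlaps = same_chrom & (df["start"].values[1:] < df["end"].values[:-1])
        if overlaps.any():
            i = int(np.flatnonzero(overlaps)[0])
            a, b = df["window_id"].iloc[i], df["window_id"].iloc[i + 1]
            raise WindowValidationError(f"windows {a!r} and {b!r} overlap")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def window_ids(self) -> pd.Index:
        return pd.Index(self.df["window_id"])

    @property
    def lengths(self) -> pd.Series:
        """Window lengths in bp (end - start), indexed by window_id."""
        return pd.Series(
            (self.df["end"] - self.df["start"]).values,
            index=self.df["window_id"].values,
            name="length",
        )

    def subset(self, window_ids: Iterable[str], provenance: str = "") -> "WindowSet":
        ids = set(window_ids)
        unknown = ids - set(self.df["window_id"])
        if unknown:
            raise KeyError(f"unknown window ids, e.g. {sorted(unknown)[:3]}")
        sub = self.df[self.df["window_id"].isin(ids)]
        return WindowSet(sub, provenance or f"{self.provenance} | subset({len(ids)})")

    def to_bed(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_windows(path: str | Path, provenance: str | None = None) -> WindowSet:
    """Read a window universe from BED5 (chrom, start, end, window_id, n_cpg).

    Tab-separated, no header; coordinates 0-based half-open. Malformed lines
    raise with the offending line number; overlapping windows or duplicate IDs
    raise :class:`WindowValidationError`.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]), parts[3], int(parts[4]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable fields: {exc}") from exc
    if not rows:
        warnings.warn(f"{path}: no windows read; returning empty WindowSet")
        df = pd.DataFrame(columns=WINDOW_COLUMNS)
    else:
        df = pd.DataFrame(rows, columns=WINDOW_COLUMNS)
    return WindowSet(df, provenance or str(path))


def filter_windows(
    ws: WindowSet,
    min_cpg: int = DEFAULT_MIN_CPG,
    excluded_chroms: Iterable[str] = DEFAULT_EXCLUDED_CHROMS,
) -> WindowSet:
    """Drop windows with fewer than ``min_cpg`` CpGs or on excluded chromosomes.

    Default thresholds mirror the discovery analysis: windows covering fewer
    than 3 CpG sites or mapping to chrX, chrY or the mitochondrial genome are
    removed. Order is preserved; the result may be empty (with a warning).
    """
    excluded = set(excluded_chroms)
    keep = (ws.df["n_cpg"] >= min_cpg) & (~ws.df["chrom"].isin(excluded))
    out = ws.df[keep]
    if out.empty:
        warnings.warn("filter_windows: no windows retained")
    prov = f"{ws.provenance} | min_cpg>={min_cpg}, excluded={sorted(excluded)}"
    return WindowSet(out, prov)


def read_fragments(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read fragment intervals from BED3(+sample) into a DataFrame.

    Gzip-transparent. A 4th column, when present, is kept as ``sample_id``;
    otherwise the ``sample_id`` argument (if given) is broadcast.
    """
    rows = []
    has_sample = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            if len(parts) >= 4:
                has_sample = True
                rows.append((parts[0], start, end, parts[3]))
            else:
                rows.append((parts[0], start, end))
    cols = FRAGMENT_COLUMNS + (["sample_id"] if has_sample else [])
    df = pd.DataFrame(rows, columns=cols)
    if not has_sample and sample_id is not None:
        df["sample_id"] = sample_id
    return df


@dataclass
class CountResult:
    """Per-window fragment counts for one sample plus bookkeeping."""

    counts: pd.Series  # indexed by window_id
    library_size: int  # fragments assigned to any window
    n_input: int
    n_unassigned: int  # midpoint in no window (known chrom)
    n_unknown_chrom: int


def assign_to_windows(fragments: pd.DataFrame, ws: WindowSet) -> np.ndarray:
    """Midpoint-assign fragments to window row indices; -1 where unassigned.

    The midpoint of [start, end) is (start + end) // 2; a fragment belongs to
    the window whose half-open interval contains that coordinate. Over a
    non-overlapping universe this assigns each fragment to at most one window.
    """
    n = len(fragments)
    out = np.full(n, -1, dtype=np.int64)
    if n == 0 or len(ws) == 0:
        return out
    mid = (fragments["start"].values + fragments["end"].values) // 2
    wdf = ws.df
    for chrom, idx in fragments.groupby("chrom", sort=False).indices.items():
        wmask = wdf["chrom"].values == chrom
        if not wmask.any():
            continue
        wrows = np.flatnonzero(wmask)
        starts = wdf["start"].values[wrows]
        ends = wdf["end"].values[wrows]
        m = mid[idx]
        pos = np.searchsorted(starts, m, side="right") - 1
        ok = (pos >= 0) & (m < ends[np.clip(pos, 0, None)])
        out[idx[ok]] = wrows[pos[ok]]
    return out


def count_fragments(fragments: pd.DataFrame, ws: WindowSet) -> CountResult:
    """Count one sample's fragments into windows by the midpoint rule.

    library_size is the number of fragments assigned to any window of the
    universe at count time; it is recorded here and deliberately not
    recomputed after later window subsetting, so RPKM denominators are stable
    across DMR subsets. Fragments on chromosomes absent from the universe are
    skipped and tallied.
    """
    assigned = assign_to_windows(fragments, ws)
    known = (
        fragments["chrom"].isin(set(ws.df["chrom"])).values
        if len(fragments)
        else np.zeros(0, dtype=bool)
    )
    hit = assigned >= 0
    counts = np.bincount(assigned[hit], minlength=len(ws)) if hit.any() else np.zeros(
        len(ws), dtype=np.int64
    )
    return CountResult(
        counts=pd.Series(counts, index=ws.window_ids, name="count"),
        library_size=int(hit.sum()),
        n_input=len(fragments),
        n_unassigned=int((~hit & known).sum()),
        n_unknown_chrom=int((~known).sum()),
    )


@dataclass
class CountMatrix:
    """Window x sample fragment counts with per-sample library sizes.

    ``library_size`` is the per-sample count of window-assigned fragments over
    the *full* universe, frozen at count time (see :func:`count_fragments`).
    """

    values: pd.DataFrame  # windows x samples, non-negative integers
    library_size: pd.Series  # per sample
    provenance: str = ""

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("negative counts")
        missing = [s for s in self.values.columns if s not in self.library_size.index]
        if missing:
            raise ValueError(f"library_size missing for samples {missing}")
        self.library_size = self.library_size.loc[self.values.columns].astype(np.int64)

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_windows(self, window_ids: Iterable[str]) -> "CountMatrix":
        ids = [w for w in window_ids if w in self.values.index]
        return CountMatrix(self.values.loc[ids], self.library_size, self.provenance)

    def write(self, counts_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        self.values.to_csv(counts_path, sep="\t", index_label="window_id")
        if sidecar_path is not None:
            meta = {
                "library_size": {k: int(v) for k, v in self.library_size.items()},
                "provenance": self.provenance,
            }
            Path(sidecar_path).write_text(json.dumps(meta, indent=1, sort_keys=True))

    @classmethod
    def read(cls, counts_path: str | Path, sidecar_path: str | Path) -> "CountMatrix":
        values = pd.read_csv(counts_path, sep="\t", index_col="window_id")
        meta = json.loads(Path(sidecar_path).read_text())
        lib = pd.Series(meta["library_size"], dtype=np.int64)
        return cls(values, lib, meta.get("provenance", str(counts_path)))


def build_count_matrix(
    fragments_by_sample: Mapping[str, pd.DataFrame], ws: WindowSet
) -> CountMatrix:
    """Count several samples' fragment sets into one matrix."""
    cols, libs = {}, {}
    for sid, frags in fragments_by_sample.items():
        res = count_fragments(frags, ws)
        cols[sid] = res.counts
        libs[sid] = res.library_size
    values = pd.DataFrame(cols, index=ws.window_ids)
    return CountMatrix(values, pd.Series(libs), provenance="build_count_matrix")


def compute_rpkm(cm: CountMatrix, ws: WindowSet) -> pd.DataFrame:
    """Reads per kilobase of window per million counted fragments.

    RPKM[w, s] = count[w, s] * 1e9 / (length_bp[w] * library_size[s]).
    Window length is end - start in bp. Zero counts map to exactly 0, and the
    value is invariant to jointly scaling counts and library size.
    """
    if (cm.library_size <= 0).any():
        bad = cm.library_size.index[cm.library_size <= 0].tolist()
        raise ValueError(f"zero library size for samples {bad}")
    lengths = ws.lengths.reindex(cm.values.index)
    if lengths.isna().any():
        bad = lengths.index[lengths.isna()].tolist()[:3]
        raise KeyError(f"windows absent from universe, e.g. {bad}")
    num = cm.values.astype(float).mul(1e9)
    return num.div(lengths, axis=0).div(cm.library_size.astype(float), axis=1)


def downsample_fragments(
    fragments: pd.DataFrame, target_n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Uniform subsample of min(target_n, n) fragments without replacement.

    Deterministic for a fixed seed; preserves the original row order of the
    retained fragments.
    """
    if target_n < 0:
        raise ValueError("target_n must be >= 0")
    n = len(fragments)
    if target_n >= n:
        return fragments.copy()
    rng = np.random.default_rng(seed)
    keep = rng.choice(n, size=target_n, replace=False)
    keep.sort()
    return fragments.iloc[keep].reset_index(drop=True)
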