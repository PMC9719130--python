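"""Synthetic cfMeDIP-seq-like data with ground truth.

The generator emulates the statistical structure the analysis assumes:

* a window universe (methylation blocks) with CpG counts, including some
  low-CpG and sex-chromosome windows so upstream filters have work to do;
* a cell-type beta panel with cfDNA contribution weights, where most windows
  are either lowly methylated across hematopoietic cell types or highly
  methylated, plus a minority methylated in a single cell type;
* a tumor methylome hypermethylated at windows drawn from the low-background
  compartment (tumor-informative DMRs by construction);
* case-specific non-tumor "blood methylation" shifts planted at windows whose
  combined background beta lies above the exclusion threshold — the
  confounding signal that background masking is meant to remove;
* negative-binomial MeDIP counts whose expectation is linear in methylated
  CpG content per window, mixed by tumor fraction;
* longitudinal tumor-fraction trajectories (exponential response, then
  exponential regrowth after resistance onset) with radiology labels derived
  from the latent fraction;
* segmental copy-number alterations in fixed bins, observable through two
  "platforms" that differ by a per-bin multiplicative bias.

Everything is seeded and deterministic; ground truth is returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import json
import numpy as np
import pandas as pd

from .background import CellTypeBetaPanel, combine_background
from .windows import CountMatrix, WindowSet

#: relative cell-type contributions to healthy cfDNA (generator ground truth)
DEFAULT_CELL_TYPE_WEIGHTS = {
    "granulocyte": 0.35,
    "lymphocyte": 0.25,
    "monocyte": 0.10,
    "megakaryocyte": 0.08,
    "erythroblast": 0.05,
    "endothelial": 0.09,
    "hepatocyte": 0.08,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions."""

    # window universe
    n_windows: int = 20_000
    window_length_range: tuple[int, int] = (200, 1_000)
    cpg_geometric_p: float = 0.25  # n_cpg ~ Geometric(p), support >= 1
    autosomes: tuple[str, ...] = ("chr1", "chr2", "chr3", "chr4")
    frac_chrx: float = 0.02
    # background methylation structure
    cell_type_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CELL_TYPE_WEIGHTS)
    )
    frac_low: float = 0.35
    frac_cellspec: float = 0.10
    beta_concentration: float = 200.0
    # tumor methylome
    n_true_dmrs: int = 200
    effect_delta_beta: float = 0.6
    background_tau: float = 0.15
    # case-specific non-tumor blood methylation shifts
    n_confounders: int = 300
    confounder_delta: float = 0.35
    confounder_beta_range: tuple[float, float] = (0.20, 0.50)
    # cohort
    n_cases: int = 20
    n_controls: int = 13
    n_tumor_tissues: int = 15
    n_normal_tissues: int = 10
    case_tumor_fraction_range: tuple[float, float] = (0.20, 0.40)
    tissue_tumor_fraction: float = 0.60
    depth: int = 500_000
    dispersion: float = 0.2
    capture_baseline: float = 0.05
    # longitudinal therapy-line trajectories
    n_longitudinal: int = 11
    sampling_interval_days: int = 30
    followup_days: int = 720
    f0_range: tuple[float, float] = (0.10, 0.30)
    response_rate_range: tuple[float, float] = (0.02, 0.05)  # per day
    onset_day_range: tuple[int, int] = (60, 200)
    regrowth_rate_range: tuple[float, float] = (0.015, 0.035)  # per day
    pd_fraction: float = 0.35  # latent fraction labeled radiologic PD
    # copy-number simulation
    cna_chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {f"cna{i}": 40_000_000 for i in range(1, 9)}
    )
    cna_bin_size: int = 1_000_000
    cna_gain_prob: float = 0.30
    cna_loss_prob: float = 0.20
    cna_depth: int = 200_000
    cna_bias_sd: float = 0.30  # lognormal per-bin bias of the MeDIP-like platform
    fragment_length: int = 160


# ---------------------------------------------------------------------------
# reference panel


def _archetypes(config: SimulationConfig, n: int, rng: np.random.Generator):
    """Per-window methylation class and archetype level.

    Classes: 'low' (background beta kept under the exclusion threshold),
    'high' (clearly methylated in all cell types), 'cellspec' (one cell type
    methylated, the rest low).
    """
    classes = rng.choice(
        ["low", "cellspec", "high"],
        size=n,
        p=[config.frac_low, config.frac_cellspec, 1 - config.frac_low - config.frac_cellspec],
    )
    low = 0.12 * rng.beta(1.0, 6.0, size=n)
    high = 0.20 + 0.80 * rng.beta(2.0, 3.0, size=n)
    spec = 0.60 + 0.40 * rng.beta(2.0, 2.0, size=n)
    return classes, low, high, spec


def simulate_reference(
    config: SimulationConfig, seed: int
) -> tuple[WindowSet, CellTypeBetaPanel]:
    """Window universe plus cell-type beta panel with ground-truth weights."""
    rng = np.random.default_rng(seed)
    n = config.n_windows
    lengths = rng.integers(*config.window_length_range, size=n, endpoint=True)
    n_cpg = rng.geometric(config.cpg_geometric_p, size=n)
    n_x = int(round(config.frac_chrx * n))
    chrom_pool = list(config.autosomes)
    chroms = np.array(
        [chrom_pool[i % len(chrom_pool)] for i in range(n - n_x)] + ["chrX"] * n_x
    )
    # consecutive placement per chromosome with 100-bp gaps
    starts = np.zeros(n, dtype=np.int64)
    cursor: dict[str, int] = {}
    for i in range(n):
        c = chroms[i]
        starts[i] = cursor.get(c, 0)
        cursor[c] = int(starts[i] + lengths[i] + 100)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + lengths,
            "window_id": [f"w{i:06d}" for i in range(n)],
            "n_cpg": n_cpg,
        }
    )
    ws = WindowSet(df, provenance=f"simulate_reference(seed={seed})")

    cell_types = list(config.cell_type_weights)
    classes, low, high, spec = _archetypes(config, n, rng)
    arche = np.where(classes == "low", low, high)
    kappa = config.beta_concentration
    beta = {}
    spec_type = rng.integers(0, len(cell_types), size=n)
    for ci, ct in enumerate(cell_types):
        m = arche.copy()
        is_spec = classes == "cellspec"
        m[is_spec] = np.where(spec_type[is_spec] == ci, spec[is_spec], low[is_spec])
        m = np.clip(m, 1e-3, 1 - 1e-3)
        beta[ct] = rng.beta(m * kappa, (1 - m) * kappa)
    beta_df = pd.DataFrame(beta, index=df["window_id"].values).loc[:, cell_types]
    weights = pd.Series(config.cell_type_weights, dtype=float)
    weights = weights / weights.sum()
    return ws, CellTypeBetaPanel(beta=beta_df, weights=weights)


# ---------------------------------------------------------------------------
# methylomes


def _eligible_hosts(ws: WindowSet, combined: pd.Series, config: SimulationConfig) -> pd.Index:
    """Windows that survive the standard upstream filters."""
    df = ws.df.set_index("window_id")
    ok = (df["n_cpg"] >= 3) & (~df["chrom"].isin(["chrX", "chrY", "chrM"]))
    return df.index[ok & combined.reindex(df.index).notna()]


def simulate_tumor_methylome(
    ws: WindowSet,
    panel: CellTypeBetaPanel,
    config: SimulationConfig,
    seed: int,
) -> tuple[pd.Series, list[str]]:
    """Tumor methylation profile: background plus planted hyper-DMRs.

    True DMRs are drawn from filter-passing windows whose combined background
    beta is at or below the exclusion threshold, so every planted DMR is
    tumor-informative by construction.
    """
    rng = np.random.default_rng(seed)
    combined = panel.combined()
    hosts = _eligible_hosts(ws, combined, config)
    hosts = hosts[combined.loc[hosts] <= config.background_tau]
    if len(hosts) < config.n_true_dmrs:
        raise ValueError(
            f"only {len(hosts)} low-background host windows for {config.n_true_dmrs} DMRs"
        )
    dmrs = sorted(rng.choice(hosts.values, size=config.n_true_dmrs, replace=False))
    tumor = combined.copy().rename("tumor_beta")
    tumor.loc[dmrs] = np.minimum(1.0, tumor.loc[dmrs] + config.effect_delta_beta)
    return tumor, list(dmrs)


def pick_confounder_windows(
    ws: WindowSet, panel: CellTypeBetaPanel, config: SimulationConfig, seed: int
) -> list[str]:
    """Hosts for case-specific blood-methylation shifts: windows methylated in
    the background (combined beta inside ``confounder_beta_range``)."""
    rng = np.random.default_rng(seed)
    combined = panel.combined()
    lo, hi = config.confounder_beta_range
    hosts = _eligible_hosts(ws, combined, config)
    hosts = hosts[(combined.loc[hosts] > lo) & (combined.loc[hosts] <= hi)]
    k = min(config.n_confounders, len(hosts))
    return sorted(rng.choice(hosts.values, size=k, replace=False))


# ---------------------------------------------------------------------------
# counts


def expected_propensity(
    methylation: pd.Series, ws: WindowSet, config: SimulationConfig
) -> pd.Series:
    """Unnormalized MeDIP pulldown propensity per window.

    lambda_w = L_w * (a + m_w * n_cpg_w): capture grows linearly with the
    window's methylated-CpG content on top of a constant nonspecific term a.
    """
    df = ws.df.set_index("window_id")
    m = methylation.reindex(df.index)
    lam = (df["end"] - df["start"]) * (config.capture_baseline + m * df["n_cpg"])
    return lam.rename("propensity")


def simulate_sample_counts(
    mixture_methylation: pd.Series,
    ws: WindowSet,
    config: SimulationConfig,
    rng: np.random.Generator,
    depth: int | None = None,
) -> pd.Series:
    """Negative-binomial window counts for one sample.

    Mean depth * lambda_w / sum(lambda); variance mu + dispersion * mu^2
    (Poisson in the dispersion -> 0 limit).
    """
    depth = config.depth if depth is None else depth
    lam = expected_propensity(mixture_methylation, ws, config).values
    mu = depth * lam / lam.sum()
    phi = config.dispersion
    if phi < 1e-9:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu))
    return pd.Series(counts, index=ws.window_ids, name="count")


def mixture_methylation(
    background: pd.Series, tumor: pd.Series, f: float
) -> pd.Series:
    if not 0.0 <= f <= 1.0:
        raise ValueError("tumor fraction must lie in [0, 1]")
    return (1.0 - f) * background + f * tumor


def counts_to_fragments(
    counts: pd.Series, ws: WindowSet, rng: np.random.Generator, frag_len: int = 160
) -> pd.DataFrame:
    """Emit fragment intervals whose midpoints fall uniformly in each window."""
    df = ws.df.set_index("window_id").loc[counts.index]
    reps = counts.values.astype(np.int64)
    chrom = np.repeat(df["chrom"].values, reps)
    lo = np.repeat(df["start"].values, reps)
    hi = np.repeat(df["end"].values, reps)
    mid = rng.integers(lo, hi)
    start = np.maximum(mid - frag_len // 2, 0)
    return pd.DataFrame({"chrom": chrom, "start": start, "end": start + frag_len})


# ---------------------------------------------------------------------------
# cohort

SampleSheet = pd.DataFrame


@dataclass
class SimulatedCohort:
    """Discovery cohort plus longitudinal series and ground truth."""

    window_set: WindowSet
    panel: CellTypeBetaPanel
    counts: CountMatrix  # discovery samples (cases, controls, tissues)
    sample_sheet: SampleSheet  # sample_id, group, tumor_fraction
    longitudinal_counts: CountMatrix
    longitudinal_sheet: SampleSheet  # + patient_id, date, therapy_line, radiology
    truth: dict
    config: SimulationConfig
    seed: int

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.window_set.to_bed(out / "windows.bed")
        self.panel.beta.to_csv(out / "beta_panel.tsv", sep="\t", index_label="window_id")
        self.panel.weights.rename("weight").to_csv(
            out / "cell_type_weights.tsv", sep="\t", header=False
        )
        self.counts.write(out / "counts.tsv", out / "counts.json")
        self.sample_sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
        self.longitudinal_counts.write(
            out / "longitudinal_counts.tsv", out / "longitudinal_counts.json"
        )
        sheet = self.longitudinal_sheet.copy()
        sheet["date"] = pd.to_datetime(sheet["date"]).dt.strftime("%Y-%m-%d")
        sheet.to_csv(out / "longitudinal_samples.tsv", sep="\t", index=False)
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        serializable = {
            k: v
            for k, v in self.truth.items()
            if k in ("true_dmrs", "confounders", "tumor_fractions")
        }
        (truth_dir / "truth.json").write_text(json.dumps(serializable, indent=1, sort_keys=True))


def _case_background(
    background: pd.Series, confounders: list[str], delta: float
) -> pd.Series:
    shifted = background.copy()
    shifted.loc[confounders] = np.minimum(1.0, shifted.loc[confounders] + delta)
    return shifted


def simulate_trajectory(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """One patient's latent tumor-fraction series with radiology labels.

    f(t) decays exponentially under therapy until resistance onset, then
    regrows exponentially; the first sampling after onset at which
    f >= pd_fraction is labeled radiologic PD and ends the line (therapy
    switch). Lines never reaching PD inside the follow-up window are censored.
    """
    f0 = rng.uniform(*config.f0_range)
    r_resp = rng.uniform(*config.response_rate_range)
    t_on = rng.uniform(*config.onset_day_range)
    r_res = rng.uniform(*config.regrowth_rate_range)
    rows = []
    t = 0
    while t <= config.followup_days:
        decay = f0 * np.exp(-r_resp * min(t, t_on))
        f = decay if t <= t_on else decay * np.exp(r_res * (t - t_on))
        f = min(f, 1.0)
        is_pd = t > t_on and f >= config.pd_fraction
        rows.append({"day": t, "tumor_fraction": f, "radiology": "PD" if is_pd else "SD"})
        if is_pd:
            break
        t += config.sampling_interval_days
    df = pd.DataFrame(rows)
    df.attrs.update(
        {"f0": f0, "response_rate": r_resp, "onset_day": t_on, "regrowth_rate": r_res}
    )
    return df


def simulate_cohort(config: SimulationConfig, seed: int) -> SimulatedCohort:
    """Generate the full synthetic study with ground truth."""
    root = np.random.default_rng(seed)
    ws, panel = simulate_reference(config, int(root.integers(2**31 - 1)))
    combined = panel.combined()
    tumor_beta, true_dmrs = simulate_tumor_methylome(
        ws, panel, config, int(root.integers(2**31 - 1))
    )
    confounders = pick_confounder_windows(
        ws, panel, config, int(root.integers(2**31 - 1))
    )
    case_bg = _case_background(combined, confounders, config.confounder_delta)

    rng = np.random.default_rng(int(root.integers(2**31 - 1)))
    cols, sheet_rows, fractions = {}, [], {}

    def add_sample(sid, group, f, background):
        m = mixture_methylation(background, tumor_beta, f)
        cols[sid] = simulate_sample_counts(m, ws, config, rng)
        sheet_rows.append({"sample_id": sid, "group": group, "tumor_fraction": f})
        fractions[sid] = f

    for i in range(config.n_controls):
        add_sample(f"healthy_{i:02d}", "control", 0.0, combined)
    case_f = rng.uniform(*config.case_tumor_fraction_range, size=config.n_cases)
    for i in range(config.n_cases):
        add_sample(f"case_{i:02d}", "case", float(case_f[i]), case_bg)
    for i in range(config.n_tumor_tissues):
        add_sample(f"tumor_tissue_{i:02d}", "tumor_tissue", config.tissue_tumor_fraction, combined)
    for i in range(config.n_normal_tissues):
        add_sample(f"normal_tissue_{i:02d}", "normal_tissue", 0.0, combined)

    values = pd.DataFrame(cols, index=ws.window_ids)
    lib = values.sum(axis=0)
    counts = CountMatrix(values, lib, provenance=f"simulate_cohort(seed={seed})")
    sample_sheet = pd.DataFrame(sheet_rows)

    # longitudinal series (one therapy line per patient)
    lrng = np.random.default_rng(int(root.integers(2**31 - 1)))
    lcols, lrows, trajectories = {}, [], {}
    t0 = pd.Timestamp("2019-01-01")
    for p in range(config.n_longitudinal):
        pid = f"P{p:03d}"
        traj = simulate_trajectory(config, lrng)
        trajectories[pid] = traj
        reached_pd = (traj["radiology"] == "PD").any()
        for j, row in traj.iterrows():
            sid = f"{pid}_t{j:02d}"
            m = mixture_methylation(case_bg, tumor_beta, float(row["tumor_fraction"]))
            lcols[sid] = simulate_sample_counts(m, ws, config, lrng)
            lrows.append(
                {
                    "sample_id": sid,
                    "patient_id": pid,
                    "date": t0 + pd.Timedelta(days=int(row["day"])),
                    "therapy_line": "L1",
                    "radiology": row["radiology"],
                    "end_reason": "switch" if reached_pd else "censored",
                    "tumor_fraction": float(row["tumor_fraction"]),
                }
            )
    lvalues = pd.DataFrame(lcols, index=ws.window_ids)
    lcounts = CountMatrix(lvalues, lvalues.sum(axis=0), provenance="simulate_cohort longitudinal")
    lsheet = pd.DataFrame(lrows)

    truth = {
        "true_dmrs": true_dmrs,
        "confounders": confounders,
        "tumor_beta": tumor_beta,
        "combined_beta": combined,
        "tumor_fractions": fractions,
        "trajectories": trajectories,
    }
    return SimulatedCohort(
        window_set=ws,
        panel=panel,
        counts=counts,
        sample_sheet=sample_sheet,
        longitudinal_counts=lcounts,
        longitudinal_sheet=lsheet,
        truth=truth,
        config=config,
        seed=seed,
    )


def simulate_marker_trajectories(
    n_patients: int,
    config: SimulationConfig,
    seed: int,
    marker_scale: float = 3.0,
    noise_sd: float = 0.15,
    marker_floor: float = 0.02,
) -> pd.DataFrame:
    """Marker-level longitudinal series for many patients (no count layer).

    The marker tracks the latent tumor fraction up to a multiplicative
    lognormal measurement error plus a small additive floor — the regime in
    which a tumor-fraction-proportional score monitors therapy. Returns a
    timepoint table ready for :func:`cfmeth.monitor.segment_therapy_lines`.
    """
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp("2019-01-01")
    rows = []
    for p in range(n_patients):
        pid = f"P{p:03d}"
        traj = simulate_trajectory(config, rng)
        reached_pd = (traj["radiology"] == "PD").any()
        for j, row in traj.iterrows():
            score = (
                marker_scale
                * float(row["tumor_fraction"])
                * float(np.exp(rng.normal(0.0, noise_sd)))
                + marker_floor * float(rng.uniform())
            )
            rows.append(
                {
                    "sample_id": f"{pid}_t{j:02d}",
                    "patient_id": pid,
                    "date": t0 + pd.Timedelta(days=int(row["day"])),
                    "therapy_line": "L1",
                    "radiology": row["radiology"],
                    "end_reason": "switch" if reached_pd else "censored",
                    "score_5mc": score,
                    "tumor_fraction": float(row["tumor_fraction"]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# copy-number simulation


def simulate_cna_segments(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, int]:
    """Per-chromosome tumor copy number (whole-chromosome events)."""
    segs = {}
    for chrom in config.cna_chrom_sizes:
        u = rng.random()
        if u < config.cna_gain_prob:
            segs[chrom] = 3
        elif u < config.cna_gain_prob + config.cna_loss_prob:
            segs[chrom] = 1
        else:
            segs[chrom] = 2
    return segs


def cna_bin_expectation(
    bins: WindowSet,
    segments: Mapping[str, int],
    f: float,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Expected (unnormalized) fragment mass per bin for tumor fraction f."""
    df = bins.df
    cn = df["chrom"].map(lambda c: segments.get(c, 2)).values.astype(float)
    mass = (df["end"] - df["start"]).values * (2.0 + f * (cn - 2.0))
    if bias is not None:
        mass = mass * bias
    return mass


def simulate_cna_counts(
    bins: WindowSet,
    segments: Mapping[str, int],
    f: float,
    depth: int,
    rng: np.random.Generator,
    bias: np.ndarray | None = None,
) -> pd.Series:
    mass = cna_bin_expectation(bins, segments, f, bias)
    counts = rng.multinomial(depth, mass / mass.sum())
    return pd.Series(counts, index=bins.window_ids, name="count")


@dataclass
class SimulatedCnaCohort:
    bins: WindowSet
    panel_a: pd.DataFrame  # sWGS-like healthy panel counts
    panel_b: pd.DataFrame  # MeDIP-like healthy panel counts
    fragments_a: dict[str, pd.DataFrame]
    fragments_b: dict[str, pd.DataFrame]
    truth: pd.DataFrame  # per sample: tumor_fraction, n_altered_chroms
    platform_bias: np.ndarray


def simulate_cna_cohort(
    config: SimulationConfig,
    n_samples: int,
    seed: int,
    n_panel_a: int = 16,
    n_panel_b: int = 13,
    tumor_fraction_range: tuple[float, float] = (0.05, 0.5),
) -> SimulatedCnaCohort:
    """Paired two-platform CNA cohort sharing one ground truth per sample.

    Platform A is unbiased (sWGS-like); platform B carries a fixed lognormal
    per-bin bias (MeDIP-like capture preference) shared by its healthy panel,
    so panel normalization can cancel it.
    """
    from .cna import make_bins  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    bins = make_bins(config.cna_chrom_sizes, config.cna_bin_size)
    bias = np.exp(rng.normal(0.0, config.cna_bias_sd, size=len(bins)))
    neutral = {c: 2 for c in config.cna_chrom_sizes}
    panel_a = pd.DataFrame(
        {
            f"panelA_{i:02d}": simulate_cna_counts(bins, neutral, 0.0, config.cna_depth, rng)
            for i in range(n_panel_a)
        }
    )
    panel_b = pd.DataFrame(
        {
            f"panelB_{i:02d}": simulate_cna_counts(
                bins, neutral, 0.0, config.cna_depth, rng, bias
            )
            for i in range(n_panel_b)
        }
    )
    frags_a, frags_b, rows = {}, {}, []
    for i in range(n_samples):
        sid = f"s{i:02d}"
        f = float(rng.uniform(*tumor_fraction_range))
        segs = simulate_cna_segments(config, rng)
        counts_a = simulate_cna_counts(bins, segs, f, config.cna_depth, rng)
        counts_b = simulate_cna_counts(bins, segs, f, config.cna_depth, rng, bias)
        frags_a[sid] = counts_to_fragments(counts_a, bins, rng, config.fragment_length)
        frags_b[sid] = counts_to_fragments(counts_b, bins, rng, config.fragment_length)
        rows.append(
            {
                "sample_id": sid,
                "tumor_fraction": f,
                "n_altered_chroms": sum(1 for v in segs.values() if v != 2),
            }
        )
    return SimulatedCnaCohort(
        bins=bins,
        panel_a=panel_a,
        panel_b=panel_b,
        fragments_a=frags_a,
        fragments_b=frags_b,
        truth=pd.DataFrame(rows).set_index("sample_id"),
        platform_bias=bias,
    )
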