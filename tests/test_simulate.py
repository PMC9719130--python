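import numpy as np
import pandas as pd
import pytest

from cfmeth import windows as W
from cfmeth.background import apply_background_mask
from cfmeth.simulate import (
    SimulationConfig,
    counts_to_fragments,
    expected_propensity,
    mixture_methylation,
    simulate_cohort,
    simulate_reference,
    simulate_sample_counts,
    simulate_trajectory,
    simulate_tumor_methylome,
)


class TestReference:
    def test_shapes_and_bounds(self, small_config):
        ws, panel = simulate_reference(small_config, 0)
        assert len(ws) == small_config.n_windows
        assert panel.beta.shape == (len(ws), len(small_config.cell_type_weights))
        assert ((panel.beta.values >= 0) & (panel.beta.values <= 1)).all()
        assert panel.weights.sum() == pytest.approx(1.0)

    def test_seed_determinism(self, small_config):
        ws1, p1 = simulate_reference(small_config, 3)
        ws2, p2 = simulate_reference(small_config, 3)
        pd.testing.assert_frame_equal(ws1.df, ws2.df)
        pd.testing.assert_frame_equal(p1.beta, p2.beta)

    def test_low_background_fraction_matches_configuration(self):
        cfg = SimulationConfig(n_windows=8000, frac_low=0.4, frac_cellspec=0.0)
        _, panel = simulate_reference(cfg, 1)
        frac = (panel.combined() <= 0.15).mean()
        se = np.sqrt(0.4 * 0.6 / 8000)
        assert abs(frac - 0.4) < 4 * se

    def test_cpg_counts_truncated_geometric(self, small_config):
        ws, _ = simulate_reference(small_config, 2)
        assert ws.df["n_cpg"].min() >= 1
        assert ws.df["n_cpg"].mean() == pytest.approx(1 / small_config.cpg_geometric_p, rel=0.1)


class TestTumorMethylome:
    def test_planted_effect_and_identity_elsewhere(self, small_config):
        ws, panel = simulate_reference(small_config, 4)
        tumor, dmrs = simulate_tumor_methylome(ws, panel, small_config, 5)
        combined = panel.combined()
        host = dmrs[0]
        assert tumor[host] == pytest.approx(
            min(1.0, combined[host] + small_config.effect_delta_beta)
        )
        untouched = combined.index.difference(dmrs)
        assert np.allclose(tumor[untouched], combined[untouched])

    def test_all_true_dmrs_in_low_background(self, small_config):
        ws, panel = simulate_reference(small_config, 6)
        _, dmrs = simulate_tumor_methylome(ws, panel, small_config, 7)
        keep = apply_background_mask(panel.combined(), small_config.background_tau)
        assert keep.loc[dmrs].all()

    def test_zero_dmrs_identity(self, small_config):
        cfg = SimulationConfig(**{**small_config.__dict__, "n_true_dmrs": 0})
        ws, panel = simulate_reference(cfg, 8)
        tumor, dmrs = simulate_tumor_methylome(ws, panel, cfg, 9)
        assert dmrs == []
        assert np.allclose(tumor.values, panel.combined().values)


class TestSampleCounts:
    def test_background_only_count_ratios_follow_propensity(self, small_config):
        ws, panel = simulate_reference(small_config, 10)
        bg = panel.combined()
        lam = expected_propensity(bg, ws, small_config)
        rng = np.random.default_rng(11)
        reps = np.stack(
            [
                simulate_sample_counts(bg, ws, small_config, rng).values
                for _ in range(30)
            ]
        )
        mean_counts = reps.mean(axis=0)
        expected = small_config.depth * lam.values / lam.values.sum()
        # compare on well-covered windows; relative error shrinks with pooling
        big = expected > 30
        ratio = mean_counts[big] / expected[big]
        assert abs(np.mean(ratio) - 1.0) < 0.02

    def test_tumor_fraction_raises_dmr_counts(self, small_config):
        ws, panel = simulate_reference(small_config, 12)
        tumor, dmrs = simulate_tumor_methylome(ws, panel, small_config, 13)
        bg = panel.combined()
        rng = np.random.default_rng(14)
        c0 = np.stack(
            [simulate_sample_counts(bg, ws, small_config, rng).loc[dmrs].values for _ in range(10)]
        )
        c1 = np.stack(
            [
                simulate_sample_counts(
                    mixture_methylation(bg, tumor, 1.0), ws, small_config, rng
                ).loc[dmrs].values
                for _ in range(10)
            ]
        )
        assert c1.mean() > 2 * c0.mean()

    def test_poisson_limit_variance_matches_mean(self, small_config):
        cfg = SimulationConfig(**{**small_config.__dict__, "dispersion": 0.0})
        ws, panel = simulate_reference(cfg, 15)
        bg = panel.combined()
        rng = np.random.default_rng(16)
        reps = np.stack(
            [simulate_sample_counts(bg, ws, cfg, rng).values for _ in range(60)]
        )
        mu = reps.mean(axis=0)
        var = reps.var(axis=0, ddof=1)
        big = mu > 20
        # index of dispersion ~ 1 under Poisson
        assert np.mean(var[big] / mu[big]) == pytest.approx(1.0, abs=0.05)

    def test_overdispersion_exceeds_poisson(self, small_config):
        ws, panel = simulate_reference(small_config, 17)
        bg = panel.combined()
        rng = np.random.default_rng(18)
        reps = np.stack(
            [simulate_sample_counts(bg, ws, small_config, rng).values for _ in range(40)]
        )
        mu = reps.mean(axis=0)
        var = reps.var(axis=0, ddof=1)
        big = mu > 20
        assert np.mean(var[big] / mu[big]) > 1.5

    def test_mixture_fraction_bounds(self):
        with pytest.raises(ValueError):
            mixture_methylation(pd.Series([0.1]), pd.Series([0.2]), 1.5)


class TestTrajectoriesAndCohort:
    def test_trajectory_shape_and_pd_labeling(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(19)
        for _ in range(20):
            traj = simulate_trajectory(cfg, rng)
            assert (traj["tumor_fraction"] >= 0).all()
            pd_rows = traj[traj["radiology"] == "PD"]
            if not pd_rows.empty:
                assert pd_rows.index[-1] == traj.index[-1]  # PD ends the line
                assert pd_rows["tumor_fraction"].iloc[0] >= cfg.pd_fraction
                # regrowth onset precedes the radiologic PD label by construction
                assert traj.attrs["onset_day"] < pd_rows["day"].iloc[0]

    def test_cohort_shapes_and_sheets(self, small_config):
        cohort = simulate_cohort(small_config, 20)
        cfg = small_config
        n_disc = cfg.n_cases + cfg.n_controls + cfg.n_tumor_tissues + cfg.n_normal_tissues
        assert cohort.counts.values.shape == (cfg.n_windows, n_disc)
        assert set(cohort.sample_sheet["group"]) == {
            "case",
            "control",
            "tumor_tissue",
            "normal_tissue",
        }
        sheet = cohort.longitudinal_sheet
        assert sheet["patient_id"].nunique() == cfg.n_longitudinal
        assert set(sheet["radiology"]) <= {"SD", "PD"}
        controls = cohort.sample_sheet.query("group == 'control'")["tumor_fraction"]
        assert (controls == 0).all()

    def test_cohort_determinism(self, small_config):
        a = simulate_cohort(small_config, 21)
        b = simulate_cohort(small_config, 21)
        pd.testing.assert_frame_equal(a.counts.values, b.counts.values)
        pd.testing.assert_frame_equal(a.longitudinal_sheet, b.longitudinal_sheet)
        assert a.truth["true_dmrs"] == b.truth["true_dmrs"]

    def test_emitted_files_roundtrip_through_readers(self, small_config, tmp_path):
        import warnings

        cohort = simulate_cohort(small_config, 22)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            cohort.write(tmp_path)
            ws = W.read_windows(tmp_path / "windows.bed")
            cm = W.CountMatrix.read(tmp_path / "counts.tsv", tmp_path / "counts.json")
            beta = pd.read_csv(tmp_path / "beta_panel.tsv", sep="\t", index_col="window_id")
        pd.testing.assert_frame_equal(ws.df, cohort.window_set.df)
        pd.testing.assert_frame_equal(cm.values, cohort.counts.values)
        assert beta.shape == cohort.panel.beta.shape

    def test_fragment_emission_midpoints_inside_windows(self, small_config):
        ws, panel = simulate_reference(small_config, 23)
        rng = np.random.default_rng(24)
        counts = simulate_sample_counts(panel.combined(), ws, small_config, rng, depth=5000)
        frags = counts_to_fragments(counts, ws, rng)
        assert len(frags) == counts.sum()
        res = W.count_fragments(frags, ws)
        pd.testing.assert_series_equal(res.counts, counts, check_names=False)


def test_dose_response_recall_grid():
    """DMR recall grows with both effect size and depth (3x3 grid, light)."""
    from cfmeth.pipeline import run_discovery

    recalls = np.zeros((3, 3))
    for i, effect in enumerate([0.1, 0.3, 0.6]):
        for j, depth in enumerate([20_000, 60_000, 200_000]):
            cfg = SimulationConfig(
                n_windows=2000,
                n_true_dmrs=40,
                n_confounders=0,
                effect_delta_beta=effect,
                depth=depth,
                n_longitudinal=0,
                n_tumor_tissues=2,
                n_normal_tissues=2,
            )
            cohort = simulate_cohort(cfg, 100 + i * 3 + j)
            disc = run_discovery(cohort, n_perm=10, seed=0)
            truth = set(cohort.truth["true_dmrs"])
            recalls[i, j] = len(disc.cf_dmrs.hyper & truth) / len(truth)
    # monotone on average along both axes
    assert recalls[2, 2] > recalls[0, 0]
    assert (np.diff(recalls.mean(axis=0)) >= -0.05).all()
    assert (np.diff(recalls.mean(axis=1)) >= -0.05).all()
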