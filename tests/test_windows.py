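import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cfmeth.windows import (
    CountMatrix,
    WindowSet,
    WindowValidationError,
    build_count_matrix,
    compute_rpkm,
    count_fragments,
    downsample_fragments,
    filter_windows,
    read_fragments,
    read_windows,
)


def frag(chrom, start, end):
    return pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]})


class TestReadAndValidate:
    def test_roundtrip_three_disjoint_windows(self, tmp_path, toy_windows):
        path = tmp_path / "w.bed"
        toy_windows.to_bed(path)
        back = read_windows(path)
        assert len(back) == 4
        pd.testing.assert_frame_equal(back.df, toy_windows.df)

    def test_overlapping_windows_rejected(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [0, 400],
                "end": [500, 900],
                "window_id": ["a", "b"],
                "n_cpg": [3, 3],
            }
        )
        with pytest.raises(WindowValidationError, match="overlap"):
            WindowSet(df)

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1", "chr2"],
                "start": [0, 0],
                "end": [10, 10],
                "window_id": ["a", "a"],
                "n_cpg": [3, 3],
            }
        )
        with pytest.raises(WindowValidationError, match="duplicate"):
            WindowSet(df)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "empty.bed"
        path.write_text("")
        with pytest.warns(UserWarning, match="no windows"):
            ws = read_windows(path)
        assert len(ws) == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t100\tw1\t3\nchr1\tnope\t200\tw2\t3\n")
        with pytest.raises(ValueError, match=":2:"):
            read_windows(path)


class TestFilterWindows:
    @pytest.mark.parametrize(
        "window_id, retained",
        [
            ("w1", True),  # n_cpg 5 on chr1
            ("w2", True),  # boundary: n_cpg exactly 3
            ("w4", False),  # n_cpg 2 below the CpG floor
        ],
    )
    def test_cpg_floor(self, toy_windows, window_id, retained):
        out = filter_windows(toy_windows, min_cpg=3, excluded_chroms=set())
        assert (window_id in set(out.df["window_id"])) is retained

    def test_sex_chromosome_exclusion(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1", "chrX", "chrY", "chrM"],
                "start": [0, 0, 0, 0],
                "end": [100, 100, 100, 100],
                "window_id": ["a", "x", "y", "m"],
                "n_cpg": [5, 5, 5, 5],
            }
        )
        out = filter_windows(WindowSet(df))
        assert set(out.df["window_id"]) == {"a"}


class TestCounting:
    def test_fragment_inside_window(self, toy_windows):
        res = count_fragments(frag("chr1", 100, 250), toy_windows)
        assert res.counts["w1"] == 1 and res.library_size == 1

    def test_boundary_spanning_fragment_goes_to_midpoint_window(self, toy_windows):
        # [480, 560) has midpoint 520, inside [500, 1000)
        res = count_fragments(frag("chr1", 480, 560), toy_windows)
        assert res.counts["w1"] == 0 and res.counts["w2"] == 1

    def test_no_fragments(self, toy_windows):
        res = count_fragments(pd.DataFrame(columns=["chrom", "start", "end"]), toy_windows)
        assert res.library_size == 0 and (res.counts == 0).all()

    def test_unknown_chromosome_skipped_and_tallied(self, toy_windows):
        res = count_fragments(frag("chr9", 0, 100), toy_windows)
        assert res.library_size == 0 and res.n_unknown_chrom == 1

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=1, max_value=400))
    def test_conservation_no_double_counting(self, start, length):
        """Counts + unassigned + unknown-chrom always equals the input size."""
        ws = WindowSet(
            pd.DataFrame(
                {
                    "chrom": ["chr1", "chr1", "chr1", "chr2"],
                    "start": [0, 500, 1000, 0],
                    "end": [500, 1000, 2000, 800],
                    "window_id": ["w1", "w2", "w3", "w4"],
                    "n_cpg": [5, 3, 8, 2],
                }
            )
        )
        rng = np.random.default_rng(start * 1000 + length)
        n = 50
        frags = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2", "chr7"], size=n),
                "start": rng.integers(start, start + 3000, size=n),
            }
        )
        frags["end"] = frags["start"] + length
        res = count_fragments(frags, ws)
        assert res.counts.sum() == res.library_size
        assert res.library_size + res.n_unassigned + res.n_unknown_chrom == n


class TestRpkm:
    def test_hand_value(self):
        ws = WindowSet(
            pd.DataFrame(
                {
                    "chrom": ["chr1"],
                    "start": [0],
                    "end": [500],
                    "window_id": ["w"],
                    "n_cpg": [3],
                }
            )
        )
        cm = CountMatrix(
            pd.DataFrame({"s": [10]}, index=["w"]), pd.Series({"s": 1_000_000})
        )
        assert compute_rpkm(cm, ws).loc["w", "s"] == pytest.approx(20.0)

    def test_zero_count_gives_zero(self, toy_windows):
        cm = CountMatrix(
            pd.DataFrame({"s": [0, 4, 0, 1]}, index=toy_windows.window_ids),
            pd.Series({"s": 100}),
        )
        rpkm = compute_rpkm(cm, toy_windows)
        assert rpkm.loc["w1", "s"] == 0.0 and rpkm.loc["w3", "s"] == 0.0

    def test_scale_invariance(self, toy_windows):
        counts = pd.DataFrame({"s": [3, 4, 5, 6]}, index=toy_windows.window_ids)
        a = compute_rpkm(CountMatrix(counts, pd.Series({"s": 1000})), toy_windows)
        b = compute_rpkm(CountMatrix(counts * 7, pd.Series({"s": 7000})), toy_windows)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_library_raises_with_sample_name(self, toy_windows):
        cm = CountMatrix(
            pd.DataFrame({"bad": [0, 0, 0, 0]}, index=toy_windows.window_ids),
            pd.Series({"bad": 0}),
        )
        with pytest.raises(ValueError, match="bad"):
            compute_rpkm(cm, toy_windows)


class TestDownsample:
    def test_target_at_or_above_n_keeps_all(self):
        frags = pd.DataFrame({"chrom": ["chr1"] * 100, "start": range(100), "end": range(1, 101)})
        assert len(downsample_fragments(frags, 100, 0)) == 100
        assert len(downsample_fragments(frags, 1000, 0)) == 100

    def test_fixed_seed_reproducible(self):
        frags = pd.DataFrame(
            {"chrom": ["chr1"] * 1000, "start": range(1000), "end": range(1, 1001)}
        )
        a = downsample_fragments(frags, 100, 7)
        b = downsample_fragments(frags, 100, 7)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 100

    def test_uniformity_across_strata(self):
        """Mean retained fraction per chromosome ~ target fraction (binomial CI)."""
        rng = np.random.default_rng(0)
        frags = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], size=1000),
                "start": np.arange(1000),
                "end": np.arange(1, 1001),
            }
        )
        fractions = []
        for seed in range(40):
            sub = downsample_fragments(frags, 100, seed)
            fractions.append((sub["chrom"] == "chr1").sum() / (frags["chrom"] == "chr1").sum())
        # per-draw SE ~ sqrt(0.1*0.9/500); mean over 40 seeds shrinks by sqrt(40)
        se = np.sqrt(0.1 * 0.9 / 500) / np.sqrt(40)
        assert abs(np.mean(fractions) - 0.1) < 3 * se


def test_fragment_reader_and_matrix_roundtrip(tmp_path, toy_windows):
    path = tmp_path / "frags.bed"
    path.write_text("chr1\t10\t150\nchr1\t700\t820\nchr2\t100\t260\n")
    frags = read_fragments(path, sample_id="s1")
    cm = build_count_matrix({"s1": frags}, toy_windows)
    assert cm.library_size["s1"] == 3
    cm.write(tmp_path / "c.tsv", tmp_path / "c.json")
    back = CountMatrix.read(tmp_path / "c.tsv", tmp_path / "c.json")
    pd.testing.assert_frame_equal(back.values, cm.values)
    pd.testing.assert_series_equal(back.library_size, cm.library_size)
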