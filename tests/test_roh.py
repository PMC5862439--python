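import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rohselect.io import ChromSizes, MISSING
from rohselect.roh import (
    ROHCallParams,
    call_roh,
    compute_froh,
    filter_autozygous,
    froh_group_comparison,
    froh_resampling,
    threshold_profile,
)

from conftest import brute_force_roh, make_genotypes, random_track


def segs_of(df):
    return [(r.start, r.end, r.n_snps) for r in df.itertuples()]


class TestCallROH:
    def test_het_breaks_run(self):
        # hom at 100..400 kb, het at 500, hom at 600..900 (kb): two segments
        pos = np.arange(1, 10) * 100_000
        dos = np.array([[0, 2, 0, 2, 1, 0, 0, 2, 2]], np.int8)
        gm = make_genotypes(dos, positions=pos)
        out = call_roh(gm, ROHCallParams(min_snps=3, max_missing_in_run=0))
        assert segs_of(out) == [(100_000, 400_000, 4), (600_000, 900_000, 4)]

    def test_all_het_no_segments(self):
        gm = make_genotypes(np.ones((1, 30), np.int8))
        assert call_roh(gm, ROHCallParams(min_snps=1)).empty

    def test_gap_breaks_run(self):
        pos = np.array([100_000, 200_000, 800_000, 900_000])
        gm = make_genotypes(np.zeros((1, 4), np.int8), positions=pos)
        out = call_roh(gm, ROHCallParams(min_snps=2, max_gap=500_000))
        assert segs_of(out) == [(100_000, 200_000, 2), (800_000, 900_000, 2)]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            make_genotypes(np.zeros((1, 3), np.int8), positions=[5, 2, 9])

    def test_matches_brute_force_on_random_tracks(self, rng):
        """The production caller must agree exactly with the O(n^2) maximal-run
        enumerator across random tracks and random parameters."""
        for _ in range(200):
            pos, dos = random_track(rng)
            params = ROHCallParams(
                min_snps=int(rng.integers(1, 8)),
                max_het_in_run=int(rng.integers(0, 3)),
                max_missing_in_run=int(rng.integers(0, 4)),
                max_gap=int(rng.choice([150_000, 400_000, 600_000])),
            )
            gm = make_genotypes(dos.reshape(1, -1), positions=pos)
            assert segs_of(call_roh(gm, params)) == brute_force_roh(pos, dos, params), (
                pos.tolist(),
                dos.tolist(),
                params,
            )


class TestLengthFilter:
    def test_shorter_than_threshold_dropped(self):
        seg = pd.DataFrame(
            {"sample_id": "a", "chrom": "1", "start": [1, 1], "end": [400_000, 600_000],
             "n_snps": 20, "length": [400_000, 600_000]}
        )
        out = filter_autozygous(seg, 500_000)
        assert out["length"].tolist() == [600_000]

    def test_exact_boundary_retained(self):
        seg = pd.DataFrame(
            {"sample_id": ["a"], "chrom": ["1"], "start": [1], "end": [500_000],
             "n_snps": [20], "length": [500_000]}
        )
        assert len(filter_autozygous(seg, 500_000)) == 1

    def test_empty_input(self):
        assert filter_autozygous(pd.DataFrame(columns=["length"]), 500_000).empty


class TestThresholdProfile:
    def test_counts_and_carrier_frequency(self):
        seg = pd.DataFrame(
            {"sample_id": ["A", "A", "B"], "chrom": "1", "start": 1,
             "end": [600_000, 700_000, 300_000], "n_snps": 20,
             "length": [600_000, 700_000, 300_000]}
        )
        prof = threshold_profile(seg, ["A", "B"], [500_000])
        row = prof.iloc[0]
        assert row["mean_count"] == 1.0  # A has 2, B has 0
        assert row["carrier_freq"] == 0.5

    def test_zero_threshold_counts_everything(self):
        seg = pd.DataFrame(
            {"sample_id": ["A"], "chrom": "1", "start": [1], "end": [100], "n_snps": [5],
             "length": [100]}
        )
        prof = threshold_profile(seg, ["A", "B"], [0])
        assert prof.iloc[0]["carrier_freq"] == 0.5

    def test_above_longest_gives_zero(self):
        seg = pd.DataFrame(
            {"sample_id": ["A"], "chrom": "1", "start": [1], "end": [100], "n_snps": [5],
             "length": [100]}
        )
        prof = threshold_profile(seg, ["A"], [1_000_000])
        assert prof.iloc[0]["mean_count"] == 0.0 and prof.iloc[0]["carrier_freq"] == 0.0

    def test_carrier_frequency_monotone_in_threshold(self, rng):
        rows = []
        for s in range(8):
            for _ in range(int(rng.integers(0, 6))):
                ln = int(rng.integers(50_000, 2_000_000))
                rows.append((f"s{s}", "1", 1, ln, 10, ln))
        seg = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "n_snps", "length"])
        prof = threshold_profile(seg, [f"s{i}" for i in range(8)])
        assert (np.diff(prof["carrier_freq"]) <= 1e-12).all()

    def test_empty_threshold_list_rejected(self):
        with pytest.raises(ValueError):
            threshold_profile(pd.DataFrame(), ["a"], [])


class TestFroh:
    sizes = ChromSizes({"1": 2_000_000, "2": 512_000})

    def test_no_segments_zero(self):
        out = compute_froh(pd.DataFrame(columns=["sample_id", "chrom", "start", "end"]),
                           self.sizes, ["a"])
        assert out["f_roh"].tolist() == [0.0]

    def test_simple_ratio(self):
        sizes = ChromSizes({"1": 2_512_000_000})
        seg = pd.DataFrame({"sample_id": ["a"], "chrom": ["1"], "start": [1],
                            "end": [25_120_000]})
        out = compute_froh(seg, sizes, ["a"])
        assert out["f_roh"].iloc[0] == pytest.approx(0.01)

    def test_unknown_chromosome_rejected(self):
        seg = pd.DataFrame({"sample_id": ["a"], "chrom": ["99"], "start": [1], "end": [10]})
        with pytest.raises(ValueError):
            compute_froh(seg, self.sizes, ["a"])

    def test_matches_per_base_coverage_marking(self, rng):
        """Merged-interval arithmetic must equal literally painting every
        covered base of a small genome."""
        sizes = ChromSizes({"1": 5_000, "2": 3_000})
        for _ in range(20):
            rows = []
            for _ in range(int(rng.integers(1, 10))):
                chrom = str(rng.choice(["1", "2"]))
                s = int(rng.integers(1, sizes[chrom] - 10))
                e = int(rng.integers(s, min(s + 2_000, sizes[chrom])))
                rows.append(("x", chrom, s, e))
            seg = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end"])
            out = compute_froh(seg, sizes, ["x"])
            marked = 0
            for chrom in ("1", "2"):
                cov = np.zeros(sizes[chrom] + 1, bool)
                for r in seg[seg["chrom"] == chrom].itertuples():
                    cov[r.start : r.end + 1] = True
                marked += int(cov.sum())
            assert out["total_roh_bp"].iloc[0] == marked


class TestGroupComparison:
    def test_identical_groups_p_maximal(self):
        vals = pd.DataFrame({"f_roh": [0.1, 0.2, 0.3]})
        res = froh_group_comparison(vals, vals)
        assert res["p_value"] > 0.9

    def test_separated_groups_exact_permutation(self):
        """5 vs 5 with complete separation: p must equal the exhaustive
        permutation value 2*1/C(10,5)."""
        from itertools import combinations

        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
        res = froh_group_comparison(pd.DataFrame({"f_roh": b}), pd.DataFrame({"f_roh": a}))
        pooled = np.concatenate([a, b])
        obs = b.sum()
        count = 0
        total = 0
        for comb in combinations(range(10), 5):
            s = pooled[list(comb)].sum()
            if abs(s - pooled.sum() / 2) >= abs(obs - pooled.sum() / 2) - 1e-12:
                count += 1
            total += 1
        assert res["p_value"] == pytest.approx(count / total)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            froh_group_comparison(pd.DataFrame({"f_roh": []}), pd.DataFrame({"f_roh": [1.0]}))


class TestResampling:
    def test_k_equals_group_size_degenerate(self):
        sel = pd.DataFrame({"f_roh": [0.1, 0.2, 0.3]})
        uns = pd.DataFrame({"f_roh": [0.0, 0.05]})
        out = froh_resampling(sel, uns, k=3, reps=10, seed=1)
        assert np.allclose(out["mean_froh"], 0.2)

    def test_exhaustive_enumeration_of_subset_means(self):
        from itertools import combinations

        vals = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        sel = pd.DataFrame({"f_roh": vals})
        uns = pd.DataFrame({"f_roh": [0.0, 0.01]})
        out = froh_resampling(sel, uns, k=3, reps=4000, seed=2)
        expected = sorted(round(np.mean(c), 10) for c in combinations(vals, 3))
        observed = sorted(set(round(v, 10) for v in out["mean_froh"]))
        assert observed == sorted(set(expected))

    def test_deterministic_under_seed(self):
        sel = pd.DataFrame({"f_roh": np.linspace(0, 1, 20)})
        uns = pd.DataFrame({"f_roh": [0.0, 0.1]})
        a = froh_resampling(sel, uns, k=5, reps=50, seed=7)
        b = froh_resampling(sel, uns, k=5, reps=50, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            froh_resampling(pd.DataFrame({"f_roh": [0.1]}), pd.DataFrame({"f_roh": [0.2]}), k=5)
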