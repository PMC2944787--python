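import numpy as np
import pandas as pd
import pytest

from capmap.intervals import GenomeInterval
from capmap.methylation import (
    DmParams,
    consensus_tumour_calls,
    conservation_table,
    dm_matrix,
    dm_score,
    window_means,
)
from capmap.track_io import DepthTrack

P = DmParams()


def track(values, chrom="c"):
    return DepthTrack({chrom: np.asarray(values, dtype=float)})


def iv(start, end, chrom="c", name=None):
    return GenomeInterval(chrom, start, end, name=name)


class TestWindowMeans:
    def test_constant_depth(self):
        means = window_means(track(np.full(300, 2.5)), iv(0, 300), P)
        assert np.allclose(means, 2.5)

    def test_window_count_formula(self):
        assert len(window_means(track(np.zeros(400)), iv(0, 300), P)) == (300 - 100) // 20 + 1

    def test_half_filled_window(self):
        depth = np.zeros(100)
        depth[:50] = 10
        assert window_means(track(depth), iv(0, 100), P)[0] == 5.0

    def test_interval_shorter_than_window_empty(self):
        assert len(window_means(track(np.zeros(400)), iv(0, 80), P)) == 0


class TestDmScore:
    def test_identical_series_scores_zero(self):
        s = np.linspace(0, 5, 15)
        call = dm_score(s, s)
        assert call.score == 0 and call.evaluable

    def test_low_coverage_windows_forced_to_unity(self):
        # both window totals below 4 reads: ratio fixed at 1, no call
        ref = np.full(15, 0.03)  # window total 3
        test = np.full(15, 0.02)  # window total 2
        assert dm_score(ref, test).score == 0

    def test_eleven_window_gain_example(self):
        ref = np.full(11, 1.0)  # totals 100
        test = np.full(11, 5.0)  # totals 500
        # ratio (500+1)/(100+1) = 4.9604, log2 = 2.31 > 2 in all windows
        assert dm_score(ref, test).score == 1
        assert dm_score(test, ref).score == -1

    def test_k_of_m_frame_rule(self):
        ref = np.full(14, 1.0)
        test = np.full(14, 5.0)
        # knock out windows so that no 10-window frame holds 9 exceedances
        test_sparse = test.copy()
        test_sparse[[2, 7, 12]] = 1.0
        assert dm_score(ref, test_sparse).score == 0
        # a single interior failure still leaves a 9-of-10 frame
        test_one = test.copy()
        test_one[5] = 1.0
        assert dm_score(ref, test_one).score == 1

    def test_short_cgi_not_evaluable(self):
        call = dm_score(np.full(6, 1.0), np.full(6, 5.0))
        assert call.score == 0 and not call.evaluable
        prop = dm_score(np.full(6, 1.0), np.full(6, 5.0), DmParams(proportional_rule=True))
        assert prop.score == 1 and prop.evaluable

    def test_antisymmetry(self, rng):
        for _ in range(100):
            a = rng.poisson(rng.uniform(0, 6), 12).astype(float)
            b = rng.poisson(rng.uniform(0, 6), 12).astype(float)
            assert dm_score(a, b).score == -dm_score(b, a).score

    def test_scale_invariance_above_floor(self, rng):
        ref = rng.uniform(0.5, 2.0, 12)
        test = ref * 8  # clear gain everywhere, totals far above floor
        base = dm_score(ref, test).score
        scaled = dm_score(ref * 10, test * 10).score
        assert base == scaled == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dm_score(np.zeros(10), np.zeros(11))

    def test_params_validation(self):
        with pytest.raises(ValueError):
            DmParams(window=20, slide=20)
        with pytest.raises(ValueError):
            DmParams(k=11, m=10)


class TestDmMatrix:
    def test_single_cgi_single_sample(self):
        ref = track(np.full(400, 1.0))
        test = track(np.full(400, 8.0))
        table = dm_matrix([iv(0, 300, name="cgi1")], ref, {"s": test})
        assert table.loc["cgi1", "s"] == 1

    def test_zero_test_track_with_covered_reference(self):
        ref = track(np.full(400, 2.0))  # window totals 200 >= floor
        table = dm_matrix([iv(0, 300)], ref, {"s": track(np.zeros(400))})
        assert table.iloc[0, 0] == -1

    def test_missing_chromosome_reported_missing(self, caplog):
        ref = track(np.full(400, 1.0))
        with caplog.at_level("WARNING"):
            table = dm_matrix([iv(0, 300, chrom="other")], ref, {"s": ref})
        assert table.isna().all().all()


class TestConsensus:
    def make_table(self, tumour_pos, normal_pos, n=5):
        cols = [f"T{i}" for i in range(n)] + [f"C{i}" for i in range(n)]
        row = [1 if i < tumour_pos else 0 for i in range(n)]
        row += [1 if i < normal_pos else 0 for i in range(n)]
        return pd.DataFrame([row], index=["cgi"], columns=cols), cols[:n], cols[n:]

    def test_three_of_five_tumours_no_normals(self):
        table, tum, nor = self.make_table(3, 0)
        assert consensus_tumour_calls(table, tum, nor)["tumour_specific"] == ["cgi"]

    def test_normal_methylation_disqualifies(self):
        table, tum, nor = self.make_table(5, 2)
        calls = consensus_tumour_calls(table, tum, nor)
        assert calls["tumour_specific"] == []
        assert calls["shared"] == ["cgi"]

    def test_all_zero_table_empty(self):
        table, tum, nor = self.make_table(0, 0)
        calls = consensus_tumour_calls(table, tum, nor)
        assert all(v == [] for v in calls.values())

    def test_subsets_disjoint(self, rng):
        cols = [f"T{i}" for i in range(5)] + [f"C{i}" for i in range(5)]
        table = pd.DataFrame(rng.choice([-1, 0, 1], size=(50, 10)), columns=cols)
        calls = consensus_tumour_calls(table, cols[:5], cols[5:])
        sets = [set(v) for v in calls.values()]
        assert sets[0] & sets[1] == set() and sets[0] & sets[2] == set() and sets[1] & sets[2] == set()

    def test_unknown_sample_rejected(self):
        table, tum, nor = self.make_table(3, 0)
        with pytest.raises(KeyError):
            consensus_tumour_calls(table, tum + ["nope"], nor)


class TestConservation:
    def test_fully_conserved_and_half_conserved(self):
        pairs = [(f"h{i}", f"m{i}") for i in range(10)]
        calls_a = {f"h{i}": 1 for i in range(10)}
        classes = {f"h{i}": "Intragenic" for i in range(10)}
        tab = conservation_table(pairs, calls_a, {f"m{i}": 1 for i in range(10)}, classes)
        assert tab.set_index("class").loc["Intragenic", "pct_conserved"] == 100.0
        calls_b = {f"m{i}": 1 if i < 5 else 0 for i in range(10)}
        tab = conservation_table(pairs, calls_a, calls_b, classes)
        assert tab.set_index("class").loc["Intragenic", "pct_conserved"] == 50.0

    def test_intergenic_excluded_by_default(self):
        pairs = [("h0", "m0")]
        tab = conservation_table(pairs, {"h0": 1}, {"m0": 1}, {"h0": "Intergenic"})
        assert len(tab) == 0

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError, match="h1"):
            conservation_table([("h1", "m1")], {"h0": 1}, {"m1": 1}, {})

    def test_empty_pairs_warns(self, caplog):
        with caplog.at_level("WARNING"):
            tab = conservation_table([], {}, {}, {})
        assert len(tab) == 0
        assert any("empty" in r.message for r in caplog.records)
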