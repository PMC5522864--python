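import numpy as np
import pandas as pd
import pytest

import zygopeak as z
from zygopeak.errors import (DegenerateInputError, StateError, ValidationError)

from conftest import run_calls_on_population


def presence_matrix(markers_present, panel=z.DEFAULT_PANEL):
    row = {m: (500.0 if m in markers_present else np.nan)
           for m in panel.all_markers}
    return pd.DataFrame([row], index=["S1"])


class TestCallPresence:
    @pytest.mark.parametrize("present, expected", [
        (("35S_S", "OCS_S", "NPTII-3", "GhUBC1"), "transgenic"),
        (("GhUBC1",), "null"),
        (("35S_S", "OCS_S", "NPTII-3"), "missing"),          # reference failed
        (("GhUBC1", "35S_S", "OCS_S"), "missing"),           # partial transgene
        ((), "missing"),
    ])
    def test_presence_rule(self, present, expected):
        status = z.call_presence(presence_matrix(present), z.DEFAULT_PANEL)
        assert status["S1"] == expected


class TestFindPit:
    def test_mixture_gives_pit_between_modes(self):
        rng = np.random.default_rng(42)
        values = np.concatenate([rng.normal(406, 50, 150), rng.normal(785, 80, 75)])
        split = z.find_pit(values)
        assert split.is_bimodal
        assert 500 < split.pit_location < 700
        m1, m2 = split.mode_locations
        assert m1 < split.pit_location < m2
        assert split.pit_density <= min(split.mode_densities)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
    def test_single_normal_not_bimodal(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(800, 90, 125)
        assert not z.find_pit(values).is_bimodal

    def test_point_masses_bracket_pit(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([400 + rng.normal(0, 1e-3, 15),
                                 800 + rng.normal(0, 1e-3, 15)])
        split = z.find_pit(values)
        assert split.is_bimodal
        assert 400 < split.pit_location < 800

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            z.find_pit(np.arange(10.0))

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            z.find_pit(np.full(30, 5.0))


class TestSplitByPit:
    def _split(self, pit):
        return z.BimodalSplit(mode_locations=(400.0, 800.0),
                              mode_densities=(1.0, 0.5), pit_location=pit,
                              pit_density=0.1, bandwidth=30.0, is_bimodal=True)

    def test_above_and_below(self):
        labels = z.split_by_pit([300.0, 900.0], self._split(600.0))
        assert list(labels) == ["AB", "AA"]

    def test_value_at_pit_goes_to_hemizygous(self):
        assert z.split_by_pit([600.0], self._split(600.0))[0] == "AB"

    def test_degenerate_all_on_one_side(self):
        labels = z.split_by_pit([700.0, 800.0, 900.0], self._split(600.0))
        assert set(labels) == {"AA"}

    def test_non_bimodal_split_rejected(self):
        bad = z.BimodalSplit(None, None, None, None, 30.0, False)
        with pytest.raises(StateError):
            z.split_by_pit([1.0, 2.0], bad)


class TestKMeans1D:
    def test_two_tight_pairs(self):
        res = z.kmeans_1d([1, 2, 9, 10])
        assert res.centroids == (1.5, 9.5)
        assert res.within_ss == pytest.approx(1.0)
        assert res.n_per_cluster == (2, 2)

    def test_two_triples_r_squared(self):
        res = z.kmeans_1d([1, 2, 3, 10, 11, 12])
        assert res.centroids == (2.0, 11.0)
        assert res.within_ss == pytest.approx(4.0)
        assert res.total_ss == pytest.approx(125.5)
        assert res.r_squared == pytest.approx(1 - 4 / 125.5)

    def test_larger_centroid_is_homozygous(self):
        res = z.kmeans_1d([400.0, 420.0, 810.0, 790.0])
        high = np.asarray([400.0, 420.0, 810.0, 790.0]) > 600
        assert list(res.assignments[high]) == ["AA", "AA"]
        assert list(res.assignments[~high]) == ["AB", "AB"]

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateInputError):
            z.kmeans_1d([5.0, 5.0, 5.0])

    def test_matches_exhaustive_partition_enumeration(self):
        """Independent oracle: best WSS over all 2^n - 2 binary assignments."""
        rng = np.random.default_rng(123)
        for _ in range(40):
            n = rng.integers(3, 11)
            vals = rng.normal(0, 1, n).round(3)
            if np.ptp(vals) == 0:
                continue
            best = np.inf
            for mask in range(1, 2 ** n - 1):
                sel = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
                a, b = vals[sel], vals[~sel]
                wss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
                best = min(best, wss)
            assert z.kmeans_1d(vals).within_ss == pytest.approx(best)

    def test_lloyd_agrees_with_exhaustive_optimum(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            vals = np.concatenate([rng.normal(400, 50, 30), rng.normal(800, 60, 20)])
            exact = z.kmeans_1d(vals)
            lloyd = z.lloyd_kmeans_1d(vals)
            assert lloyd.within_ss == pytest.approx(exact.within_ss)
            assert list(lloyd.assignments) == list(exact.assignments)

    def test_agrees_with_sklearn(self):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(406, 50, 100), rng.normal(785, 80, 60)])
        km = sklearn_cluster.KMeans(n_clusters=2, n_init=10, random_state=0).fit(
            vals.reshape(-1, 1))
        assert z.kmeans_1d(vals).within_ss == pytest.approx(km.inertia_, rel=1e-9)


class TestCCC:
    def _result(self, r2):
        return z.KMeansResult(assignments=np.array(["AB"] * 50 + ["AA"] * 50),
                              centroids=(0.0, 1.0), n_per_cluster=(50, 50),
                              within_ss=1 - r2, total_ss=1.0, r_squared=r2)

    def test_zero_at_null_expectation(self):
        e = z.expected_r_squared(100)
        assert z.compute_ccc(self._result(e), n=100) == pytest.approx(0.0, abs=1e-12)

    def test_negative_below_expectation(self):
        e = z.expected_r_squared(100)
        assert z.compute_ccc(self._result(e - 0.1), n=100) < 0

    def test_positive_above_expectation(self):
        e = z.expected_r_squared(100)
        assert z.compute_ccc(self._result(e + 0.1), n=100) > 0

    def test_separated_clusters_exceed_threshold(self):
        rng = np.random.default_rng(17)
        vals = np.concatenate([rng.normal(406, 50, 113), rng.normal(785, 50, 57)])
        res = z.kmeans_1d(vals)
        assert z.compute_ccc(res, n=vals.size) >= 2.0

    def test_perfect_fit_is_infinite_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isinf(z.compute_ccc(self._result(1.0), n=100))

    def test_expectation_approaches_three_quarters(self):
        assert z.expected_r_squared(10 ** 6) == pytest.approx(0.75, abs=1e-4)


class TestTukeyKramer:
    def test_well_separated_triples(self):
        res = z.tukey_kramer([1, 2, 3], [11, 12, 13])
        assert res.q_statistic == pytest.approx(10 * np.sqrt(3), rel=1e-6)  # 17.32
        assert res.df == 4
        assert res.p_value < 0.001
        assert res.significant

    def test_identical_groups_not_significant(self):
        res = z.tukey_kramer([5, 6], [5, 6])
        assert res.q_statistic == 0
        assert not res.significant

    def test_unequal_group_sizes_use_kramer_se(self):
        a, b = [1.0, 2.0], [1.0, 2.0, 3.0, 4.0]
        res = z.tukey_kramer(a, b)
        msw = (0.5 + 5.0) / 4
        expected_q = 1.0 / np.sqrt((msw / 2) * (1 / 2 + 1 / 4))
        assert res.q_statistic == pytest.approx(expected_q)

    def test_p_matches_studentized_range(self):
        from scipy.stats import studentized_range
        res = z.tukey_kramer([1, 2, 3, 4], [8, 9, 10, 12])
        assert res.p_value == pytest.approx(
            studentized_range.sf(res.q_statistic, 2, res.df), rel=1e-6)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            z.tukey_kramer([5, 5], [7, 7])


class TestCallZygosity:
    def test_simulated_population_recovery(self, simulated_calls):
        calls, merged = simulated_calls
        tg = merged[merged["presence"] == "transgenic"]
        assert (tg["final_call"] == tg["genotype"]).mean() >= 0.95
        pstat = calls.population_stats["pop1"]
        assert pstat.ccc >= 2.0
        assert pstat.split.is_bimodal
        assert pstat.hsd.significant

    def test_homozygous_line_not_forced_into_two_classes(self):
        """A uniformly homozygous line shows a unimodal distribution: the pit
        method must not produce AB calls."""
        table, truth = z.simulate_population(125, (1, 0, 0), seed=21)
        calls, merged = run_calls_on_population(
            table, truth, z.CallConfig(method="pit"))
        pstat = calls.population_stats["pop1"]
        assert not pstat.split.is_bimodal
        assert "not_bimodal" in pstat.flags
        assert calls.calls["pit_call"].isna().all()
        assert (calls.calls["final_call"] != "hemizygous").all()

    def test_homozygous_line_kmeans_ccc_rejects_split(self):
        table, truth = z.simulate_population(125, (1, 0, 0), seed=22)
        calls, _ = run_calls_on_population(
            table, truth, z.CallConfig(method="kmeans"))
        pstat = calls.population_stats["pop1"]
        assert pstat.ccc < 2.0
        assert (calls.calls["final_call"] != "hemizygous").all()

    def test_null_and_missing_propagate_from_presence(self, simulated_calls):
        calls, merged = simulated_calls
        assert (merged.loc[merged["presence"] == "null", "final_call"] == "null").all()
        assert (merged.loc[merged["presence"] == "missing",
                           "final_call"] == "missing").all()

    def test_missing_trait_table_rejected(self, simulated_calls):
        calls, _ = simulated_calls
        with pytest.raises(ValidationError):
            z.call_zygosity({"area": object()}, pd.Series(dtype=object),
                            z.CallConfig(trait="height"))


class TestConcordance:
    def _callset(self, pit, km):
        df = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(len(pit))],
            "population_id": "p", "presence": "transgenic",
            "pit_call": pit, "kmeans_call": km,
            "final_call": "homozygous",
            "normalized_height": 1.0, "normalized_area": 1.0,
        })
        return z.ZygosityCallSet(calls=df, population_stats={},
                                 config=z.CallConfig())

    def test_identical_calls_agree_fully(self):
        c = z.concordance(self._callset(["AA"] * 10, ["AA"] * 10))
        assert (c.n_disagree, c.fraction_agree) == (0, 1.0)

    def test_one_flip_in_ten(self):
        c = z.concordance(self._callset(["AA"] * 10, ["AA"] * 9 + ["AB"]))
        assert c.n_disagree == 1
        assert c.fraction_agree == pytest.approx(0.9)

    def test_methods_concordant_on_separated_clusters(self, simulated_calls):
        calls, _ = simulated_calls
        assert z.concordance(calls).fraction_agree >= 0.95
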