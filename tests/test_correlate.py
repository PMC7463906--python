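import itertools
import math

import numpy as np
import pandas as pd
import pytest

from genophen import synthdata
from genophen.correlate import (
    DescriptorScan,
    classify_trend,
    descriptor_scan,
    matrix_correlation,
    profile_distance,
    psw,
    psw_trend,
    region_max_correlation,
    scan_spectra_by_condition,
)
from genophen.distmat import DistanceMatrix


def from_triangle(labels, tri):
    return DistanceMatrix.from_condensed(labels, tri)


class TestProfileDistance:
    def test_identical_profiles_zero(self):
        D = profile_distance(np.ones((3, 5)), labels=list("abc"))
        np.testing.assert_allclose(D.values, 0.0)

    def test_one_dimensional(self):
        D = profile_distance(np.array([[0.0], [3.0], [4.0]]), labels=list("abc"))
        np.testing.assert_allclose(D.condensed(), [3.0, 4.0, 1.0])

    def test_pythagorean(self):
        D = profile_distance(np.array([[0.0, 0.0], [3.0, 4.0]]), labels=list("ab"))
        assert D["a", "b"] == pytest.approx(5.0)


class TestMatrixCorrelation:
    def test_self_correlation_is_one(self):
        D = from_triangle("abc", [1.0, 2.0, 3.0])
        res = matrix_correlation(D, D)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_perfect_reversal(self):
        D1 = from_triangle("abc", [1.0, 2.0, 3.0])
        D2 = from_triangle("abc", [3.0, 2.0, 1.0])
        assert matrix_correlation(D1, D2).r == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_pearson(self):
        D1 = from_triangle("abc", [1.0, 2.0, 4.0])
        D2 = from_triangle("abc", [1.0, 3.0, 4.0])
        assert matrix_correlation(D1, D2).r == pytest.approx(39 / 42, abs=1e-9)
        assert matrix_correlation(D1, D2).r == pytest.approx(0.92857, abs=1e-5)

    def test_label_alignment_not_order(self):
        D1 = from_triangle("abc", [1.0, 2.0, 4.0])
        # same distances with rows permuted: correlation must be identical
        D2 = from_triangle("abc", [1.0, 3.0, 4.0]).reorder(("c", "a", "b"))
        assert matrix_correlation(D1, D2).r == pytest.approx(39 / 42, abs=1e-9)

    def test_label_mismatch_lists_difference(self):
        D1 = from_triangle("abc", [1.0, 2.0, 4.0])
        D2 = from_triangle("abd", [1.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="'d'"):
            matrix_correlation(D1, D2)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        D1 = from_triangle("abcd", rng.uniform(1, 5, 6))
        D2 = from_triangle("abcd", rng.uniform(1, 5, 6))
        a = matrix_correlation(D1, D2)
        b = matrix_correlation(D2, D1)
        assert a.r == pytest.approx(b.r, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_exhaustive_permutation_matches_brute_force(self):
        rng = np.random.default_rng(1)
        D1 = from_triangle("abcd", rng.uniform(1, 5, 6))
        D2 = from_triangle("abcd", rng.uniform(1, 5, 6))
        res = matrix_correlation(D1, D2, n_perm=9999)
        assert res.exhaustive
        # independent brute force over all 24 relabelings of D2
        iu = np.triu_indices(4, 1)
        c1 = D1.values[iu]
        hits = 0
        for perm in itertools.permutations(range(4)):
            sq = D2.values[np.ix_(perm, perm)]
            r = np.corrcoef(c1, sq[iu])[0, 1]
            if abs(r) >= abs(res.r) - 1e-12:
                hits += 1
        assert res.p_value == pytest.approx(hits / 24, abs=1e-12)

    def test_sampled_permutation_p_in_range(self):
        rng = np.random.default_rng(2)
        labels = [f"t{i}" for i in range(8)]
        D1 = from_triangle(labels, rng.uniform(1, 5, 28))
        D2 = from_triangle(labels, rng.uniform(1, 5, 28))
        res = matrix_correlation(D1, D2, n_perm=99, seed=3)
        assert not res.exhaustive
        assert 1 / 100 <= res.p_value <= 1.0

    def test_parametric_p_matches_t_distribution(self):
        from scipy import stats

        D1 = from_triangle("abcd", [1.0, 2.0, 3.0, 4.0, 5.0, 6.5])
        D2 = from_triangle("abcd", [1.1, 2.2, 2.9, 4.3, 4.8, 6.6])
        res = matrix_correlation(D1, D2, method="parametric_t")
        t = res.r * math.sqrt(4) / math.sqrt(1 - res.r**2)
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), df=4), abs=1e-12)

    def test_zero_variance_triangle_rejected(self):
        D1 = from_triangle("abc", [1.0, 1.0, 1.0])
        D2 = from_triangle("abc", [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="variance"):
            matrix_correlation(D1, D2)


class TestDescriptorScan:
    def test_affine_descriptor_gives_r_one(self):
        # four strains on a line: descriptor affine in the embedding
        pos = np.array([0.0, 1.0, 2.5, 4.0])
        g = np.abs(pos[:, None] - pos[None, :])
        D = DistanceMatrix(("a", "b", "c", "d"), g)
        profiles = pd.DataFrame(
            {"x": 3.0 + 2.0 * pos, "noise": [1.0, 1.0, 1.0, 1.0]},
            index=["a", "b", "c", "d"],
        )
        scan = descriptor_scan(D, profiles)
        assert scan.r[0] == pytest.approx(1.0, abs=1e-12)

    def test_constant_descriptor_recorded_as_zero(self):
        D = from_triangle("abc", [1.0, 2.0, 3.0])
        profiles = pd.DataFrame({"c": [5.0, 5.0, 5.0]}, index=list("abc"))
        scan = descriptor_scan(D, profiles)
        assert scan.r[0] == 0.0
        assert scan.p[0] == 1.0

    def test_vectorized_r_matches_naive_loop(self):
        rng = np.random.default_rng(4)
        labels = [f"s{i}" for i in range(5)]
        D = from_triangle(labels, rng.uniform(0.5, 2.0, 10))
        profiles = pd.DataFrame(
            rng.normal(size=(5, 40)), index=labels,
            columns=[f"w{j}" for j in range(40)],
        )
        scan = descriptor_scan(D, profiles)
        iu = np.triu_indices(5, 1)
        g = D.values[iu]
        for j, col in enumerate(profiles.columns):
            x = profiles[col].to_numpy()
            d = np.abs(x[iu[0]] - x[iu[1]])
            assert scan.r[j] == pytest.approx(np.corrcoef(g, d)[0, 1], abs=1e-10)

    def test_exhaustive_scan_p_matches_single_matrix_correlation(self):
        rng = np.random.default_rng(5)
        labels = list("abcd")
        D = from_triangle(labels, rng.uniform(0.5, 2.0, 6))
        profiles = pd.DataFrame(
            rng.normal(size=(4, 5)), index=labels,
            columns=[f"w{j}" for j in range(5)],
        )
        scan = descriptor_scan(D, profiles)
        for j, col in enumerate(profiles.columns):
            x = profiles[col].to_numpy()
            Dd = DistanceMatrix(
                tuple(labels), np.abs(x[:, None] - x[None, :])
            )
            ref = matrix_correlation(D, Dd)
            assert scan.r[j] == pytest.approx(ref.r, abs=1e-10)
            assert scan.p[j] == pytest.approx(ref.p_value, abs=1e-10)

    def test_duplicate_descriptors_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            DescriptorScan(("w", "w"), np.array([0.1, 0.2]))


class TestPsw:
    def test_worked_example(self):
        assert psw(np.array([0.8, 0.5, 0.9, 0.2])) == pytest.approx(50.0)

    def test_all_below_threshold(self):
        assert psw(np.array([0.1, 0.2])) == 0.0

    def test_planted_fraction(self):
        r = np.zeros(901)
        r[:50] = 0.99
        assert psw(r) == pytest.approx(100 * 50 / 901, abs=1e-9)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        r = rng.uniform(-1, 1, 500)
        values = [psw(r, threshold=t) for t in (0.9, 0.75, 0.5, 0.0)]
        assert values == sorted(values)

    def test_order_invariant(self):
        rng = np.random.default_rng(7)
        r = rng.uniform(-1, 1, 100)
        assert psw(r) == psw(r[::-1])


class TestClassifyTrend:
    def test_low_intensity_response(self):
        assert classify_trend([0.0, 0.0, 1.67, 2.44]) == "low"

    def test_high_intensity_response(self):
        assert classify_trend([7.19, 3.0, 0.0, 22.34]) == "high"

    def test_non_monotonous_response(self):
        assert classify_trend([2.0, 6.0, 4.0, 2.05]) == "non_monotonous"

    def test_maximum_at_first_condition_is_monotone_class(self):
        assert classify_trend([7.0, 3.0, 2.0, 1.0]) == "high"
        assert classify_trend([3.0, 2.0, 1.0, 0.5]) == "low"

    def test_needs_three_conditions(self):
        with pytest.raises(ValueError, match="3"):
            classify_trend([1.0, 2.0])


class TestRegionMaxCorrelation:
    def _scenario(self, amplitudes):
        return synthdata.ScenarioConfig(
            locus_specs=(("locA", 500, 1.0), ("locB", 500, 1.0)),
            planted_signals=(
                synthdata.PlantedSignal("W1", "locA", amplitudes, 30),
            ),
            baseline_sd=0.0,
            noise_sd=0.0,
            feature_source_locus="locA",
            seed=21,
        )

    def test_planted_control_signal_found_in_w1_control(self):
        from genophen import seqdist

        sc = self._scenario((0.006, 0.0, 0.0, 0.0))  # control only
        alns = synthdata.simulate_alignments(sc)
        sset = synthdata.simulate_spectra(sc, alns)
        Ds = {
            name: seqdist.evolutionary_distance(a, model="p")
            for name, a in alns.items()
        }
        table = region_max_correlation(Ds, sset, sc.region_map)
        w1a = table[(table.marker == "locA") & (table.region == "W1")]
        ctrl = float(w1a[w1a.group == "control"]["max_r"].iloc[0])
        stress = float(w1a[w1a.group == "stressed"]["max_r"].iloc[0])
        assert ctrl > 0.75
        # no planted signal in any stressed condition: constant descriptors
        assert stress == 0.0

    def test_single_wavelength_region_max_is_that_r(self):
        from genophen import seqdist
        from genophen.ftir import RegionMap

        sc = self._scenario((0.006, 0.006, 0.006, 0.006))
        alns = synthdata.simulate_alignments(sc)
        sset = synthdata.simulate_spectra(sc, alns)
        D = seqdist.evolutionary_distance(alns["locA"], model="p")
        idx = synthdata.planted_wavelengths(sc)[0][0]
        w = synthdata.AXIS[idx]
        rm = RegionMap(one=(w, w - 4.0), **dict(sc.region_map))
        table = region_max_correlation(
            {"locA": D}, sset, rm, regions=("one",)
        )
        scans = scan_spectra_by_condition(D, sset, "locA")
        ctrl_scan = scans[0.0]
        j = list(ctrl_scan.descriptors).index(w)
        ctrl = table[(table.group == "control")]["max_r"].iloc[0]
        assert ctrl == pytest.approx(ctrl_scan.r[j], abs=1e-12)


def test_psw_trend_convenience_round_trip():
    sc = synthdata.ScenarioConfig(
        locus_specs=(("locA", 500, 1.0),),
        planted_signals=(
            synthdata.PlantedSignal("W2", "locA", (0.0, 0.0, 0.004, 0.008), 50),
        ),
        baseline_sd=0.0,
        noise_sd=0.0,
        feature_source_locus="locA",
        seed=31,
    )
    from genophen import seqdist

    alns = synthdata.simulate_alignments(sc)
    sset = synthdata.simulate_spectra(sc, alns)
    D = seqdist.evolutionary_distance(alns["locA"], model="p")
    scans = scan_spectra_by_condition(D, sset, "locA")
    trend = psw_trend("locA", scans)
    assert trend.conditions == (0.0, 8.0, 12.0, 16.0)
    assert trend.psw_percent[0] == 0.0
    assert trend.psw_percent[-1] == pytest.approx(100 * 50 / 901, abs=1e-9)
    assert trend.trend_class in ("low", "high")
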