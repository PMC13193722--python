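"""TIC normalization, FC/p classification, chirality calls, RT shift test."""

import math

import numpy as np
import pandas as pd
import pytest

from hgmod.quant import (
    AbundanceMatrix,
    chirality_call,
    classify_modified,
    high_confidence_filter,
    occupancy,
    overlap_sets,
    paired_rt_test,
    tic_normalize,
)


def make_matrix(data: dict, samples: list[tuple]) -> AbundanceMatrix:
    cols = [s[0] for s in samples]
    meta = pd.DataFrame(
        [s[1:] for s in samples],
        columns=["condition", "series", "dose", "replicate"],
        index=cols,
    )
    return AbundanceMatrix(pd.DataFrame(data, index=cols).T, meta)


def two_group_matrix(control_vals, treated_vals) -> AbundanceMatrix:
    samples = [
        (f"c{i}", "ctrl", "vehicle", 0.0, i + 1) for i in range(len(control_vals))
    ] + [
        (f"t{i}", "trt", "D2HG", 20.0, i + 1) for i in range(len(treated_vals))
    ]
    data = {"pep1": list(control_vals) + list(treated_vals)}
    return make_matrix(data, samples)


class TestTICNormalize:
    def test_column_sums_equalized_to_median_tic(self):
        samples = [("s1", "a", "vehicle", 0.0, 1), ("s2", "b", "D2HG", 5.0, 1)]
        m = make_matrix({"p1": [40.0, 80.0], "p2": [60.0, 120.0]}, samples)
        out = tic_normalize(m)
        sums = out.data.sum(axis=0)
        assert np.allclose(sums, 150.0)  # median of {100, 200}

    def test_equal_columns_unchanged_up_to_scale(self):
        samples = [("s1", "a", "vehicle", 0.0, 1), ("s2", "b", "D2HG", 5.0, 1)]
        m = make_matrix({"p1": [40.0, 40.0], "p2": [60.0, 60.0]}, samples)
        out = tic_normalize(m)
        assert np.allclose(out.data.to_numpy(), m.data.to_numpy())

    def test_zero_tic_column_is_named_in_error(self):
        samples = [("s1", "a", "vehicle", 0.0, 1), ("s2", "b", "D2HG", 5.0, 1)]
        m = make_matrix({"p1": [40.0, 0.0], "p2": [60.0, 0.0]}, samples)
        with pytest.raises(ValueError, match="s2"):
            tic_normalize(m)


class TestClassifyModified:
    def test_welch_example(self):
        """Hand-checked Welch t on {10,11,12} vs {14,15,16}."""
        m = two_group_matrix([10, 11, 12], [14, 15, 16])
        res = classify_modified(m, "trt", "ctrl")
        row = res.loc["pep1"]
        assert math.isclose(row["fold_change"], 15 / 11, rel_tol=1e-9)
        assert math.isclose(row["p_value"], 0.00805, abs_tol=5e-5)
        assert bool(row["passed"])

    def test_fc_gate_blocks_significant_but_small_changes(self):
        # tight CV -> tiny p, but FC 1.1 < 1.2 threshold
        m = two_group_matrix([100, 100.1, 99.9], [110, 110.1, 109.9])
        res = classify_modified(m, "trt", "ctrl")
        row = res.loc["pep1"]
        assert row["p_value"] < 0.001 and not bool(row["passed"])

    def test_identical_groups_not_passed(self):
        m = two_group_matrix([10, 11, 12], [10, 11, 12])
        res = classify_modified(m, "trt", "ctrl")
        assert math.isclose(res.loc["pep1", "fold_change"], 1.0)
        assert not bool(res.loc["pep1", "passed"])

    def test_zero_control_mean_flagged_not_classified(self):
        m = two_group_matrix([0, 0, 0], [14, 15, 16])
        res = classify_modified(m, "trt", "ctrl")
        assert bool(res.loc["pep1", "flagged"])
        assert not bool(res.loc["pep1", "passed"])

    def test_single_replicate_rejected(self):
        m = two_group_matrix([10], [14])
        with pytest.raises(ValueError, match="replicates"):
            classify_modified(m, "trt", "ctrl")

    def test_null_calibration_without_fc_gate(self):
        """Type-I error of the t-test itself: ~5% of null peptides at p<0.05."""
        rng = np.random.default_rng(123)
        n_pep, cv = 1000, 0.15
        sigma = math.sqrt(math.log(1 + cv * cv))
        samples = [(f"c{i}", "ctrl", "vehicle", 0.0, i + 1) for i in range(3)] + [
            (f"t{i}", "trt", "D2HG", 20.0, i + 1) for i in range(3)
        ]
        data = {
            f"p{k}": np.exp(rng.normal(math.log(1e6), sigma, 6)) for k in range(n_pep)
        }
        m = make_matrix(data, samples)
        res = classify_modified(m, "trt", "ctrl", fc_threshold=0.0)
        frac = float((res["p_value"] < 0.05).mean())
        assert abs(frac - 0.05) <= 0.02
        # restoring the FC gate can only remove positives
        gated = classify_modified(m, "trt", "ctrl", fc_threshold=1.2)
        assert gated["passed"].sum() <= (res["p_value"] < 0.05).sum()


def dose_series_matrix(values: dict[str, dict[str, list[float]]]) -> AbundanceMatrix:
    """values: peptide -> condition name -> 3 replicate areas."""
    conditions = [
        ("vehicle_0", "vehicle", 0.0),
        ("D2HG_5", "D2HG", 5.0), ("D2HG_10", "D2HG", 10.0), ("D2HG_20", "D2HG", 20.0),
        ("L2HG_5", "L2HG", 5.0), ("L2HG_10", "L2HG", 10.0), ("L2HG_20", "L2HG", 20.0),
    ]
    samples, order = [], []
    for cond, series, dose in conditions:
        for r in (1, 2, 3):
            samples.append((f"{cond}_r{r}", cond, series, dose, r))
            order.append((cond, r - 1))
    data = {
        pep: [vals[cond][i] for cond, i in order] for pep, vals in values.items()
    }
    return make_matrix(data, samples)


def graded(base, factors, jitter=(0.97, 1.0, 1.03)):
    return {
        "vehicle_0": [base * j for j in jitter],
        "D2HG_5": [base * factors["D"][0] * j for j in jitter],
        "D2HG_10": [base * factors["D"][1] * j for j in jitter],
        "D2HG_20": [base * factors["D"][2] * j for j in jitter],
        "L2HG_5": [base * factors["L"][0] * j for j in jitter],
        "L2HG_10": [base * factors["L"][1] * j for j in jitter],
        "L2HG_20": [base * factors["L"][2] * j for j in jitter],
    }


class TestChiralityCall:
    def test_d_responder_called_d(self):
        m = dose_series_matrix({
            "pep_d": graded(100, {"D": (1.5, 1.8, 2.2), "L": (1.0, 1.0, 1.0)}),
        })
        calls, evidence = chirality_call(m)
        assert calls.loc["pep_d", "call"] == "D"
        ev = evidence[(evidence.peptide == "pep_d") & (evidence.series == "D2HG")]
        assert ev["passed"].all() and (ev["fold_change"] > 1.2).all()

    def test_both_series_responding_is_shared(self):
        m = dose_series_matrix({
            "pep_s": graded(100, {"D": (1.5, 1.8, 2.2), "L": (1.4, 1.9, 2.1)}),
        })
        calls, _ = chirality_call(m)
        assert calls.loc["pep_s", "call"] == "shared"

    def test_single_passing_dose_is_ambiguous(self):
        m = dose_series_matrix({
            "pep_a": graded(100, {"D": (1.0, 1.0, 2.2), "L": (1.0, 1.0, 1.0)}),
        })
        calls, _ = chirality_call(m)  # min_passing_doses = 2
        assert calls.loc["pep_a", "call"] == "ambiguous"

    def test_nonmonotone_dose_response_not_called(self):
        # passes the gate at two doses but falls with dose: not a dose response
        m = dose_series_matrix({
            "pep_n": graded(100, {"D": (2.4, 1.7, 1.3), "L": (1.0, 1.0, 1.0)}),
        })
        calls, _ = chirality_call(m)
        assert calls.loc["pep_n", "call"] == "ambiguous"


class TestHighConfidenceFilter:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["group", "peptide", "call"])

    def test_consistent_multigroup_call_retained(self):
        out = high_confidence_filter(self._calls(
            [("g1", "p1", "D"), ("g2", "p1", "D"), ("g3", "p1", "D")]
        ))
        assert out.iloc[0]["peptide"] == "p1"
        assert out.iloc[0]["n_groups"] == 3

    def test_single_group_call_dropped(self):
        out = high_confidence_filter(self._calls([("g1", "p1", "D")]))
        assert out.empty

    def test_conflicting_enantiomers_dropped(self):
        out = high_confidence_filter(self._calls(
            [("g1", "p1", "D"), ("g2", "p1", "L")]
        ))
        assert out.empty


class TestOverlapAndOccupancy:
    def test_specific_and_shared_counts(self):
        """56 and 130 identifications sharing 16 -> 40 and 114 specific."""
        a = {f"d{i}" for i in range(40)} | {f"s{i}" for i in range(16)}
        b = {f"l{i}" for i in range(114)} | {f"s{i}" for i in range(16)}
        res = overlap_sets(a, b)
        assert res.counts == (40, 114, 16)
        assert len(a) == len(res.a_specific) + len(res.shared)
        assert len(b) == len(res.b_specific) + len(res.shared)

    def test_disjoint_and_identical_sets(self):
        assert overlap_sets({1, 2}, {3}).counts == (2, 1, 0)
        assert overlap_sets({1, 2}, {1, 2}).counts == (0, 0, 2)

    @pytest.mark.parametrize(
        "mod, unmod, expected",
        [(25, 75, 0.25), (0, 10, 0.0), (10, 0, 1.0)],
    )
    def test_occupancy_fraction(self, mod, unmod, expected):
        assert occupancy(mod, unmod) == expected

    def test_occupancy_undefined_for_double_zero(self):
        assert math.isnan(occupancy(0.0, 0.0))


class TestPairedRTTest:
    def test_hand_computed_paired_t(self):
        rts = [(10.8, 10.0), (11.0, 10.0), (11.2, 10.0), (11.0, 10.0)]
        res = paired_rt_test(rts)
        assert math.isclose(res.mean_delta, 1.0, abs_tol=1e-12)
        assert math.isclose(res.t_statistic, 12.2474, abs_tol=1e-3)
        assert math.isclose(res.p_value, 0.00117, abs_tol=5e-5)

    def test_zero_variance_flagged_degenerate(self):
        res = paired_rt_test([(10.0, 10.0)] * 4)
        assert res.degenerate and res.mean_delta == 0.0
        assert math.isnan(res.p_value)

    def test_sign_flip_negates_delta_keeps_p(self):
        rts = [(10.8, 10.0), (11.0, 10.0), (11.2, 10.0), (11.0, 10.0)]
        fwd = paired_rt_test(rts)
        rev = paired_rt_test([(b, a) for a, b in rts])
        assert math.isclose(rev.mean_delta, -fwd.mean_delta, abs_tol=1e-12)
        assert math.isclose(rev.p_value, fwd.p_value, abs_tol=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_rt_test([(1.0, 0.5), (1.1, 0.4)])
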