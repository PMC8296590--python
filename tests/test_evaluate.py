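import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import pedsignal as ps
from helpers import make_table
from pedsignal.evaluate import UndefinedMetricError
from pedsignal.stages import STAGE_NAMES


def exhaustive_auroc(pos, neg):
    """Independent oracle: enumerate all (positive, negative) pairs."""
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestAuroc:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([2, 3], [1], 1.0),
            ([1, 3], [2], 0.5),
            ([1], [2, 3], 0.0),
            ([1, 1], [1], 0.5),  # all ties count one half
        ],
    )
    def test_small_examples(self, pos, neg, expected):
        assert ps.auroc(pos, neg) == pytest.approx(expected)

    def test_matches_exhaustive_counting(self, rng):
        """Rank-statistic AUROC equals brute-force pair enumeration on
        small sets, including ties and infinities."""
        for _ in range(200):
            n_p = rng.integers(1, 21)
            n_n = rng.integers(1, 21)
            pool = np.concatenate([rng.integers(0, 6, 30).astype(float), [np.inf, np.inf]])
            pos = rng.choice(pool, n_p)
            neg = rng.choice(pool, n_n)
            assert ps.auroc(pos, neg) == pytest.approx(exhaustive_auroc(pos, neg))

    def test_identical_distributions_expect_half(self, rng):
        vals = rng.normal(size=4000)
        assert ps.auroc(vals[:2000], vals[2000:]) == pytest.approx(0.5, abs=0.05)

    def test_nan_excluded(self):
        assert ps.auroc([np.nan, 2.0], [1.0]) == 1.0

    def test_empty_after_exclusion_raises(self):
        with pytest.raises(UndefinedMetricError):
            ps.auroc([np.nan], [1.0])


class TestThresholdMetrics:
    def test_perfect_split(self):
        m = ps.threshold_metrics([2.0], [0.5], threshold=1.0)
        assert m == {"sensitivity": 1.0, "ppv": 1.0, "npv": 1.0}

    def test_all_below_threshold(self):
        m = ps.threshold_metrics([0.1, 0.2], [0.0, 0.3, 0.4], threshold=1.0)
        assert m["sensitivity"] == 0.0
        assert np.isnan(m["ppv"])  # nothing predicted positive
        assert m["npv"] == pytest.approx(3 / 5)

    def test_threshold_at_minus_infinity(self):
        m = ps.threshold_metrics([1.0, 2.0], [0.5], threshold=-np.inf)
        assert m["sensitivity"] == 1.0
        assert m["ppv"] == pytest.approx(2 / 3)

    def test_boundary_is_negative_call(self):
        """A score exactly at the threshold calls negative ('>' vs '<=')."""
        m = ps.threshold_metrics([1.0], [1.0], threshold=1.0)
        assert m["sensitivity"] == 0.0
        assert m["npv"] == pytest.approx(0.5)


class TestBootstrapCI:
    def test_constant_scores_zero_width(self):
        point, lo, hi = ps.bootstrap_ci(ps.auroc, [2.0] * 5, [1.0] * 5, n_boot=20, seed=0)
        assert point == lo == hi == 1.0

    def test_same_seed_identical(self, rng):
        pos, neg = rng.normal(1, 1, 30), rng.normal(0, 1, 30)
        a = ps.bootstrap_ci(ps.auroc, pos, neg, n_boot=50, seed=7)
        b = ps.bootstrap_ci(ps.auroc, pos, neg, n_boot=50, seed=7)
        assert a == b

    def test_interval_contains_point_typically(self, rng):
        pos, neg = rng.normal(1, 1, 100), rng.normal(0, 1, 100)
        point, lo, hi = ps.bootstrap_ci(ps.auroc, pos, neg, n_boot=100, seed=1)
        assert lo <= point <= hi

    def test_coverage_of_analytic_auroc(self, rng):
        """Normal vs shifted-normal: the 95% interval covers the closed-form
        AUROC = Phi(delta / sqrt(2)) in about 95% of replications."""
        delta = 1.0
        true_auroc = norm.cdf(delta / np.sqrt(2))
        covered = 0
        n_rep = 60
        for i in range(n_rep):
            pos = rng.normal(delta, 1, 120)
            neg = rng.normal(0, 1, 120)
            _, lo, hi = ps.bootstrap_ci(ps.auroc, pos, neg, n_boot=100, seed=i)
            covered += lo <= true_auroc <= hi
        assert covered / n_rep >= 0.85  # binomial slack below the nominal 95%


class TestLowReportingPerformance:
    def _frames(self, rng):
        pos = pd.DataFrame({"value": rng.normal(1.5, 1, 200), "n_drug": rng.integers(1, 100, 200)})
        neg = pd.DataFrame({"value": rng.normal(0, 1, 400), "n_drug": rng.integers(1, 100, 400)})
        return pos, neg

    def test_single_bin_equals_overall(self, rng):
        pos, neg = self._frames(rng)
        out = ps.low_reporting_performance(pos, neg, 0.0, bins=[0, 1000], n_boot=10, seed=0)
        assert len(out) == 1
        assert out.iloc[0]["auroc"] == pytest.approx(ps.auroc(pos["value"], neg["value"]))

    def test_empty_bin_skipped(self, rng):
        pos, neg = self._frames(rng)
        out = ps.low_reporting_performance(
            pos, neg, 0.0, bins=[0, 50, 100, 100000], n_boot=10, seed=0
        )
        assert len(out) == 2  # the (100, 100000] bin has no members


class TestRemoveDrugReports:
    def _table(self, rng):
        return make_table(
            rng.choice(STAGE_NAMES, 2000), rng.integers(0, 2, 2000), rng.integers(0, 2, 2000)
        )

    def test_fraction_zero_identity(self, rng):
        t = self._table(rng)
        pd.testing.assert_frame_equal(ps.remove_drug_reports(t, "toddler", 0.0, seed=1), t)

    def test_fraction_one_removes_all_stage_drug_rows(self, rng):
        t = self._table(rng)
        out = ps.remove_drug_reports(t, "toddler", 1.0, seed=1)
        assert ((out["nichd_stage"] == "toddler") & (out["drug"] == 1)).sum() == 0

    def test_other_rows_untouched(self, rng):
        t = self._table(rng)
        out = ps.remove_drug_reports(t, "toddler", 0.5, seed=1)
        kept_other = out[(out["nichd_stage"] != "toddler") | (out["drug"] == 0)]
        orig_other = t[(t["nichd_stage"] != "toddler") | (t["drug"] == 0)]
        assert len(kept_other) == len(orig_other)
        n_stage_drug = ((t["nichd_stage"] == "toddler") & (t["drug"] == 1)).sum()
        removed = n_stage_drug - ((out["nichd_stage"] == "toddler") & (out["drug"] == 1)).sum()
        assert removed == round(0.5 * n_stage_drug)

    def test_bad_fraction(self, rng):
        with pytest.raises(ValueError):
            ps.remove_drug_reports(self._table(rng), "toddler", 1.5)


class TestRealWorldValidation:
    def _corpus_scores(self, rng, n_pos=26, n_neg=123, separation=3.0):
        rows = []
        for method in ("GAM", "PRR"):
            null = 0.0 if method == "GAM" else 1.0
            for label, n, shift in [("P", n_pos, separation), ("N", n_neg, 0.0)]:
                for i in range(n):
                    for stage in STAGE_NAMES:
                        val = null + rng.normal(shift, 0.5)
                        rows.append(
                            {
                                "pair_id": f"{label}{i}",
                                "method": method,
                                "nichd_stage": stage,
                                "score": val,
                                "lower90": val - 0.4,
                                "quality": "finite",
                            }
                        )
        scores = pd.DataFrame(rows)
        ref = pd.DataFrame(
            {
                "drug_id": [f"P{i}".split("|")[0] for i in range(n_pos)],
                "event_id": ["E"] * n_pos,
                "control": ["C"] * n_pos,
            }
        )
        ref["pair_id"] = [f"P{i}" for i in range(n_pos)]
        return scores, ref

    def test_separated_corpus_high_auroc(self, rng):
        scores, ref = self._corpus_scores(rng)
        perf, tally, prop = ps.real_world_validation(scores, ref, n_boot=20, seed=0)
        assert (perf["auroc"] > 0.95).all()
        assert set(perf["method"]) == {"GAM", "PRR"}
        assert set(prop) == {"chi2", "pvalue"}
        # both methods flag every reference pair here, so the proportions
        # are identical; a non-significant (or degenerate NaN) p is expected
        assert not (prop["pvalue"] < 0.05)

    def test_positive_class_size(self, rng):
        scores, ref = self._corpus_scores(rng)
        perf, tally, _ = ps.real_world_validation(scores, ref, n_boot=5, seed=0)
        assert (perf["n_pos"] == 26).all()
        assert (perf["n_neg"] == 123).all()
        assert (tally["n_pairs"] == 26).all()

    def test_identical_scores_auroc_half(self, rng):
        scores, ref = self._corpus_scores(rng, separation=0.0)
        scores["score"] = 5.0
        scores["lower90"] = 4.0
        perf, _, _ = ps.real_world_validation(scores, ref, n_boot=5, seed=0)
        assert np.allclose(perf["auroc"], 0.5)

    def test_grip_file_round_trip(self, tmp_path, rng):
        ref = pd.DataFrame(
            {
                "ATC_concept_id": ["a1", "a2", "a3"],
                "MedDRA_concept_id": ["m1", "m2", "m3"],
                "Control": ["C", "N", "C"],
            }
        )
        path = tmp_path / "synthetic_reference.csv"
        ref.to_csv(path, index=False)
        parsed = ps.read_grip_reference(path)
        assert (parsed["control"] == "C").sum() == 2
        assert parsed["pair_id"].tolist() == ["a1|m1", "a2|m2", "a3|m3"]

    def test_missing_control_column(self, tmp_path):
        pd.DataFrame({"atc": ["a"], "meddra": ["m"]}).to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValueError, match="Control|control"):
            ps.read_grip_reference(tmp_path / "bad.csv")
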