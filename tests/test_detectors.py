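import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pedsignal as ps
from helpers import brute_force_prr, make_table, table_from_counts
from pedsignal.detectors import Z_LOWER_90, _prr_frame
from pedsignal.stages import ContingencyTable, STAGE_NAMES, stage_count_frame


class TestPRR:
    def test_printed_formula(self):
        score, lower, quality = ps.prr(ContingencyTable(a=20, b=100, c=80, d=900))
        assert score == pytest.approx(2.0)
        assert quality == "finite"
        var = 1 / 20 - 1 / 100 + 1 / 100 - 1 / 1000
        assert lower == pytest.approx(np.exp(np.log(2.0) - Z_LOWER_90 * np.sqrt(var)))
        assert lower < score

    def test_quality_zero(self):
        score, lower, quality = ps.prr(ContingencyTable(a=0, b=5, c=10, d=100))
        assert score == 0.0 and lower == 0.0 and quality == "zero"

    def test_quality_nan_drug_absent(self):
        score, _, quality = ps.prr(ContingencyTable(a=0, b=5, c=0, d=100))
        assert np.isnan(score) and quality == "nan"

    def test_quality_infinite(self):
        score, _, quality = ps.prr(ContingencyTable(a=3, b=0, c=10, d=100))
        assert np.isinf(score) and quality == "infinite"

    @given(
        a=st.integers(0, 30), b=st.integers(0, 30),
        c=st.integers(0, 30), d=st.integers(0, 30),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_brute_force_from_raw_rows(self, a, b, c, d):
        """PRR on the 2x2 equals direct counting over raw report rows."""
        table = table_from_counts(a, b, c, d, stage="toddler")
        expected_score, expected_quality = brute_force_prr(table, "toddler")
        ct = ps.stage_contingency(table, "toddler")
        score, lower, quality = ps.prr(ct)
        assert quality == expected_quality
        if quality == "finite":
            assert score == pytest.approx(expected_score)
            assert lower <= score  # equality only when the log-variance is 0
        elif quality == "nan":
            assert np.isnan(score)
        elif quality == "zero":
            assert score == 0.0
        else:
            assert np.isinf(score)

    def test_vectorized_frame_matches_scalar(self, rng):
        rows = []
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, size=4)
            rows.append(
                make_table(
                    rng.choice(STAGE_NAMES, a + b + c + d) if a + b + c + d else [],
                    [1] * a + [0] * b + [1] * c + [0] * d,
                    [1] * a + [1] * b + [0] * c + [0] * d,
                )
            )
        for t in rows:
            counts = stage_count_frame(t)
            frame = _prr_frame(counts, Z_LOWER_90)
            for i, stage in enumerate(STAGE_NAMES):
                ct = ps.stage_contingency(t, stage)
                score, lower, quality = ps.prr(ct)
                assert frame.loc[i, "quality"] == quality
                if quality == "finite":
                    assert frame.loc[i, "score"] == pytest.approx(score)
                    assert frame.loc[i, "lower90"] == pytest.approx(lower)


class TestPRRByStage:
    def test_drug_only_in_one_stage(self):
        t = make_table(
            ["toddler"] * 6 + ["infancy"] * 4,
            [1, 1, 0, 0, 0, 0] + [0] * 4,
            [1, 0, 1, 0, 0, 0] + [1, 0, 0, 0],
        )
        sc = ps.prr_by_stage(t, "p")
        assert len(sc) == 7
        by_stage = sc.set_index("nichd_stage")
        assert by_stage.loc["toddler", "quality"] == "finite"
        for s in STAGE_NAMES:
            if s != "toddler":
                assert by_stage.loc[s, "quality"] == "nan"

    def test_null_simulation_scores_near_one(self):
        cfg = ps.GeneratorConfig(
            n_reports=100_000, pair_catalog=[ps.PairSpec("D", "E", 0.2, 0.2)], seed=21
        )
        _, t = next(ps.generate_reports(cfg))
        sc = ps.prr_by_stage(t)
        finite = sc[sc["quality"] == "finite"]
        assert len(finite) == 7
        assert ((finite["score"] > 0.8) & (finite["score"] < 1.25)).all()

    def test_uniform_injection_scores_near_fc(self):
        cfg = ps.GeneratorConfig(
            n_reports=100_000, pair_catalog=[ps.PairSpec("D", "E", 0.2, 0.01)], seed=22
        )
        _, t = next(ps.generate_reports(cfg))
        from pedsignal.augment import drug_reports_per_stage

        spec = ps.DynamicsSpec.solve(
            "uniform", 4.0, 0.01, drug_reports_per_stage(t), seed=23
        )
        sc = ps.prr_by_stage(ps.inject_events(t, spec))
        finite = sc[sc["quality"] == "finite"]
        assert ((finite["score"] > 3.0) & (finite["score"] < 5.2)).all()


class TestStratifiedPRREstimator:
    def test_sklearn_protocol(self):
        from sklearn.base import clone

        est = ps.StratifiedPRR(z_lower=1.645)
        assert est.get_params() == {"z_lower": 1.645}
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_array_input(self, rng):
        stage_idx = rng.integers(1, 8, size=400)
        drug = rng.integers(0, 2, size=400)
        event = rng.integers(0, 2, size=400)
        est = ps.StratifiedPRR().fit(np.column_stack([stage_idx, drug]), event)
        names = np.array(STAGE_NAMES)
        t = make_table(names[stage_idx - 1], drug, event)
        expected = ps.prr_by_stage(t)
        got = est.stage_scores()
        pd.testing.assert_series_equal(
            got["score"], expected["score"], check_names=False
        )


class TestNormalitySummary:
    def _scores(self, values, method="GAM", quality="finite"):
        rows = []
        for i, v in enumerate(values):
            rows.append(
                {
                    "pair_id": f"p{i}",
                    "method": method,
                    "nichd_stage": "toddler",
                    "score": v,
                    "lower90": v - 0.5,
                    "quality": quality,
                }
            )
        return pd.DataFrame(rows)

    def test_normal_scores_high_p(self, rng):
        out = ps.normality_summary(self._scores(rng.normal(0, 1, 80)), n_boot=50, seed=0)
        cell = out[out["score_type"] == "score"].iloc[0]
        assert cell["assessable"]
        assert cell["shapiro_p_mean"] > 0.05

    def test_point_mass_not_assessable(self):
        out = ps.normality_summary(self._scores([2.0] * 10), n_boot=10, seed=0)
        assert not out.iloc[0]["assessable"]

    def test_too_few_scores_not_assessable(self):
        out = ps.normality_summary(self._scores([1.0, 2.0]), n_boot=10, seed=0)
        assert not out.iloc[0]["assessable"]

    def test_prr_quality_tally_and_log_transform(self, rng):
        df = self._scores(np.exp(rng.normal(0, 0.5, 60)), method="PRR")
        df.loc[0, ["score", "quality"]] = [np.nan, "nan"]
        df.loc[1, ["score", "quality"]] = [0.0, "zero"]
        out = ps.normality_summary(df, n_boot=30, seed=1)
        cell = out[out["score_type"] == "score"].iloc[0]
        assert cell["frac_nan"] > 0 and cell["frac_zero"] > 0
        assert cell["n_usable"] == 58  # zero and nan excluded
        # log-normal scores look normal after the log10 transform
        assert cell["shapiro_p_mean"] > 0.05
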