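"""Recoding, tabulation, filtering and internal-consistency summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metacog import survey_io
from metacog.survey_io import (
    ConfidenceCounts,
    IntegrityError,
    ResponseTable,
    SchemaError,
    cronbach_alpha,
    decode_response,
    filter_conspiracy_believers,
    read_responses,
    recode_response,
    tabulate_counts,
)


def make_table(rows):
    return ResponseTable(df=pd.DataFrame(rows))


def row(rid, sid, raw, domain="covid", truth="false_statement"):
    return {"respondent_id": rid, "statement_id": sid, "domain": domain,
            "truth": truth, "raw_response": raw}


class TestRecode:
    @given(raw=st.integers(min_value=1, max_value=6))
    @settings(derandomize=True, deadline=None)
    def test_round_trip_bijection(self, raw):
        judgement, confidence = recode_response(raw)
        assert decode_response(judgement, confidence) == raw

    @pytest.mark.parametrize("raw,judgement,confidence", [
        (1, "respond_true", 3), (2, "respond_true", 2), (3, "respond_true", 1),
        (4, "respond_false", 1), (5, "respond_false", 2), (6, "respond_false", 3),
    ])
    def test_scale_mapping(self, raw, judgement, confidence):
        assert recode_response(raw) == (judgement, confidence)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            recode_response(7)


class TestReadResponses:
    def test_toy_csv(self, tmp_path):
        p = tmp_path / "r.csv"
        pd.DataFrame([row("a", "s1", 1), row("a", "s2", 4),
                      row("a", "s3", 6)]).to_csv(p, index=False)
        table = read_responses(p)
        assert list(table.df["judgement"]) == [0, 1, 1]
        assert list(table.df["confidence"]) == [3, 1, 3]

    def test_out_of_range_row_rejected_and_reported(self, tmp_path):
        p = tmp_path / "r.csv"
        pd.DataFrame([row("a", "s1", 1), row("a", "s2", 7)]).to_csv(p, index=False)
        table = read_responses(p)
        assert len(table.df) == 1
        assert len(table.rejected) == 1
        assert table.log[0]["rejected"] == 1

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "r.csv"
        pd.DataFrame([{"respondent_id": "a", "raw_response": 1}]).to_csv(p, index=False)
        with pytest.raises(SchemaError):
            read_responses(p)

    def test_duplicate_pair_is_integrity_error(self, tmp_path):
        p = tmp_path / "r.csv"
        pd.DataFrame([row("a", "s1", 1), row("a", "s1", 2)]).to_csv(p, index=False)
        with pytest.raises(IntegrityError):
            read_responses(p)

    def test_schema_mapping_adapts_foreign_headers(self, tmp_path):
        p = tmp_path / "r.csv"
        pd.DataFrame([{"ID": "a", "item": "s1", "topic": "C19",
                       "label": "F", "answer": 2}]).to_csv(p, index=False)
        schema = {
            "columns": {"respondent_id": "ID", "statement_id": "item",
                        "domain": "topic", "truth": "label",
                        "raw_response": "answer"},
            "domain_values": {"C19": "covid"},
            "truth_values": {"F": "false_statement"},
        }
        table = read_responses(p, schema=schema)
        assert table.df.loc[0, "domain"] == "covid"
        assert table.df.loc[0, "judgement"] == 0


class TestTabulate:
    def test_all_confident_true_respondent(self):
        rows = [row("a", f"t{i}", 1, truth="true_statement") for i in range(7)]
        rows += [row("a", f"f{i}", 1, truth="false_statement") for i in range(7)]
        counts = tabulate_counts(make_table(rows))
        cc = counts[("a", "covid")]
        assert cc.counts[0, 0, 2] == 7      # true stmt, respond true, conf 3
        assert cc.counts[1, 0, 2] == 7      # false stmt, respond true, conf 3
        assert cc.counts.sum() == 14

    def test_totals_conserved_per_group(self, small_cohort, small_counts):
        responses, _, _ = small_cohort
        sizes = responses.df.groupby(["respondent_id", "domain"]).size()
        for key, cc in small_counts.items():
            assert cc.counts.sum() == cc.n_total == sizes[key]

    def test_type1_collapse(self, small_counts):
        cc = next(iter(small_counts.values()))
        assert cc.type1_table().shape == (2, 2)
        assert cc.type1_table().sum() == cc.n_total

    def test_cell_frequencies_match_generator_probabilities(self):
        """Pooled cell frequencies agree with the exact generative law."""
        from metacog import cohort, sdt_core

        d, c, m = 1.5, 0.2, 1.0
        cfg = cohort.CohortConfig(
            n_subjects=400, items_per_domain=56,
            population=cohort.PopulationConfig(
                dprime_mean=(d, d), dprime_sd=(1e-9, 1e-9),
                logm_mean=(np.log(m), np.log(m)), logm_sd=(1e-9, 1e-9),
                rho=0.0, c_mean=c, c_sd=1e-9),
            seed=77)
        responses, _, _ = cohort.generate_cohort(cfg)
        counts = tabulate_counts(responses)
        pooled = sum(cc.counts for cc in counts.values())
        n_per_stim = pooled.sum(axis=(1, 2))

        meta_d = m * d
        cprime = c * meta_d / d
        w1, w2 = cfg.population.criterion_offsets
        crit = np.array([cprime - w2, cprime - w1, cprime + w1, cprime + w2])
        cell = sdt_core.type2_cell_probabilities(meta_d, type2_criteria=crit,
                                                 c=c, d_prime=d)
        cond = sdt_core.type2_conditional_probs(cell)
        from scipy.special import ndtr
        p_true = np.array([ndtr(d / 2 - c), ndtr(-d / 2 - c)])
        expected = cond * np.stack([p_true, 1 - p_true], axis=1)[..., None]
        for s in range(2):
            n = n_per_stim[s]
            se = np.sqrt(expected[s] * (1 - expected[s]) / n)
            assert np.all(np.abs(pooled[s] / n - expected[s]) < 4 * se + 1e-12)


class TestConspiracyFilter:
    def make_ten(self):
        rows = []
        for i in range(10):
            raw_flag = [1, 2, 3][i] if i < 3 else 5
            rows.append(row(f"r{i}", "bioweapon", raw_flag))
            rows.append(row(f"r{i}", "other", 4))
        return make_table(rows)

    def test_exclusion_fraction(self):
        filtered, frac = filter_conspiracy_believers(self.make_ten(), "bioweapon")
        assert frac == pytest.approx(0.30)
        assert filtered.df["respondent_id"].nunique() == 7

    def test_idempotent(self):
        once, _ = filter_conspiracy_believers(self.make_ten(), "bioweapon")
        twice, frac2 = filter_conspiracy_believers(once, "bioweapon")
        assert frac2 == 0.0
        pd.testing.assert_frame_equal(once.df.reset_index(drop=True),
                                      twice.df.reset_index(drop=True))

    def test_no_believers_is_identity(self):
        rows = [row("a", "bioweapon", 6), row("b", "bioweapon", 4)]
        table = make_table(rows)
        filtered, frac = filter_conspiracy_believers(table, "bioweapon")
        assert frac == 0.0
        pd.testing.assert_frame_equal(filtered.df.reset_index(drop=True),
                                      table.df.reset_index(drop=True))

    def test_absent_statement_raises(self):
        with pytest.raises(LookupError):
            filter_conspiracy_believers(self.make_ten(), "nope")


class TestCronbach:
    def test_identical_items_give_alpha_one(self):
        rows = []
        for i in range(20):
            correct = i % 2 == 0
            for k in range(5):
                raw = 1 if correct else 6   # judge true when correct
                rows.append(row(f"r{i}", f"s{k}", raw, truth="true_statement"))
        alpha = cronbach_alpha(make_table(rows), "covid")
        assert alpha == pytest.approx(1.0, abs=1e-12)

    def test_independent_items_give_alpha_near_zero(self, rng):
        n, k = 5000, 14
        correct = rng.integers(0, 2, size=(n, k))
        rows = []
        for i in range(n):
            for j in range(k):
                rows.append(row(i, f"s{j}", 1 if correct[i, j] else 6,
                                truth="true_statement"))
        alpha = cronbach_alpha(make_table(rows), "covid")
        assert abs(alpha) < 0.05

    def test_zero_variance_signalled(self):
        rows = [row(f"r{i}", f"s{k}", 1, truth="true_statement")
                for i in range(4) for k in range(3)]
        with pytest.raises(ZeroDivisionError):
            cronbach_alpha(make_table(rows), "covid")
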