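"""Seed-match classification, QC filtering, quantile normalization and the
SM vs non-SM expression shift."""

import numpy as np
import pandas as pd
import pytest

from sirmsd.errors import QcError, SirmsdError
from sirmsd.offtarget import (
    classify_sm,
    offtarget_magnitude,
    qc_filter,
    quantile_normalize,
    rank_sum_test,
    seed_match_site,
    seed_of,
)
from sirmsd.simulate import simulate_expression, simulate_qc_flags

from oracles import ranksum_exact_p


class TestSeed:
    def test_positions_two_to_eight(self):
        assert seed_of("UACGGAUCAAU") == "ACGGAUC"

    def test_eight_mer_guide(self):
        assert seed_of("UACGGAUC") == "ACGGAUC"

    def test_short_guide_rejected(self):
        with pytest.raises(SirmsdError):
            seed_of("UACGGAU")

    def test_generator_declared_seed(self):
        fixture = simulate_expression(n_transcripts=50, utr_length=40, seed=1)
        assert seed_of(fixture.guide) == fixture.manifest.truths["seed7"]


class TestClassify:
    def test_reverse_complement_by_hand(self):
        # seed ACGGAUC -> DNA ACGGATC -> reverse complement GATCCGT
        assert seed_match_site("ACGGAUC") == "GATCCGT"
        flags = classify_sm({"t1": "AAAGATCCGTAAA"}, "ACGGAUC")
        assert bool(flags["t1"])

    def test_utr_without_site_is_non_sm(self):
        flags = classify_sm({"t1": "AAAAAAAAAAAA"}, "ACGGAUC")
        assert not bool(flags["t1"])

    def test_empty_utr_is_non_sm(self):
        assert not bool(classify_sm({"t1": ""}, "ACGGAUC")["t1"])

    def test_u_t_reencoding_invariance(self):
        utrs = {"t1": "AAAGATCCGTAAA", "t2": "CCCCCCCCCCCC"}
        utrs_u = {k: v.replace("T", "U") for k, v in utrs.items()}
        a = classify_sm(utrs, "ACGGAUC")
        b = classify_sm(utrs_u, "ACGGAUC")
        assert (a == b).all()

    def test_planted_flags_recovered_exactly(self):
        fixture = simulate_expression(n_transcripts=300, utr_length=60, seed=7)
        flags = classify_sm(fixture.utrs, seed_of(fixture.guide))
        assert (flags.reindex(fixture.sm.index) == fixture.sm).all()


class TestQcFilter:
    def _table(self):
        rows = []
        for i in range(10):
            rows.append({
                "SystematicName": f"NM_{i:06d}",
                "ControlType": 0, "gIsPosAndSignif": 1, "gIsFeatNonUnifOL": 0,
                "gIsWellAboveBG": 1, "gIsSaturated": 0, "gIsFeatPopnOL": 0,
            })
        rows[2]["gIsSaturated"] = 1
        rows[5]["gIsWellAboveBG"] = 0
        rows[8]["ControlType"] = 1
        return pd.DataFrame(rows)

    def test_all_passing_kept(self):
        table = self._table()
        assert "NM_000000" in set(qc_filter(table)["SystematicName"])

    def test_saturated_dropped(self):
        assert "NM_000002" not in set(qc_filter(self._table())["SystematicName"])

    def test_toy_table_count(self):
        assert len(qc_filter(self._table())) == 7

    def test_name_pattern_applies(self):
        table = self._table()
        table.loc[0, "SystematicName"] = "A_23_P10095"
        assert len(qc_filter(table)) == 6

    def test_missing_flag_named(self):
        table = self._table().drop(columns=["gIsFeatPopnOL"])
        with pytest.raises(QcError, match="gIsFeatPopnOL"):
            qc_filter(table)

    def test_generator_survivor_count(self):
        ids = [f"NM_{i:06d}" for i in range(200)]
        table, manifest = simulate_qc_flags(ids, fail_fraction=0.25, seed=3)
        assert len(qc_filter(table)) == manifest.truths["n_surviving"]


class TestQuantileNormalize:
    def test_hand_example(self):
        matrix = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]})
        out = quantile_normalize(matrix)
        np.testing.assert_allclose(out["s1"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["s2"], [2.5, 3.5, 4.5])

    def test_identical_distributions_unchanged(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(1, 10, 50)
        matrix = pd.DataFrame({"a": col, "b": rng.permutation(col)})
        out = quantile_normalize(matrix)
        np.testing.assert_allclose(np.sort(out["a"]), np.sort(col))
        np.testing.assert_allclose(out["a"], matrix["a"])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        matrix = pd.DataFrame(rng.lognormal(2, 1, size=(40, 4)),
                              columns=list("abcd"))
        once = quantile_normalize(matrix)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), rtol=1e-12)

    def test_column_means_equal_after(self):
        rng = np.random.default_rng(2)
        matrix = pd.DataFrame(rng.lognormal(3, 0.7, size=(30, 3)))
        out = quantile_normalize(matrix)
        means = out.mean(axis=0).to_numpy()
        np.testing.assert_allclose(means, means[0])

    def test_ranks_preserved(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(rng.uniform(1, 5, size=(25, 2)))
        out = quantile_normalize(matrix)
        for col in matrix:
            assert (matrix[col].rank() == out[col].rank()).all()

    def test_ties_get_mean_of_tied_targets(self):
        matrix = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(matrix)
        # sorted means: [1.5, 2.5, 5.5]; tied pair in 'a' -> mean(1.5, 2.5)
        np.testing.assert_allclose(out["a"], [2.0, 2.0, 5.5])

    def test_nonpositive_rejected(self):
        with pytest.raises(SirmsdError):
            quantile_normalize(pd.DataFrame({"a": [1.0, -1.0]}))


class TestRankSum:
    def test_small_sample_matches_enumeration_oracle(self):
        a = [1.2, 3.4, 0.7, 5.1, 2.2]
        b = [4.4, 6.1, 5.9, 8.0, 7.3]
        assert rank_sum_test(np.array(a), np.array(b)) == pytest.approx(
            ranksum_exact_p(a, b), rel=1e-9)

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
        assert rank_sum_test(a, b) == pytest.approx(rank_sum_test(b, a))


class TestOffTargetMagnitude:
    def _matrix(self, n=60, seed=0, shift=0.0, n_sm=12):
        rng = np.random.default_rng(seed)
        mock = rng.lognormal(8, 1, n)
        sm = np.zeros(n, dtype=bool)
        sm[:n_sm] = True
        treated = mock * (2.0 ** (shift * sm))
        idx = pd.Index([f"NM_{i}" for i in range(n)])
        return (pd.DataFrame({"mock": mock, "treated": treated}, index=idx),
                pd.Series(sm, index=idx))

    def test_treated_equal_mock_is_null(self):
        matrix, sm = self._matrix()
        summary, cumulative, ma = offtarget_magnitude(matrix, sm, "treated", "mock")
        assert summary.difference == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(ma["M"], 0.0)

    def test_uniform_sm_shift_recovered_exactly(self):
        matrix, sm = self._matrix(shift=-1.0)
        summary, _, _ = offtarget_magnitude(matrix, sm, "treated", "mock")
        assert summary.difference == pytest.approx(-1.0, rel=1e-12)
        assert summary.n_sm == 12 and summary.n_nonsm == 48

    def test_reordering_invariance(self):
        matrix, sm = self._matrix(shift=-0.6, seed=5)
        base, _, _ = offtarget_magnitude(matrix, sm, "treated", "mock")
        rng = np.random.default_rng(9)
        order = rng.permutation(matrix.index)
        shuffled, _, _ = offtarget_magnitude(matrix.loc[order], sm.loc[order],
                                             "treated", "mock")
        assert shuffled.difference == pytest.approx(base.difference, rel=1e-12)
        assert shuffled.p_wilcoxon == pytest.approx(base.p_wilcoxon, rel=1e-9)

    def test_empty_group_rejected(self):
        matrix, sm = self._matrix()
        with pytest.raises(SirmsdError):
            offtarget_magnitude(matrix, pd.Series(False, index=matrix.index),
                                "treated", "mock")

    def test_cumulative_fraction_structure(self):
        matrix, sm = self._matrix(shift=-1.0)
        _, cumulative, _ = offtarget_magnitude(matrix, sm, "treated", "mock")
        for group, sub in cumulative.groupby("group"):
            assert sub["l2fc"].is_monotonic_increasing
            assert sub["cumulative_fraction"].iloc[-1] == pytest.approx(1.0)

    def test_simulated_effect_converges_with_n(self):
        fixture = simulate_expression(n_transcripts=2000, effect_l2fc=-0.8,
                                      noise_sd=0.25, utr_length=30, seed=11)
        summary, _, _ = offtarget_magnitude(fixture.matrix, fixture.sm,
                                            "treated", "mock")
        se = np.sqrt(2) * 0.25 * np.sqrt(1 / summary.n_sm + 1 / summary.n_nonsm)
        assert abs(summary.difference - (-0.8)) <= 3 * se
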