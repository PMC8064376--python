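"""Paired t, BH adjustment and the placebo-concordance filter vs. independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import peepkit as pk
from conftest import make_matrix, make_metadata


def bh_step_up(p):
    """Brute-force Benjamini–Hochberg step-up (independent of statsmodels)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


def paired_meta(n_subjects, arm="case"):
    rows = []
    for i in range(n_subjects):
        subj = f"p{i}"
        rows.append((f"{subj}_pre", subj, arm, "pre"))
        rows.append((f"{subj}_post", subj, arm, "post"))
    return make_metadata(rows)


def matrix_from_deltas(deltas, arm="case"):
    """Pre samples at 0, post samples equal to the deltas."""
    deltas = np.atleast_2d(np.asarray(deltas, dtype=float))
    n = deltas.shape[1]
    meta = paired_meta(n, arm)
    values = np.zeros((deltas.shape[0], 2 * n))
    samples = []
    for i in range(n):
        samples += [f"p{i}_pre", f"p{i}_post"]
        values[:, 2 * i + 1] = deltas[:, i]
    return make_matrix(values, samples=samples), meta


class TestPairedT:
    def test_textbook_deltas(self):
        matrix, meta = matrix_from_deltas([2.0, 4.0, 6.0])
        result = pk.paired_t(matrix, meta, "case")
        row = result.table.iloc[0]
        # t = mean / (sd / sqrt(n)) = 4 / (2 / sqrt(3))
        assert row.t == pytest.approx(4 / (2 / np.sqrt(3)), abs=1e-12)
        assert result.n_pairs == 3
        assert row.p_value == pytest.approx(2 * stats.t.sf(abs(row.t), df=2), abs=1e-15)

    def test_matches_scipy_ttest_rel_on_simulated_trial(self, default_trial):
        _, matrix, meta, _ = default_trial
        for arm in ("case", "control"):
            result = pk.paired_t(matrix, meta, arm)
            subjects = meta.paired_subjects(arm)
            pre = matrix.data[[meta.sample_id(s, "pre") for s in subjects]].to_numpy()
            post = matrix.data[[meta.sample_id(s, "post") for s in subjects]].to_numpy()
            t_ref, p_ref = stats.ttest_rel(post, pre, axis=1)
            np.testing.assert_allclose(result.table["t"].to_numpy(), t_ref, atol=1e-10)
            np.testing.assert_allclose(result.table["p_value"].to_numpy(), p_ref, atol=1e-10)

    def test_zero_variance_gene_flagged_with_p_one(self):
        matrix, meta = matrix_from_deltas([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]])
        result = pk.paired_t(matrix, meta, "case")
        degenerate = result.table.iloc[0]
        assert degenerate.zero_variance
        assert degenerate.p_value == 1.0
        assert not result.table.iloc[1].zero_variance

    def test_fewer_than_two_pairs_is_an_error(self):
        matrix, meta = matrix_from_deltas([1.0])
        with pytest.raises(pk.ValidationError, match="pairs"):
            pk.paired_t(matrix, meta, "case")

    def test_genes_with_missing_values_excluded_and_counted(self):
        matrix, meta = matrix_from_deltas([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        data = matrix.data.copy()
        data.iloc[0, 0] = np.nan
        result = pk.paired_t(pk.ExpressionMatrix(data), meta, "case")
        assert result.n_excluded_missing == 1
        assert list(result.table.index) == ["g1"]


class TestBHAdjust:
    def test_hand_computed_example(self):
        q = pk.bh_adjust([0.01, 0.02, 0.04, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.5], atol=1e-12)

    @pytest.mark.parametrize(
        "p, expected",
        [([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]), ([0.3], [0.3])],
    )
    def test_degenerate_inputs(self, p, expected):
        np.testing.assert_allclose(pk.bh_adjust(p), expected, atol=1e-15)

    @pytest.mark.parametrize("bad", [[-0.1], [1.5], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(pk.ValidationError):
            pk.bh_adjust(bad)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=1000))
    @settings(max_examples=100, deadline=None)
    def test_equals_brute_force_step_up(self, p):
        np.testing.assert_allclose(pk.bh_adjust(p), bh_step_up(p), atol=1e-10)


def de_from_rows(rows):
    """rows: gene -> (p, mean_delta); build a minimal DEResult."""
    table = pd.DataFrame(
        {
            "mean_delta": {g: m for g, (p, m) in rows.items()},
            "t": 0.0,
            "p_value": {g: p for g, (p, m) in rows.items()},
            "q_value": 1.0,
            "n_pairs": 5,
            "direction": {g: int(np.sign(m)) for g, (p, m) in rows.items()},
            "zero_variance": False,
        }
    )
    return pk.DEResult(arm="x", table=table, n_pairs=5)


class TestPlaceboFilter:
    def test_concordant_significant_gene_removed_discordant_retained(self):
        case = de_from_rows({"g1": (0.01, 1.0), "g2": (0.01, 1.0), "g3": (0.5, 1.0)})
        control = de_from_rows({"g1": (0.01, 2.0), "g2": (0.01, -2.0), "g3": (0.01, 1.0)})
        result = pk.placebo_filter(case, control)
        assert result.panel_set == {"g2"}  # significant both arms, opposite signs
        assert set(result.removed) == {"g1"}  # same direction in both arms
        assert result.n_case_significant == 2

    def test_panel_is_subset_of_case_significant_and_order_invariant(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(50)]
        rows_case = {g: (rng.uniform(), rng.normal()) for g in genes}
        rows_ctrl = {g: (rng.uniform(), rng.normal()) for g in genes}
        result = pk.placebo_filter(de_from_rows(rows_case), de_from_rows(rows_ctrl))
        sig = {g for g, (p, _) in rows_case.items() if p <= 0.05}
        assert result.panel_set <= sig
        shuffled = list(genes)
        rng.shuffle(shuffled)
        result2 = pk.placebo_filter(
            de_from_rows({g: rows_case[g] for g in shuffled}),
            de_from_rows({g: rows_ctrl[g] for g in shuffled}),
        )
        assert result2.panel_set == result.panel_set
        assert set(result2.removed) == set(result.removed)

    def test_mismatched_gene_universes_rejected(self):
        case = de_from_rows({"g1": (0.01, 1.0)})
        control = de_from_rows({"g2": (0.01, 1.0)})
        with pytest.raises(pk.ValidationError, match="universe"):
            pk.placebo_filter(case, control)

    def test_planted_placebo_genes_removed_from_significant_set(self, default_trial, default_analysis):
        *_, truth = default_trial
        panel = default_analysis["panel"]
        case_de = default_analysis["case_de"]
        assert not truth.placebo_genes & panel.panel_set
        sig_placebo = truth.placebo_genes & case_de.significant(panel.alpha)
        assert sig_placebo  # the drift is detectable in the treated arm
        assert sig_placebo <= set(panel.removed)
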