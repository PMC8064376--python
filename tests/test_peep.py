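"""Perturbation z-profiles: reference fitting, calls, invariances."""

import numpy as np
import pandas as pd
import pytest

import peepkit as pk
from conftest import make_matrix, make_metadata


@pytest.fixture
def tiny_trial():
    """One treated subject (post value configurable), three control-post refs."""

    def build(case_post_value, ref_values=(10.0, 12.0, 14.0)):
        samples = ["c1_pre", "c1_post"] + [f"r{i}_post" for i in range(len(ref_values))]
        values = [[9.0, case_post_value, *ref_values]]
        rows = [("c1_pre", "c1", "case", "pre"), ("c1_post", "c1", "case", "post")]
        rows += [(f"r{i}_post", f"r{i}", "control", "post") for i in range(len(ref_values))]
        return make_matrix(values, genes=["gA"], samples=samples), make_metadata(rows)

    return build


class TestFitReference:
    def test_location_and_scale_are_mean_and_sample_sd(self, tiny_trial):
        matrix, meta = tiny_trial(0.0)
        ref = pk.fit_reference(matrix, meta, ["gA"])
        row = ref.table.loc["gA"]
        assert row.location == pytest.approx(12.0)
        assert row.scale == pytest.approx(2.0)
        assert row.n_reference == 3
        assert row.usable

    def test_constant_reference_gene_flagged_unusable(self, tiny_trial):
        matrix, meta = tiny_trial(0.0, ref_values=(5.0, 5.0, 5.0))
        ref = pk.fit_reference(matrix, meta, ["gA"])
        assert not ref.table.loc["gA", "usable"]
        with pytest.raises(pk.ValidationError, match="usable"):
            pk.compute_profiles(matrix, meta, ref)

    def test_too_few_reference_samples_rejected(self, tiny_trial):
        matrix, meta = tiny_trial(0.0, ref_values=(1.0, 2.0))
        with pytest.raises(pk.ValidationError, match=">= 3"):
            pk.fit_reference(matrix, meta, ["gA"])

    def test_unknown_panel_gene_rejected(self, tiny_trial):
        matrix, meta = tiny_trial(0.0)
        with pytest.raises(pk.ValidationError, match="not in matrix"):
            pk.fit_reference(matrix, meta, ["nope"])

    def test_reference_modes_select_expected_samples(self, default_trial):
        _, matrix, meta, _ = default_trial
        sizes = {"control_post": 14, "control_all": 28, "case_pre": 10}
        for mode, n in sizes.items():
            ref = pk.fit_reference(matrix, meta, matrix.gene_ids[:5], mode)
            assert int(ref.table["n_reference"].iloc[0]) == n
            assert ref.mode == mode

    def test_reference_location_tracks_simulated_baseline(self, default_trial):
        design, matrix, meta, truth = default_trial
        plain = sorted(set(matrix.gene_ids) - truth.module_genes - truth.placebo_genes)[:200]
        ref = pk.fit_reference(matrix, meta, plain)
        # reference mean across many null genes is centred on the simulated
        # baseline mean within Monte-Carlo error
        spread = ref.table["location"].std(ddof=1) / np.sqrt(len(plain))
        assert abs(ref.table["location"].mean() - design.baseline_mean) < 4 * spread


class TestComputeProfiles:
    def test_boundary_z_of_two_is_called_up(self, tiny_trial):
        matrix, meta = tiny_trial(16.0)  # (16 - 12) / 2 = 2.0, inclusive threshold
        ref = pk.fit_reference(matrix, meta, ["gA"])
        (profile,) = pk.compute_profiles(matrix, meta, ref)
        assert profile.z["gA"] == pytest.approx(2.0)
        assert profile.up_calls == {"gA"}
        assert not profile.down_calls

    def test_post_at_reference_mean_gives_zero_and_no_call(self, tiny_trial):
        matrix, meta = tiny_trial(12.0)
        ref = pk.fit_reference(matrix, meta, ["gA"])
        (profile,) = pk.compute_profiles(matrix, meta, ref)
        assert profile.z["gA"] == pytest.approx(0.0)
        assert not profile.up_calls and not profile.down_calls

    def test_z_matches_brute_force_recomputation(self, default_trial, default_analysis):
        _, matrix, meta, _ = default_trial
        profiles = default_analysis["profiles"]
        ref_samples = meta.samples_for(arm="control", timepoint="post")
        for profile in profiles[:3]:
            post = meta.sample_id(profile.subject_id, "post")
            for gene in profile.z.index[:50]:
                ref_values = matrix.data.loc[gene, ref_samples].to_numpy()
                expected = (matrix.data.loc[gene, post] - ref_values.mean()) / ref_values.std(ddof=1)
                assert profile.z[gene] == pytest.approx(expected, abs=1e-10)

    def test_profiles_invariant_to_gene_and_sample_order(self, default_trial):
        _, matrix, meta, _ = default_trial
        panel = matrix.gene_ids[:40]
        rng = np.random.default_rng(0)
        shuffled = pk.ExpressionMatrix(
            matrix.data.sample(frac=1.0, axis=0, random_state=1).sample(
                frac=1.0, axis=1, random_state=2
            )
        )
        ref_a = pk.fit_reference(matrix, meta, panel)
        ref_b = pk.fit_reference(shuffled, meta, list(rng.permutation(panel)))
        prof_a = pk.compute_profiles(matrix, meta, ref_a)
        prof_b = pk.compute_profiles(shuffled, meta, ref_b)
        for a, b in zip(prof_a, prof_b):
            assert a.subject_id == b.subject_id
            pd.testing.assert_series_equal(a.z.sort_index(), b.z.sort_index(), atol=1e-12)

    def test_subject_without_post_sample_skipped_with_warning(self, tiny_trial, caplog):
        matrix, meta = tiny_trial(16.0)
        extra = meta.samples.copy()
        extra.loc["c2_pre"] = {"subject_id": "c2", "arm": "case", "timepoint": "pre",
                               "fev1_pre": np.nan, "fev1_post": np.nan}
        matrix2 = pk.ExpressionMatrix(
            matrix.data.assign(c2_pre=8.0)
        )
        profiles = pk.compute_profiles(matrix2, pk.TrialMetadata(extra),
                                       pk.fit_reference(matrix2, pk.TrialMetadata(extra), ["gA"]))
        assert [p.subject_id for p in profiles] == ["c1"]

    def test_strong_responders_repress_module_genes_far_above_null_rate(
        self, default_trial, default_analysis
    ):
        *_, truth = default_trial
        panel_module = None
        rates = []
        for profile in default_analysis["profiles"]:
            if truth.subject_strata[profile.subject_id] != "strong":
                continue
            module_in_panel = truth.module_genes & set(profile.z.index)
            panel_module = module_in_panel
            rates.append(len(profile.down_calls & module_in_panel) / len(module_in_panel))
        assert panel_module  # some module genes survive the panel filter
        assert min(rates) > 0.5  # null down-call rate is ~0.04


class TestSharedCalls:
    def test_intersection_and_union_semantics(self):
        z1 = pd.Series({"a": -3.0, "b": -2.5, "c": -2.1, "d": 0.0})
        z2 = pd.Series({"a": 0.0, "b": -4.0, "c": -2.0, "d": 3.0})
        p1 = pk.PeepProfile("s1", z1)
        p2 = pk.PeepProfile("s2", z2)
        assert pk.shared_calls([p1, p2], "down") == {"b", "c"}
        assert pk.union_calls([p1, p2], "down") == {"a", "b", "c"}
        assert pk.shared_calls([p1, p2], "up") == frozenset()
        assert pk.shared_calls([p1], "down") == p1.down_calls

    def test_empty_profile_list_rejected(self):
        with pytest.raises(pk.ValidationError):
            pk.shared_calls([], "down")

    def test_frame_round_trip(self, default_analysis):
        profiles = default_analysis["profiles"]
        frame = pk.profiles_to_frame(profiles)
        again = pk.profiles_from_frame(frame)
        assert [p.subject_id for p in again] == [p.subject_id for p in profiles]
        assert again[0].down_calls == profiles[0].down_calls
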