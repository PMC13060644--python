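"""Normalization chain: reference selection, rank-invariant correction, pooling,
bridging, replicate collapsing, and their algebraic invariants."""

import numpy as np
import pandas as pd
import pytest

from combiphos.io import MultiplexMatrix
from combiphos.normalize import (
    bridge_multiplexes,
    collapse_replicates,
    compute_pool,
    find_median_channel,
    iron_pairwise,
    normalize_multiplex,
)
from combiphos.simulate import TmtSimConfig, simulate_tmt


def _matrix(vals, channels, run_id="run1"):
    df = pd.DataFrame(
        np.asarray(vals, dtype=float),
        index=[f"F{i:03d}" for i in range(len(vals))],
        columns=channels,
    )
    return MultiplexMatrix(run_id=run_id, intensities=df)


class TestFindMedianChannel:
    def test_identical_channels_tie_break_to_first(self):
        x = 2.0 ** np.random.default_rng(0).normal(20, 2, 30)
        m = _matrix(np.column_stack([x, x, x]), ["126C", "127N", "127C"])
        assert find_median_channel(m) == "126C"

    def test_two_identical_one_shuffled(self):
        rng = np.random.default_rng(1)
        x = 2.0 ** rng.normal(20, 2, 40)
        shuffled = rng.permutation(x)
        m = _matrix(np.column_stack([x, x, shuffled]), ["126C", "127N", "127C"])
        assert find_median_channel(m) in ("126C", "127N")

    def test_matches_brute_force_argmax(self, small_sim):
        matrices, *_ = small_sim
        m = matrices[0]
        log2 = np.log2(m.intensities)
        cols = list(log2.columns)
        means = []
        for c in cols:
            rs = []
            for d in cols:
                if c == d:
                    continue
                both = log2[[c, d]].dropna()
                rs.append(np.corrcoef(both[c], both[d])[0, 1])
            means.append(np.nanmean(rs))
        expected = cols[int(np.argmax(means))]
        assert find_median_channel(m) == expected

    def test_rejects_without_complete_pairs(self):
        vals = np.array([[1.0, np.nan], [np.nan, 2.0], [3.0, np.nan]])
        df = pd.DataFrame(vals, index=["a", "b", "c"], columns=["126C", "127N"])
        m = MultiplexMatrix(run_id="r", intensities=df)
        with pytest.raises(ValueError, match="pairwise-complete"):
            find_median_channel(m)


class TestIronPairwise:
    @pytest.mark.parametrize("mode", ["global", "curve"])
    def test_identity_correction_is_zero(self, mode):
        rng = np.random.default_rng(2)
        x = 2.0 ** rng.normal(20, 2, 200)
        corrected, curve = iron_pairwise(x, x, mode=mode)
        assert np.allclose(np.log2(corrected) - np.log2(x), 0.0, atol=1e-9)
        assert curve.is_zero

    @pytest.mark.parametrize("mode", ["global", "curve"])
    def test_pure_global_scale_removed(self, mode):
        rng = np.random.default_rng(3)
        ref = 2.0 ** rng.normal(20, 2, 200)
        target = 4.0 * ref
        corrected, _ = iron_pairwise(target, ref, mode=mode)
        assert np.allclose(np.log2(corrected), np.log2(ref), atol=1e-9)

    def test_planted_distortion_slope_recovered(self):
        # intensity-dependent distortion: ratio = slope * (x - mean x); the fitted
        # curve must leave |median residual| <= 0.01 and match the slope's sign
        rng = np.random.default_rng(4)
        x = rng.normal(20, 2, 600)
        slope = 0.03
        ref = 2.0**x
        target = 2.0 ** (x + slope * (x - x.mean()) + rng.normal(0, 0.05, x.size))
        corrected, curve = iron_pairwise(target, ref, mode="curve")
        resid = np.log2(corrected) - np.log2(ref)
        assert abs(np.median(resid)) <= 0.01
        far = np.abs(curve.knots_x - x.mean()) > 1.0
        expected_sign = np.sign(slope * (curve.knots_x[far] - x.mean()))
        assert (np.sign(curve.knots_y[far]) == expected_sign).all()

    def test_too_few_shared_features_rejected(self):
        x = np.array([1.0, 2, 4, 8, np.nan, np.nan, np.nan, np.nan])
        y = np.array([1.0, 2, 4, np.nan, 8, 16, 32, 64])
        with pytest.raises(ValueError, match="both channels"):
            iron_pairwise(x, y)


class TestNormalizeMultiplex:
    def test_identical_channels_pass_through(self):
        x = 2.0 ** np.random.default_rng(5).normal(20, 2, 100)
        m = _matrix(np.column_stack([x, x]), ["126C", "127N"])
        nm = normalize_multiplex(m)
        assert np.allclose(
            np.log2(nm.intensities), np.log2(m.intensities), atol=1e-9
        )

    def test_reference_override_leaves_reference_unchanged(self, small_sim):
        matrices, *_ = small_sim
        nm = normalize_multiplex(matrices[0], reference="130C")
        assert nm.reference_channel == "130C"
        ref_in = matrices[0].intensities["130C"]
        ref_out = nm.intensities["130C"]
        assert ((ref_in == ref_out) | ref_in.isna()).all()
        assert nm.curves["130C"].is_zero

    def test_invariant_residuals_within_tolerance_on_simulated_run(self, small_sim):
        matrices, *_ = small_sim
        nm = normalize_multiplex(matrices[0])
        ref = np.log2(nm.intensities[nm.reference_channel])
        for ch in nm.channel_ids:
            if ch == nm.reference_channel:
                continue
            resid = (np.log2(nm.intensities[ch]) - ref).dropna()
            assert abs(resid.median()) <= 0.05  # median over all shared features

    def test_idempotent_in_global_mode(self, small_sim):
        matrices, *_ = small_sim
        first = normalize_multiplex(matrices[0], mode="global")
        second = normalize_multiplex(first, reference=first.reference_channel,
                                     mode="global")
        for ch, curve in second.curves.items():
            assert np.all(np.abs(curve.knots_y) < 1e-6)

    def test_channel_permutation_changes_no_numbers(self, small_sim):
        matrices, *_ = small_sim
        m = matrices[0]
        perm = list(m.intensities.columns[::-1])
        m_perm = MultiplexMatrix(run_id=m.run_id, intensities=m.intensities[perm])
        a = normalize_multiplex(m)
        b = normalize_multiplex(m_perm)
        assert a.reference_channel == b.reference_channel
        pd.testing.assert_frame_equal(
            a.intensities, b.intensities[a.intensities.columns]
        )


class TestPool:
    def test_two_point_geometric_mean(self):
        m = _matrix([[4.0, 16.0]], ["126C", "127N"])
        assert compute_pool(m).iloc[0] == pytest.approx(8.0)

    def test_missing_channels_skipped(self):
        m = _matrix([[8.0, np.nan]], ["126C", "127N"])
        assert compute_pool(m).iloc[0] == pytest.approx(8.0)

    def test_random_row_matches_brute_force(self):
        rng = np.random.default_rng(6)
        row = 2.0 ** rng.normal(20, 2, 18)
        m = _matrix([row], [f"ch{i}" for i in range(18)])
        expected = 2.0 ** np.mean(np.log2(row))
        assert compute_pool(m).iloc[0] == pytest.approx(expected, rel=1e-12)


class TestBridging:
    def test_pool_ratio_geometric_mean_is_one(self, small_sim):
        matrices, *_ = small_sim
        nm = normalize_multiplex(matrices[0])
        pool = compute_pool(nm)
        ratios = nm.intensities.div(pool, axis=0)
        log_gm = np.log2(ratios).mean(axis=1, skipna=True).dropna()
        assert np.allclose(log_gm, 0.0, atol=1e-9)

    def test_duplicated_run_bridges_to_identical_abundances(self):
        # run2 = 2 x run1 cell-for-cell: after bridging both runs agree exactly
        rng = np.random.default_rng(7)
        vals = 2.0 ** rng.normal(20, 2, size=(40, 3))
        m1 = _matrix(vals, ["126C", "127N", "127C"], run_id="run1")
        m2 = _matrix(2.0 * vals, ["126C", "127N", "127C"], run_id="run2")
        n1 = normalize_multiplex(m1, reference="126C")
        n2 = normalize_multiplex(m2, reference="126C")
        bridged = bridge_multiplexes([n1, n2])
        pd.testing.assert_frame_equal(bridged["run1"], bridged["run2"], atol=1e-9,
                                      rtol=1e-9, check_exact=False)

    def test_hand_computed_toy_bridging(self):
        # 3 features x 2 channels, run2 globally 2x run1: bridged abundances are
        # the per-run ratios times the cross-run pool geometric mean
        vals = np.array([[4.0, 16.0], [8.0, 8.0], [2.0, 32.0]])
        m1 = _matrix(vals, ["126C", "127N"], run_id="run1")
        m2 = _matrix(2 * vals, ["126C", "127N"], run_id="run2")
        # normalization with identical channel structure: use global mode with
        # relaxed minimums via direct bridging of already-normalized matrices
        from combiphos.normalize import NormalizedMultiplex, MIN_PAIRWISE

        # bypass iron (only 3 features) by treating inputs as already normalized
        n1 = NormalizedMultiplex("run1", m1.intensities, "126C")
        n2 = NormalizedMultiplex("run2", m2.intensities, "126C")
        pools = {"run1": compute_pool(n1), "run2": compute_pool(n2)}
        m_f = 2.0 ** ((np.log2(pools["run1"]) + np.log2(pools["run2"])) / 2)
        expected_run1 = m1.intensities.div(pools["run1"], axis=0).mul(m_f, axis=0)
        expected_run2 = m2.intensities.div(pools["run2"], axis=0).mul(m_f, axis=0)
        # both runs identical after bridging (pure global shift between runs)
        pd.testing.assert_frame_equal(expected_run1, expected_run2, atol=1e-12)
        # and the per-run ratio structure is preserved: ratio of channels equals raw
        r1 = expected_run1["126C"] / expected_run1["127N"]
        assert np.allclose(r1, vals[:, 0] / vals[:, 1])

    def test_bridging_preserves_within_run_channel_ratios(self, small_sim):
        matrices, *_ = small_sim
        normalized = [normalize_multiplex(m) for m in matrices]
        bridged = bridge_multiplexes(normalized)
        for nm in normalized:
            pre = nm.intensities
            post = bridged[nm.run_id]
            pre_ratio = pre.iloc[:, 0] / pre.iloc[:, 1]
            post_ratio = post.iloc[:, 0] / post.iloc[:, 1]
            ok = pre_ratio.notna() & post_ratio.notna()
            assert np.allclose(pre_ratio[ok], post_ratio[ok], rtol=1e-12)

    def test_bridging_reduces_between_run_sd_on_most_features(self, default_sim):
        matrices, design, _, _ = default_sim
        normalized = [normalize_multiplex(m) for m in matrices]
        bridged = bridge_multiplexes(normalized)
        pre = [np.log2(nm.intensities) for nm in normalized]
        post = [np.log2(bridged[nm.run_id]) for nm in normalized]
        pre_sd = (pre[0] - pre[1]).abs()
        post_sd = (post[0] - post[1]).abs()
        per_feature_pre = pre_sd.mean(axis=1, skipna=True)
        per_feature_post = post_sd.mean(axis=1, skipna=True)
        ok = per_feature_pre.notna() & per_feature_post.notna()
        frac = (per_feature_post[ok] < per_feature_pre[ok]).mean()
        assert frac >= 0.95

    def test_too_few_shared_features_rejected(self):
        vals = np.array([[4.0, 16.0], [8.0, 8.0], [2.0, 32.0]])
        from combiphos.normalize import NormalizedMultiplex

        n1 = NormalizedMultiplex("run1", _matrix(vals, ["a", "b"]).intensities, "a")
        n2 = NormalizedMultiplex("run2", _matrix(vals, ["a", "b"]).intensities, "a")
        with pytest.raises(ValueError, match="share"):
            bridge_multiplexes([n1, n2])


class TestCollapseReplicates:
    def test_single_run_is_log2_passthrough(self, design_18plex):
        rng = np.random.default_rng(8)
        vals = 2.0 ** rng.normal(20, 2, size=(30, 18))
        channels = list(design_18plex.table["channel_id"])
        m = _matrix(vals, channels)
        out = collapse_replicates({"run1": m.intensities}, design_18plex)
        sample_of = dict(zip(design_18plex.table["channel_id"],
                             design_18plex.table["sample_id"]))
        for ch in channels:
            assert np.allclose(out.log2_abundance[sample_of[ch]], np.log2(vals[:, channels.index(ch)]))

    def test_two_injections_average_on_log2_scale(self):
        rows = pd.DataFrame(
            {
                "run_id": ["r1", "r2"],
                "channel_id": ["126C", "126C"],
                "sample_id": ["s1", "s1"],
                "condition": ["DMSO", "DMSO"],
                "bio_rep": [1, 1],
                "injection_rep": [1, 2],
            }
        )
        from combiphos.io import SampleDesign

        design = SampleDesign(rows)
        df1 = pd.DataFrame({"126C": [16.0]}, index=["F1"])
        df2 = pd.DataFrame({"126C": [64.0]}, index=["F1"])
        out = collapse_replicates({"r1": df1, "r2": df2}, design)
        assert out.log2_abundance.loc["F1", "s1"] == pytest.approx(5.0)

    def test_simulated_pair_matches_brute_force(self, small_sim):
        matrices, design, _, _ = small_sim
        bridged = {m.run_id: m.intensities for m in matrices}
        out = collapse_replicates(bridged, design)
        # brute force: mean of log2 across the two runs per channel, skipping NaN
        t = design.table
        for sid in t["sample_id"].unique()[:5]:
            sub = t[t["sample_id"] == sid]
            cols = [np.log2(bridged[r][c]) for r, c in zip(sub["run_id"], sub["channel_id"])]
            expected = pd.concat(cols, axis=1).mean(axis=1, skipna=True)
            pd.testing.assert_series_equal(
                out.log2_abundance[sid], expected, check_names=False
            )

    def test_unassigned_channel_rejected_with_offenders(self, design_18plex):
        df = pd.DataFrame(
            2.0 ** np.random.default_rng(9).normal(20, 2, size=(5, 2)),
            index=list("abcde"), columns=["126C", "999X"],
        )
        with pytest.raises(ValueError, match="run1.999X"):
            collapse_replicates({"run1": df}, design_18plex)
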