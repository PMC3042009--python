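"""Assay arithmetic: blot normalization, replicate summaries, qPCR, RSNC, volumes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import two_pass_mean_sem
from stat1kin import (
    ModelDomainError,
    blot_normalize,
    qpcr_relative_expression,
    rsnc_from_cells,
    summarize_replicates,
    tumor_volume,
)
from stat1kin.assay import average_technical_replicates


def blot_frame(target, loading, replicate=1):
    return pd.DataFrame(
        {
            "replicate": replicate,
            "time_min": np.arange(len(target), dtype=float) * 30.0,
            "target_signal": target,
            "loading_signal": loading,
        }
    )


class TestBlotNormalize:
    def test_two_point_arithmetic(self):
        out = blot_normalize(blot_frame([2.0, 4.0], [1.0, 1.0]))
        np.testing.assert_allclose(out["value"], [2 / 3, 4 / 3])

    def test_loading_proportional_to_target_flattens(self):
        target = np.array([1.0, 3.0, 7.0])
        out = blot_normalize(blot_frame(target, 0.5 * target))
        np.testing.assert_allclose(out["value"], 1.0)

    def test_invariant_to_constant_loading_rescale(self):
        rng = np.random.default_rng(11)
        target = rng.uniform(0.5, 3.0, 6)
        loading = rng.uniform(0.5, 2.0, 6)
        a = blot_normalize(blot_frame(target, loading))["value"].to_numpy()
        b = blot_normalize(blot_frame(target, 4.2 * loading))["value"].to_numpy()
        # direct-formula oracle
        ratio = target / loading
        expected = ratio / ratio.mean()
        np.testing.assert_allclose(a, expected, rtol=1e-12)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_zero_loading_rejected_with_time_point(self):
        with pytest.raises(ModelDomainError, match="30"):
            blot_normalize(blot_frame([1.0, 1.0], [1.0, 0.0]))

    def test_single_time_point_rejected(self):
        with pytest.raises(ModelDomainError):
            blot_normalize(blot_frame([1.0], [1.0]))


class TestSummarizeReplicates:
    def test_identical_replicates_have_zero_sem(self):
        frame = pd.DataFrame(
            {"replicate": [1, 2, 3, 4], "time_min": 0.0, "value": 1.0}
        )
        out = summarize_replicates(frame)
        assert out["mean"].iloc[0] == 1.0 and out["sem"].iloc[0] == 0.0

    def test_two_replicate_example(self):
        frame = pd.DataFrame(
            {"replicate": [1, 2], "time_min": 0.0, "value": [0.0, 2.0]}
        )
        out = summarize_replicates(frame)
        assert out["mean"].iloc[0] == pytest.approx(1.0)
        assert out["sem"].iloc[0] == pytest.approx(1.0)  # sd sqrt(2) over sqrt(2)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(6)
        values = rng.lognormal(0.0, 0.3, 6)
        frame = pd.DataFrame(
            {"replicate": np.arange(6), "time_min": 60.0, "value": values}
        )
        out = summarize_replicates(frame)
        mean, sem = two_pass_mean_sem(values)
        assert out["mean"].iloc[0] == pytest.approx(mean, rel=1e-12)
        assert out["sem"].iloc[0] == pytest.approx(sem, rel=1e-12)

    def test_single_replicate_time_point_rejected(self):
        frame = pd.DataFrame(
            {"replicate": [1, 2, 1], "time_min": [0.0, 0.0, 30.0],
             "value": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ModelDomainError, match="30"):
            summarize_replicates(frame)

    def test_rescaling_commutes_with_normalization(self):
        rng = np.random.default_rng(13)
        frames = []
        for rep in range(3):
            frames.append(blot_frame(rng.uniform(1, 4, 5), rng.uniform(0.5, 2, 5),
                                     replicate=rep))
        raw = pd.concat(frames, ignore_index=True)
        scaled = raw.copy()
        # per-replicate global intensity rescale drops out of the chain
        for rep, c in zip(range(3), (2.0, 0.5, 7.0)):
            sel = scaled["replicate"] == rep
            scaled.loc[sel, ["target_signal", "loading_signal"]] *= c
        a = summarize_replicates(blot_normalize(raw))
        b = summarize_replicates(blot_normalize(scaled))
        pd.testing.assert_frame_equal(a, b)


class TestQPCR:
    @pytest.mark.parametrize(
        "dct,expected", [(0.0, 1.0), (1.0, 0.5), (-1.0, 2.0)]
    )
    def test_delta_ct_identities(self, dct, expected):
        assert qpcr_relative_expression(20.0 + dct, 20.0) == pytest.approx(expected)

    def test_matches_log_domain_oracle(self):
        rng = np.random.default_rng(2)
        ct_t = rng.uniform(18, 35, 10)
        ct_h = rng.uniform(18, 25, 10)
        got = qpcr_relative_expression(ct_t, ct_h)
        expected = np.exp(-(ct_t - ct_h) * np.log(2.0))
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ModelDomainError):
            qpcr_relative_expression(np.nan, 20.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        ct=st.floats(15.0, 35.0),
        bump=st.floats(0.1, 5.0),
        ct_h=st.floats(15.0, 25.0),
    )
    def test_monotone_in_both_cts(self, ct, bump, ct_h):
        assert qpcr_relative_expression(ct + bump, ct_h) < qpcr_relative_expression(
            ct, ct_h
        )
        assert qpcr_relative_expression(ct, ct_h + bump) > qpcr_relative_expression(
            ct, ct_h
        )

    def test_technical_averaging_domains(self):
        frame = pd.DataFrame(
            {
                "replicate": [1, 1], "time_min": [0.0, 0.0], "gene": "SOCS1",
                "ct_target": [24.0, 26.0], "ct_hprt": [20.0, 20.0],
            }
        )
        ct_dom = average_technical_replicates(frame, domain="ct")
        lin_dom = average_technical_replicates(frame, domain="linear")
        assert ct_dom["rel_expr"].iloc[0] == pytest.approx(2.0 ** -5)          # mean Ct 25
        assert lin_dom["rel_expr"].iloc[0] == pytest.approx((2.0**-4 + 2.0**-6) / 2)


class TestRSNC:
    def test_unit_ratio(self):
        cells = pd.DataFrame(
            {"nuc_sum": [10.0], "nuc_area": [10.0], "cyt_sum": [10.0],
             "cyt_area": [10.0]}
        )
        mean, sem, ratios = rsnc_from_cells(cells)
        assert mean == 1.0 and np.isnan(sem)

    def test_area_normalization(self):
        cells = pd.DataFrame(
            {"nuc_sum": [5.0], "nuc_area": [5.0], "cyt_sum": [10.0],
             "cyt_area": [10.0]}
        )
        mean, _, _ = rsnc_from_cells(cells)
        assert mean == pytest.approx(1.0)

    def test_matches_two_pass_oracle_and_brightness_invariance(self):
        rng = np.random.default_rng(21)
        n = 35
        cells = pd.DataFrame(
            {
                "nuc_sum": rng.uniform(5, 20, n),
                "nuc_area": rng.uniform(50, 100, n),
                "cyt_sum": rng.uniform(5, 20, n),
                "cyt_area": rng.uniform(100, 200, n),
            }
        )
        mean, sem, ratios = rsnc_from_cells(cells)
        o_mean, o_sem = two_pass_mean_sem(ratios)
        assert mean == pytest.approx(o_mean, rel=1e-12)
        assert sem == pytest.approx(o_sem, rel=1e-12)
        bright = cells.copy()
        bright[["nuc_sum", "cyt_sum"]] *= 13.0
        mean_b, sem_b, _ = rsnc_from_cells(bright)
        assert mean_b == pytest.approx(mean, rel=1e-12)
        assert sem_b == pytest.approx(sem, rel=1e-12)

    def test_zero_cytoplasm_names_cell(self):
        cells = pd.DataFrame(
            {"nuc_sum": [1.0, 1.0], "nuc_area": [1.0, 1.0],
             "cyt_sum": [1.0, 0.0], "cyt_area": [1.0, 1.0]}
        )
        with pytest.raises(ModelDomainError, match="cell 1"):
            rsnc_from_cells(cells)


class TestTumorVolume:
    def test_unit_dimensions_give_the_shape_constant(self):
        assert tumor_volume(1.0, 1.0) == pytest.approx(0.52)

    def test_hand_arithmetic(self):
        assert tumor_volume(2.0, 3.0) == pytest.approx(4 * 3 * 0.52)

    def test_swaps_and_warns_when_width_exceeds_length(self):
        with pytest.warns(UserWarning, match="swap"):
            v = tumor_volume(3.0, 2.0)
        assert v == pytest.approx(tumor_volume(2.0, 3.0))

    def test_rejects_non_positive_dimensions(self):
        with pytest.raises(ModelDomainError):
            tumor_volume(0.0, 1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(w=st.floats(0.1, 5.0), ell=st.floats(5.0, 20.0), s=st.floats(0.1, 10.0))
    def test_degree_three_homogeneity(self, w, ell, s):
        assert tumor_volume(s * w, s * ell) == pytest.approx(
            s**3 * tumor_volume(w, ell), rel=1e-9
        )
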