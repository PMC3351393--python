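"""Normalization, probe-model fitting and the LCB fold-change statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reprotome import (
    NormalizationError,
    fit_expression_index,
    fold_change_with_ci,
    generate_experiment,
    normalize_to_median_array,
)
from reprotome.probe_model import fold_change_ci_from_summary

from conftest import make_probe_matrix, small_config


def _flat_matrix(means, probes=4):
    """Arrays whose overall mean intensities are exactly `means`."""
    P = probes
    pm = np.tile(np.asarray(means, float), (P, 1)) * 1.5
    mm = np.tile(np.asarray(means, float), (P, 1)) * 0.5
    return make_probe_matrix(pm, mm, probes_per_set=P)


class TestNormalization:
    def test_median_array_is_reference_and_scale_factors(self):
        pm = _flat_matrix([100.0, 180.0, 260.0])
        out, factors = normalize_to_median_array(pm)
        np.testing.assert_allclose(factors.to_numpy(), [1.8, 1.0, 180.0 / 260.0])
        # reference column untouched, others rescaled onto its mean
        np.testing.assert_allclose(out.pm[:, 1], pm.pm[:, 1])
        means = (out.pm.mean(axis=0) + out.mm.mean(axis=0)) / 2
        np.testing.assert_allclose(means, 180.0)

    def test_identical_arrays_are_left_unchanged(self):
        pm = _flat_matrix([150.0, 150.0, 150.0])
        out, factors = normalize_to_median_array(pm)
        np.testing.assert_allclose(factors.to_numpy(), 1.0)
        np.testing.assert_array_equal(out.pm, pm.pm)

    def test_even_count_takes_lower_mean_of_middle_pair(self):
        pm = _flat_matrix([100.0, 200.0])
        out, factors = normalize_to_median_array(pm)
        np.testing.assert_allclose(factors.to_numpy(), [1.0, 0.5])

    def test_all_zero_array_raises_naming_the_array(self):
        pm = _flat_matrix([100.0, 0.0, 260.0])
        with pytest.raises(NormalizationError, match="s1"):
            normalize_to_median_array(pm)

    def test_scale_equivariance_of_fold_changes(self):
        """A global rescaling of every intensity leaves LCBs unchanged."""
        cfg = small_config(n_transcripts=60, target_enriched_size=12,
                           n_activated_offpath=3, n_suppressed=2, marker_panel_size=5)
        probes, _ = generate_experiment(cfg)
        scaled = probes.copy()
        scaled.pm *= 7.3
        scaled.mm *= 7.3
        e1 = fit_expression_index(normalize_to_median_array(probes)[0])
        e2 = fit_expression_index(normalize_to_median_array(scaled)[0])
        cols_t = e1.columns_for("treated", "D14")
        cols_c = e1.columns_for("control", "D14")
        reliable = e1.theta.dropna().index.intersection(e2.theta.dropna().index)
        assert len(reliable) >= 20
        for t in list(reliable)[:20]:
            ci1 = fold_change_with_ci(
                e1.theta.loc[t, cols_c], e1.theta.loc[t, cols_t],
                e1.se.loc[t, cols_c], e1.se.loc[t, cols_t],
            )
            ci2 = fold_change_with_ci(
                e2.theta.loc[t, cols_c], e2.theta.loc[t, cols_t],
                e2.se.loc[t, cols_c], e2.se.loc[t, cols_t],
            )
            np.testing.assert_allclose([ci1.fc, ci1.lcb], [ci2.fc, ci2.lcb], rtol=1e-6)


class TestExpressionIndexFit:
    def test_single_probe_probeset_collapses_to_difference(self):
        pm = np.array([[50.0, 80.0, 110.0]])
        mm = np.array([[10.0, 20.0, 30.0]])
        expr = fit_expression_index(make_probe_matrix(pm, mm, probes_per_set=1))
        np.testing.assert_allclose(expr.theta.iloc[0].to_numpy(), [40.0, 60.0, 80.0])
        np.testing.assert_allclose(expr.se.iloc[0].to_numpy(), 0.0)
        np.testing.assert_allclose(expr.phi["PS000"], [1.0])

    def test_noiseless_rank_one_probeset_recovered_exactly(self):
        # theta = (2, 4) scaled up to stay above the signal floor, phi = (1,1,1)
        theta = np.array([20.0, 40.0])
        y = np.outer(np.ones(3), theta)
        expr = fit_expression_index(make_probe_matrix(y + 5.0, np.full_like(y, 5.0), 3))
        fitted = expr.theta.iloc[0].to_numpy()
        assert fitted[1] / fitted[0] == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(expr.se.iloc[0].to_numpy(), 0.0, atol=1e-9)
        assert np.sum(expr.phi["PS000"] ** 2) == pytest.approx(3.0)

    def test_contaminated_cell_is_masked_and_ratio_restored(self):
        theta = np.array([20.0, 40.0])
        y = np.outer(np.ones(3), theta)
        y[0, 1] *= 100.0  # gross outlier in probe 0, array 1
        expr = fit_expression_index(make_probe_matrix(y + 5.0, np.full_like(y, 5.0), 3))
        mask = expr.outlier_mask["PS000"]
        assert mask[0, 1]
        fitted = expr.theta.iloc[0].to_numpy()
        assert fitted[1] / fitted[0] == pytest.approx(2.0, abs=1e-6)

    def test_phi_normalization_holds_across_probesets(self, noisy_experiment):
        probes, _ = noisy_experiment
        expr = fit_expression_index(probes)
        for t in list(expr.theta.index)[:50]:
            retained = ~expr.outlier_mask[t].all(axis=1)
            ss = np.sum(expr.phi[t][retained] ** 2)
            assert ss == pytest.approx(retained.sum(), abs=1e-6)

    def test_noiseless_theta_tracks_true_signal(self, noiseless_experiment):
        # fit on raw probes: normalization would rescale arrays relative to
        # the simulated signal in a small simulation where the activated
        # fraction is a large share of the total intensity
        probes, truth = noiseless_experiment
        expr = fit_expression_index(probes)
        sids = expr.theta.columns
        for g in truth.activated_ids[:10]:
            t = g + "_at"
            f3, f14 = truth.per_gene_fold[g]
            truth_signal = []
            for s in sids:
                fold = 1.0
                if s.startswith("treated_D3"):
                    fold = f3
                elif s.startswith("treated_D14"):
                    fold = f14
                elif s.startswith("target"):
                    fold = truth.target_fold.get(g, 1.0)
                truth_signal.append(np.exp(truth.log_baseline[g]) * fold)
            r = np.corrcoef(expr.theta.loc[t].to_numpy(), truth_signal)[0, 1]
            assert r > 0.999


class TestFoldChangeCI:
    def test_hand_evaluated_interval(self):
        ci = fold_change_ci_from_summary(300.0, 20.0, 100.0, 10.0, level=0.90)
        assert ci.fc == pytest.approx(3.0)
        assert ci.lcb == pytest.approx(2.294, abs=2e-3)
        assert ci.ucb == pytest.approx(3.984, abs=2e-3)

    def test_degenerate_zero_se_collapses_to_point(self):
        ci = fold_change_with_ci([100.0, 100.0], [100.0, 100.0])
        assert ci.fc == ci.lcb == ci.ucb == 1.0

    def test_floored_denominator_gives_infinite_ucb(self):
        ci = fold_change_ci_from_summary(300.0, 20.0, 10.0, 50.0, level=0.90)
        assert np.isinf(ci.ucb)
        assert ci.lcb <= ci.fc

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        tm=st.floats(1.0, 1e4), ts=st.floats(0.0, 1e3),
        rm=st.floats(1.0, 1e4), rs=st.floats(0.0, 1e3),
        level=st.floats(0.5, 0.99),
    )
    def test_interval_always_brackets_fold_change(self, tm, ts, rm, rs, level):
        ci = fold_change_ci_from_summary(tm, ts, rm, rs, level=level)
        assert ci.lcb <= ci.fc <= ci.ucb

    def test_lcb_monotone_in_se_and_level(self):
        base = fold_change_ci_from_summary(300.0, 20.0, 100.0, 10.0)
        wider = fold_change_ci_from_summary(300.0, 40.0, 100.0, 10.0)
        assert wider.lcb < base.lcb and wider.ucb >= base.ucb
        stricter = fold_change_ci_from_summary(300.0, 20.0, 100.0, 10.0, level=0.99)
        assert stricter.lcb < base.lcb
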