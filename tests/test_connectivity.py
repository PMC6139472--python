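"""HRF, psych factor, deconvolution, detrending, PPI chain, r features."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fcmvpa.connectivity import (
    NodeSignalSet,
    PsychFactor,
    canonical_hrf,
    connectivity_features,
    deconvolve_bold,
    detrend,
    lower_triangle_pairs,
    make_psych_factor,
    ppi_node_series,
)
from fcmvpa.nodes import NodeSpec, VoxelTimeSeriesBlock, build_node_cube, extract_block
from fcmvpa.simulate import SimCohortConfig, default_affine, iter_cohort

from conftest import SMALL_GRID, small_config


def _events(rows):
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])


def _block(series27):
    affine = default_affine((12, 12, 12))
    node = build_node_cube((0, 0, 0), affine, (12, 12, 12))
    return VoxelTimeSeriesBlock(node=node, series=series27, tr=2.0)


class TestCanonicalHRF:
    def test_default_tr2_kernel_length(self, hrf_tr2):
        # 0..32 s inclusive at 2-s steps
        assert len(hrf_tr2) == 17

    def test_finite_and_small_first_sample(self, hrf_tr2):
        assert np.all(np.isfinite(hrf_tr2.values))
        assert abs(hrf_tr2.values[0]) < 1e-6
        assert hrf_tr2.values.sum() > 0

    def test_peak_location_against_fine_grid_density(self):
        """Oracle: the closed-form gamma-difference density on a 1-ms grid.
        Its mode is just below 5 s; the sampled kernel's argmax must land
        on the grid point nearest that mode when the grid contains it
        (tr = 1), and within one sample of it otherwise."""
        t_fine = np.arange(0, 32, 0.001)
        dens = stats.gamma.pdf(t_fine, 6.0) - stats.gamma.pdf(t_fine, 16.0) / 6.0
        t_mode = t_fine[np.argmax(dens)]
        assert 4.5 < t_mode < 5.5
        h1 = canonical_hrf(1.0)
        assert np.argmax(h1.values) * 1.0 == round(t_mode)
        for tr in (1.0, 2.0):
            h = canonical_hrf(tr)
            assert abs(np.argmax(h.values) * tr - t_mode) <= tr

    def test_rejects_non_positive_tr(self):
        with pytest.raises(ValueError):
            canonical_hrf(0.0)

    def test_shape_matches_independent_implementation(self):
        """nilearn's SPM-style double-gamma (different normalization) must
        be a scalar multiple of ours: correlation ~ 1 on the shared grid."""
        nilearn_hrf = pytest.importorskip("nilearn.glm.first_level").spm_hrf
        dt = 0.01
        ours = canonical_hrf(dt).values  # samples at 0, dt, 2dt, ...
        theirs = nilearn_hrf(1.0, oversampling=100)  # samples on linspace(0, 32, n)
        t_theirs = np.linspace(0, 32.0, len(theirs))
        ours_on_their_grid = np.interp(t_theirs, dt * np.arange(len(ours)), ours)
        r = np.corrcoef(ours_on_their_grid, theirs)[0, 1]
        assert r > 0.9999


class TestPsychFactor:
    def test_stick_positions(self):
        ev = _events([(10.0, 4.0, "R-hit"), (20.0, 4.0, "K-hit")])
        psych = make_psych_factor(ev, 20, tr=2.0)
        expected = np.zeros(20)
        expected[5], expected[10] = 1.0, -1.0
        np.testing.assert_array_equal(psych.values, expected)

    def test_no_rk_events_gives_zero_vector(self):
        ev = _events([(0.0, 4.0, "miss"), (4.0, 4.0, "CR")])
        psych = make_psych_factor(ev, 10, tr=2.0)
        np.testing.assert_array_equal(psych.values, np.zeros(10))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sum_equals_rhit_minus_khit_count(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice(["R-hit", "K-hit", "miss", "CR", "FA"], size=40)
        ev = _events([(4.0 * i, 4.0, lab) for i, lab in enumerate(labels)])
        psych = make_psych_factor(ev, 80, tr=2.0)
        assert psych.values.sum() == np.sum(labels == "R-hit") - np.sum(labels == "K-hit")

    def test_opposite_sign_collision_reports_trials(self):
        ev = _events([(10.0, 4.0, "R-hit"), (10.4, 4.0, "K-hit")])
        with pytest.raises(ValueError, match="trials 0 and 1"):
            make_psych_factor(ev, 20, tr=2.0)

    def test_onset_outside_run_rejected(self):
        ev = _events([(100.0, 4.0, "R-hit")])
        with pytest.raises(ValueError, match="outside"):
            make_psych_factor(ev, 10, tr=2.0)


class TestDeconvolve:
    def test_noiseless_round_trip_under_one_percent(self, hrf_tr2):
        rng = np.random.default_rng(0)
        n = rng.standard_normal(360)
        x = np.convolve(n, hrf_tr2.values)  # full-mode convolution
        nhat = deconvolve_bold(x, hrf_tr2, lam=1e-6)
        rel = np.linalg.norm(nhat - n) / np.linalg.norm(n)
        assert rel < 0.01

    def test_zero_input_gives_zero_output(self, hrf_tr2):
        out = deconvolve_bold(np.zeros(100), hrf_tr2, lam="gcv")
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_noisy_round_trip_matches_oracle_ridge(self, hrf_tr2):
        """Monte-Carlo contract at amplitude SNR 10 (noise sd = signal
        sd / 10): the GCV choice must sit within 0.005 correlation of the
        best fixed ridge on a lambda sweep, and recover the truth with
        corr > 0.9 (the information ceiling here is ~0.93)."""
        rng = np.random.default_rng(42)
        n = rng.standard_normal(360)
        sig = np.convolve(n, hrf_tr2.values)
        y = sig + rng.standard_normal(sig.size) * sig.std() / 10
        gcv_corr = np.corrcoef(deconvolve_bold(y, hrf_tr2, lam="gcv"), n)[0, 1]
        oracle = max(
            np.corrcoef(deconvolve_bold(y, hrf_tr2, lam=lam), n)[0, 1]
            for lam in np.logspace(-8, 2, 40)
        )
        assert gcv_corr > 0.9
        assert gcv_corr >= oracle - 0.005

    def test_singular_at_lam_zero_instructs_positive_penalty(self, hrf_tr2):
        y = np.random.default_rng(1).standard_normal(120)
        with pytest.raises(ValueError, match="positive ridge"):
            deconvolve_bold(y, hrf_tr2, lam=0.0, n_out=120)

    def test_batch_matches_single_series(self, hrf_tr2):
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((4, 200))
        batch = deconvolve_bold(Y, hrf_tr2, lam=1e-3)
        for i in range(4):
            np.testing.assert_allclose(
                batch[i], deconvolve_bold(Y[i], hrf_tr2, lam=1e-3), atol=1e-10
            )

    def test_series_shorter_than_kernel_rejected(self, hrf_tr2):
        with pytest.raises(ValueError):
            deconvolve_bold(np.zeros(5), hrf_tr2)


class TestDetrend:
    def test_pure_line_maps_to_zero(self):
        t = np.arange(50, dtype=float)
        np.testing.assert_allclose(detrend(3.0 + 0.25 * t), 0.0, atol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(80)
        once = detrend(y)
        np.testing.assert_allclose(detrend(once), once, atol=1e-10)

    def test_sine_plus_line_recovers_sine_component(self):
        """Oracle: the closed-form least-squares projection of the signal
        onto [1, t] — detrending must equal subtracting that projection."""
        t = np.arange(100, dtype=float)
        y = np.sin(2 * np.pi * t / 25) + 0.7 + 0.03 * t
        Z = np.column_stack([np.ones_like(t), t])
        proj = Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        np.testing.assert_allclose(detrend(y), y - proj, atol=1e-10)
        # residual trend is numerically zero
        slope = np.polyfit(t, detrend(y), 1)[0]
        assert abs(slope) < 1e-10


class TestPPISeries:
    def test_zero_psych_annihilates(self, hrf_tr2):
        rng = np.random.default_rng(3)
        block = _block(rng.standard_normal((27, 100)))
        psych = PsychFactor(values=np.zeros(100), tr=2.0)
        out = ppi_node_series(block, psych, hrf_tr2)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_identical_voxels_equal_single_voxel_result(self, hrf_tr2):
        rng = np.random.default_rng(4)
        row = rng.standard_normal(100)
        block = _block(np.tile(row, (27, 1)))
        psych_vals = np.zeros(100)
        psych_vals[::10] = 1.0
        psych = PsychFactor(values=psych_vals, tr=2.0)
        avg = ppi_node_series(block, psych, hrf_tr2)
        # single-voxel result: same chain on one row
        from fcmvpa.connectivity import _causal_convolve

        neural = detrend(deconvolve_bold(detrend(row), hrf_tr2, lam="gcv", n_out=100))
        single = detrend(_causal_convolve((neural * psych_vals)[None, :], hrf_tr2.values))[0]
        np.testing.assert_allclose(avg, single, atol=1e-8)

    def test_sign_equivariance(self, hrf_tr2):
        """Negating the psych factor negates the PPI series and leaves
        every |r| unchanged."""
        rng = np.random.default_rng(6)
        psych_vals = np.zeros(120)
        psych_vals[5:100:8] = 1.0
        psych_vals[9:100:8] = -1.0
        plus = PsychFactor(values=psych_vals, tr=2.0)
        minus = PsychFactor(values=-psych_vals, tr=2.0)
        sigs_p, sigs_m = [], []
        for _ in range(3):
            block = _block(rng.standard_normal((27, 120)))
            sigs_p.append(ppi_node_series(block, plus, hrf_tr2))
            sigs_m.append(ppi_node_series(block, minus, hrf_tr2))
        np.testing.assert_allclose(np.vstack(sigs_m), -np.vstack(sigs_p), atol=1e-8)
        fp = connectivity_features(NodeSignalSet("s", np.vstack(sigs_p), ("a", "b", "c")))
        fm = connectivity_features(NodeSignalSet("s", np.vstack(sigs_m), ("a", "b", "c")))
        np.testing.assert_allclose(np.abs(fp.values), np.abs(fm.values), atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_effect_edge_couples_ppi_series(self, seed, hrf_tr2):
        """Ground-truth check: the two nodes sharing an injected
        condition-dependent coupling correlate more strongly than any
        uncoupled pair."""
        cfg = small_config(
            n_ctrl=0, n_pp=1, n_nodes=6, effect_edges=(((0, 1), 0.6),),
            base_rho=0.0, seed=100 + seed,
        )
        sub = next(iter(iter_cohort(cfg)))
        psych = make_psych_factor(sub.events, cfg.n_volumes, cfg.tr_seconds)
        nodes = cfg.node_specs()
        sigs = np.vstack(
            [
                ppi_node_series(extract_block(sub.bold_run, nd, tr=2.0), psych, hrf_tr2)
                for nd in nodes
            ]
        )
        R = np.corrcoef(sigs)
        effect_r = R[0, 1]
        others = [R[i, j] for i, j in lower_triangle_pairs(6) if (i, j) != (1, 0)]
        assert effect_r > max(others)


class TestConnectivityFeatures:
    def _signals(self, X, names=None):
        names = names or tuple(f"n{i}" for i in range(X.shape[0]))
        return NodeSignalSet("sub", X, names)

    def test_16_nodes_give_120_features(self):
        rng = np.random.default_rng(7)
        feats = connectivity_features(self._signals(rng.standard_normal((16, 50))))
        assert len(feats.values) == 120
        assert len(feats.edge_pairs) == 120

    def test_identical_series_r_one(self):
        rng = np.random.default_rng(8)
        row = rng.standard_normal(40)
        X = np.vstack([row, row, rng.standard_normal(40)])
        feats = connectivity_features(self._signals(X))
        assert feats.values[feats.edge_pairs.index((1, 0))] == pytest.approx(1.0)

    def test_toy_perfect_and_anti_correlation(self):
        X = np.array([[1.0, 2, 3, 4], [2.0, 4, 6, 8], [4.0, 3, 2, 1]])
        feats = connectivity_features(self._signals(X))
        vals = dict(zip(feats.edge_pairs, feats.values))
        assert vals[(1, 0)] == pytest.approx(1.0)
        assert vals[(2, 0)] == pytest.approx(-1.0)

    def test_matrix_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(9)
        feats = connectivity_features(self._signals(rng.standard_normal((16, 100))))
        R = feats.matrix
        np.testing.assert_allclose(R, R.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(R), 1.0)
        assert np.all(np.abs(feats.values) <= 1.0)

    def test_constant_series_errors_with_node_name(self):
        X = np.vstack([np.ones(30), np.random.default_rng(10).standard_normal(30)])
        with pytest.raises(ValueError, match="flatnode"):
            connectivity_features(self._signals(X, names=("flatnode", "ok")))

    def test_chain_determinism(self, hrf_tr2):
        rng = np.random.default_rng(11)
        series = rng.standard_normal((27, 100))
        psych_vals = np.zeros(100)
        psych_vals[::6] = 1.0
        psych = PsychFactor(values=psych_vals, tr=2.0)
        a = ppi_node_series(_block(series), psych, hrf_tr2)
        b = ppi_node_series(_block(series.copy()), psych, hrf_tr2)
        np.testing.assert_array_equal(a, b)
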