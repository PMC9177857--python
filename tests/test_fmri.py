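"""Event-related GLM: HRF, designs, OLS oracle, group stats, FD, connectivity."""

import numpy as np
import pandas as pd
import pytest

from olfrl import fmri, synth
from olfrl import td as tdm
from olfrl.fmri import (DesignMatrix, benjamini_hochberg_mask,
                        beta_series_connectivity, build_design, convolve_events,
                        extract_beta_series, fit_glm, framewise_displacement,
                        group_stats, image_to_matrix, intersect_maps, mouse_hrf,
                        percent_signal_change, stratify_events, us_event_type)
from olfrl.task import scanner_config, generate_trial_sequence


@pytest.fixture(scope="module")
def scanner():
    seq = generate_trial_sequence(scanner_config(seed=50))
    td = tdm.run_td_session(seq, init="trained")
    n_vols = int((seq["onset"].iloc[-1] + 15.0) / fmri.TR)
    return seq, td, n_vols


class TestHRF:
    def test_unit_peak(self):
        assert mouse_hrf(0.05).max() == pytest.approx(1.0)

    def test_zero_beyond_support(self):
        k = mouse_hrf(0.05, duration=6.0)
        assert len(k) == int(6.0 / 0.05)
        assert k[0] == 0.0

    def test_single_stick_reproduces_shifted_kernel(self):
        tr, ov = 1.0, 10
        # event aligned to the volume grid
        series = convolve_events(np.array([5.0]), None, n_vols=30, tr=tr, oversample=ov)
        kernel = mouse_hrf(tr / ov)[::ov]  # kernel at volume resolution
        np.testing.assert_allclose(series[5 : 5 + len(kernel)], kernel, atol=1e-12)
        np.testing.assert_allclose(series[:5], 0.0)


class TestDesign:
    def test_glm2_column_construction(self, scanner):
        seq, td, n_vols = scanner
        rng = np.random.default_rng(0)
        d = build_design(seq, n_vols, variant="glm2", td=td,
                         lick_times=np.array([4.0]), csf=rng.normal(size=n_vols))
        # 3 CS + 1 history modulator + 4 US + licks + CSF + constant
        assert d.columns == ["CS100", "CS50", "CS0", "CS50xHist", "US_R100",
                             "US_R50", "US_N50", "US_N0", "licks", "csf", "constant"]

    def test_beta_series_has_two_regressors_per_trial(self, scanner):
        seq, td, n_vols = scanner
        d = build_design(seq, n_vols, variant="betaseries")
        assert len(d.event_columns) == 2 * len(seq)  # 120 CS + 120 US

    def test_us_event_types(self):
        assert us_event_type("CS100", True) == "US_R100"
        assert us_event_type("CS50", True) == "US_R50"
        assert us_event_type("CS50", False) == "US_N50"
        assert us_event_type("CS0", False) == "US_N0"

    def test_glm1_requires_td(self, scanner):
        seq, _, n_vols = scanner
        with pytest.raises(ValueError):
            build_design(seq, n_vols, variant="glm1")

    def test_first_trial_modulator_values_by_cue(self, scanner):
        # under trained initial values the first presentations carry
        # V = 0, 0.5, 1 for CS0, CS50, CS100
        seq, td, _ = scanner
        for cs, v in (("CS0", 0.0), ("CS50", 0.5), ("CS100", 1.0)):
            first = td[td["cs"] == cs].iloc[0]
            assert first["V_cs"] == pytest.approx(v)


class TestFit:
    def test_noiseless_recovery_exact(self, scanner):
        seq, td, n_vols = scanner
        d = build_design(seq, n_vols, variant="glm1", td=td)
        rb = pd.DataFrame(
            {"CS": [1.0, 0.2], "CSxV": [0.8, -0.3], "US_R100": [0.5, 0.0],
             "US_R50": [0.9, 0.1]},
            index=["Tu", "aPC"],
        )
        sim = synth.simulate_bold(d, rb, grid_shape=(8, 8, 2), noise_sd=0.0)
        Y, vox = image_to_matrix(sim["data"])
        fit = fit_glm(Y, d)
        lab = sim["labels"].ravel()[vox]
        for i, region in enumerate(["Tu", "aPC"], start=1):
            est = fit.betas.to_numpy()[:, lab == i]
            want = sim["truth"].loc[region].to_numpy()[:, None]
            np.testing.assert_allclose(est, np.broadcast_to(want, est.shape), atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 6))
        Y = rng.normal(size=(40, 9))
        d = pd.DataFrame(X, columns=[f"c{i}" for i in range(6)])
        fit = fit_glm(Y, d)
        oracle = np.linalg.solve(X.T @ X, X.T @ Y)
        np.testing.assert_allclose(fit.betas.to_numpy(), oracle, atol=1e-10)

    def test_rank_deficiency_names_columns(self):
        X = np.ones((20, 2))
        d = pd.DataFrame(X, columns=["constant", "dup"])
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            fit_glm(np.random.default_rng(0).normal(size=20), d)

    def test_orthogonal_nuisance_leaves_betas_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(size=60)
        fit0 = fit_glm(y, pd.DataFrame(X, columns=list("abc")))
        extra = rng.normal(size=60)
        extra -= X @ np.linalg.lstsq(X, extra, rcond=None)[0]  # orthogonalize
        X1 = np.column_stack([X, extra])
        fit1 = fit_glm(y, pd.DataFrame(X1, columns=list("abcd")))
        np.testing.assert_allclose(
            fit1.betas.to_numpy()[:3], fit0.betas.to_numpy(), atol=1e-10
        )

    def test_modulator_invariant_to_mean_shift(self, scanner):
        # mean-centering makes the modulator beta invariant to adding a
        # constant to the modulator values
        seq, td, n_vols = scanner
        d0 = build_design(seq, n_vols, variant="glm1", td=td)
        td_shift = td.copy()
        td_shift["V_cs"] = td_shift["V_cs"] + 5.0
        d1 = build_design(seq, n_vols, variant="glm1", td=td_shift)
        np.testing.assert_allclose(
            d0.X["CSxV"].to_numpy(), d1.X["CSxV"].to_numpy(), atol=1e-10
        )


class TestGroupStats:
    def test_all_zero_betas_give_empty_masks(self):
        res = group_stats(np.zeros((8, 30)))
        assert not res["mask_pos"].any() and not res["mask_neg"].any()

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, size=(12, 100))
        vals[:, :20] += 5.0
        res = group_stats(vals)
        assert res["mask_pos"][:20].all()
        assert res["mask_pos"][20:].mean() < 0.1

    def test_sign_flip_swaps_masks(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0.5, 1, size=(10, 50))
        a = group_stats(vals)
        b = group_stats(-vals)
        np.testing.assert_array_equal(a["mask_pos"], b["mask_neg"])

    def test_fdr_false_positive_rate_at_most_nominal(self):
        rng = np.random.default_rng(4)
        any_fp = []
        for _ in range(200):
            vals = rng.normal(0, 1, size=(10, 40))
            res = group_stats(vals, q=0.05)
            any_fp.append(res["mask_pos"].any())
        # under the global null, P(any rejection) <= q
        assert np.mean(any_fp) <= 0.08

    def test_single_session_fails(self):
        with pytest.raises(ValueError):
            group_stats(np.zeros((1, 10)))


class TestMapsAndPSC:
    def test_intersection_logic(self):
        a = np.array([True, True, False])
        b = np.array([True, False, False])
        np.testing.assert_array_equal(intersect_maps(a, b), [True, False, False])
        np.testing.assert_array_equal(intersect_maps(a, a), a)
        with pytest.raises(ValueError):
            intersect_maps(a, np.array([True]))

    def test_psc_roundtrip_and_scaling(self, scanner):
        seq, td, n_vols = scanner
        d = build_design(seq, n_vols, variant="glm1", td=td)
        # a 1% planted response relative to a baseline of 200
        rb = pd.DataFrame({"CS": [2.0]}, index=["Tu"])
        sim = synth.simulate_bold(d, rb, grid_shape=(6, 6, 2), baseline=200.0,
                                  noise_sd=0.0)
        Y, vox = image_to_matrix(sim["data"])
        fit = fit_glm(Y, d)
        psc = percent_signal_change(fit, "CS", sim["labels"], vox)
        assert psc.loc[0, "psc"] == pytest.approx(1.0, abs=1e-6)

    def test_zero_beta_gives_zero_psc(self, scanner):
        seq, td, n_vols = scanner
        d = build_design(seq, n_vols, variant="glm1", td=td)
        sim = synth.simulate_bold(d, pd.DataFrame({"CS": [0.0]}, index=["Tu"]),
                                  grid_shape=(6, 6, 2), noise_sd=0.0)
        Y, vox = image_to_matrix(sim["data"])
        fit = fit_glm(Y, d)
        psc = percent_signal_change(fit, "CS", sim["labels"], vox)
        assert psc.loc[0, "psc"] == pytest.approx(0.0, abs=1e-9)


class TestMotion:
    def test_constant_parameters_give_zero_fd(self):
        fd = framewise_displacement(np.ones((20, 6)))
        np.testing.assert_allclose(fd, 0.0)
        assert stratify_events(np.array([3.0, 10.0]), fd).all()

    def test_single_jump_formula(self):
        m = np.zeros((10, 6))
        m[5:, 0] = 0.1
        fd = framewise_displacement(m)
        assert fd[5] == pytest.approx(0.1)
        assert fd.sum() == pytest.approx(0.1)

    def test_threshold_sweep_monotone_in_retained_events(self):
        rng = np.random.default_rng(5)
        fd = np.abs(rng.normal(0, 0.05, 200))
        onsets = rng.uniform(0, 200 * fmri.TR - 5, 40)
        kept = [stratify_events(onsets, fd, threshold=th).sum()
                for th in (0.01, 0.05, 0.1, 0.5)]
        assert kept == sorted(kept)


class TestConnectivity:
    def test_region_with_itself_is_unity(self):
        rng = np.random.default_rng(6)
        series = rng.normal(size=(40, 1))
        bs = pd.DataFrame(np.column_stack([series, series]), columns=["a", "b"])
        res = beta_series_connectivity([bs] * 4)
        # perfect correlation is clipped before the Fisher transform
        assert res["group_r"].loc["a", "b"] == pytest.approx(1.0, abs=1e-5)

    def test_shared_latent_gives_positive_group_connectivity(self):
        rng = np.random.default_rng(7)
        sessions = []
        for _ in range(10):
            latent = rng.normal(size=40)
            a = 1.0 * latent + rng.normal(0, 0.5, 40)
            b = 1.0 * latent + rng.normal(0, 0.5, 40)
            c = rng.normal(0, 1, 40)
            sessions.append(pd.DataFrame({"a": a, "b": b, "c": c}))
        res = beta_series_connectivity(sessions)
        assert res["significant"].loc["a", "b"]
        assert res["group_r"].loc["a", "b"] > 0.5
        assert not res["significant"].loc["a", "c"]

    def test_null_rejection_rate_nominal(self):
        rng = np.random.default_rng(8)
        hits = []
        for _ in range(100):
            sessions = [pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
                        for _ in range(10)]
            res = beta_series_connectivity(sessions, alpha=0.05)
            hits.append(bool(res["significant"].loc["a", "b"]))
        assert np.mean(hits) <= 0.1

    def test_too_few_events_rejected(self):
        bs = pd.DataFrame(np.zeros((5, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            beta_series_connectivity([bs])


class TestBetaSeriesEndToEnd:
    def test_shared_trialwise_amplitude_recovered_from_bold(self, scanner):
        # two regions driven by one latent per-trial CS amplitude produce
        # positive beta-series correlation after the full fit
        seq, td, n_vols = scanner
        d = build_design(seq, n_vols, variant="betaseries")
        rng = np.random.default_rng(9)
        latent = rng.normal(1.0, 0.5, size=len(seq))
        cols = {}
        for i, tid in enumerate(seq["trial_index"], start=0):
            cols[f"CS_{int(tid):03d}"] = [latent[i], latent[i], 0.0]
            cols[f"US_{int(tid):03d}"] = [0.3, 0.3, 0.3]
        rb = pd.DataFrame(cols, index=["A", "B", "C"])
        sim = synth.simulate_bold(d, rb, grid_shape=(6, 6, 2), noise_sd=0.05, rng=10)
        Y, vox = image_to_matrix(sim["data"])
        fit = fit_glm(Y, d)
        bs = extract_beta_series(fit, seq, sim["labels"], vox, event="CS",
                                 cs_type="CS100")
        r = np.corrcoef(bs[1], bs[2])[0, 1]
        assert r > 0.5
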