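"""Generator tests: protocol arithmetic, stack statistics, histology, cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fuslink as fl
from fuslink.synthetic import cbv_response_curve

from conftest import disk_mask


class TestStimulusProtocol:
    @pytest.mark.parametrize(
        "args, total",
        [
            ((20, 20, 20, 10), 420.0),  # the standard acquisition
            ((1, 1, 1, 1), 3.0),
            ((20, 20, 20, 3), 140.0),
        ],
    )
    def test_total_duration(self, args, total):
        assert fl.make_stimulus_protocol(*args).total_duration_s == total

    def test_onsets_and_epochs(self):
        p = fl.make_stimulus_protocol(20, 20, 20, 3)
        assert np.allclose(p.onsets_s(), [20, 60, 100])
        assert p.epochs_s() == [(20, 40), (60, 80), (100, 120)]

    @pytest.mark.parametrize("bad", [(0, 20, 20, 10), (20, -1, 20, 10), (20, 20, 20, 0)])
    def test_invalid_arguments_rejected(self, bad):
        with pytest.raises(ValueError):
            fl.make_stimulus_protocol(*bad)

    @given(
        baseline=st.floats(0.1, 100),
        stim=st.floats(0.1, 100),
        rest=st.floats(0.1, 100),
        reps=st.integers(1, 50),
    )
    @settings(derandomize=True, max_examples=50)
    def test_duration_identity(self, baseline, stim, rest, reps):
        p = fl.make_stimulus_protocol(baseline, stim, rest, reps)
        assert p.total_duration_s == pytest.approx(baseline + reps * (stim + rest))


class TestCbvResponse:
    def test_zero_before_onset_and_plateau(self):
        p = fl.make_stimulus_protocol(20, 20, 20, 2)
        t = np.linspace(0, p.total_duration_s, 5000, endpoint=False)
        d = cbv_response_curve(t, p, amplitude_pct=10, rise_tau_s=1, decay_tau_s=1)
        assert np.all(d[t < 20] == 0)
        # late in the epoch the response sits at the plateau
        late = (t > 38) & (t < 40)
        assert np.allclose(d[late], 10, atol=0.01)

    def test_decay_after_offset(self):
        p = fl.make_stimulus_protocol(20, 20, 20, 1)
        t = np.array([40.0, 41.0, 43.0])
        d = cbv_response_curve(t, p, 10, rise_tau_s=0.5, decay_tau_s=2.0)
        end = 10 * (1 - np.exp(-20 / 0.5))
        assert d[0] == pytest.approx(end)
        assert d[1] == pytest.approx(end * np.exp(-0.5))
        assert d[2] == pytest.approx(end * np.exp(-1.5))


def _small_cfg(**kw):
    defaults = dict(nz=12, nx=12, ultrafast_rate_hz=50, duration_s=60.0,
                    tissue_rank=3, seed=7, pd_block_size=20)
    defaults.update(kw)
    return fl.SimulationConfig(**defaults)


SMALL_PROTOCOL = fl.make_stimulus_protocol(20, 20, 20, 1)


class TestSimulateStack:
    def test_determinism(self):
        cfg = _small_cfg()
        s1, t1 = fl.simulate_ultrafast_stack(cfg, SMALL_PROTOCOL)
        s2, t2 = fl.simulate_ultrafast_stack(_small_cfg(), SMALL_PROTOCOL)
        assert np.array_equal(s1.frames, s2.frames)
        assert np.array_equal(t1.cbv_curve, t2.cbv_curve)

    def test_null_response_stationary(self):
        cfg = _small_cfg(response_amplitude_pct=0.0)
        _, truth = fl.simulate_ultrafast_stack(cfg, SMALL_PROTOCOL)
        assert np.all(truth.cbv_curve == 0)

    def test_duration_mismatch_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            fl.simulate_ultrafast_stack(_small_cfg(duration_s=61.0), SMALL_PROTOCOL)

    def test_active_outside_vessel_rejected(self):
        vessel = np.zeros((12, 12), dtype=bool)
        vessel[:6] = True
        active = np.zeros_like(vessel)
        active[8, 8] = True
        with pytest.raises(ValueError, match="subset"):
            _small_cfg(vessel_mask=vessel, active_mask=active)

    def test_plateau_power_matches_amplitude(self):
        # sample-mean oracle: empirical blood power in the active patch
        # during the plateau over the pre-stimulus mean recovers the
        # programmed amplitude within 3 Monte-Carlo SDs
        amp = 20.0
        cfg = _small_cfg(response_amplitude_pct=amp, rise_tau_s=0.5, noise_sigma=0.0)
        stack, truth = fl.simulate_ultrafast_stack(cfg, SMALL_PROTOCOL)
        filtered = fl.svd_clutter_filter(stack, 8)  # strip tissue
        power = np.abs(filtered.frames) ** 2
        t = np.arange(stack.n_frames) / cfg.ultrafast_rate_hz
        pre = power[truth.active_mask][:, t < 20]
        plateau = power[truth.active_mask][:, (t > 25) & (t < 40)]
        ratio = plateau.mean() / pre.mean() - 1
        n = plateau.size
        mc_sd = 3 * (1 + amp / 100) / np.sqrt(n)  # var(|s|^2) = p^2
        assert ratio == pytest.approx(amp / 100, abs=3 * mc_sd + 0.01)

    def test_energy_bookkeeping(self):
        # tissue, blood and noise are independent, so total energy matches
        # the sum of the component energies within cross-term MC tolerance
        cfg = _small_cfg(noise_sigma=0.3)
        stack, _ = fl.simulate_ultrafast_stack(cfg, SMALL_PROTOCOL)
        total = stack.energy()
        nt = stack.n_frames
        npix = cfg.nz * cfg.nx
        t = np.arange(nt) / cfg.ultrafast_rate_hz
        delta = cbv_response_curve(t, SMALL_PROTOCOL, cfg.response_amplitude_pct,
                                   cfg.rise_tau_s, cfg.decay_tau_s)
        blood = cfg.vessel_mask.sum() * nt + cfg.active_mask.sum() * delta.sum() / 100
        noise = npix * nt * cfg.noise_sigma ** 2
        tissue = cfg.tissue_to_blood_energy_ratio * blood
        expected = tissue + blood + noise
        assert total == pytest.approx(expected, rel=0.02)

    def test_ground_truth_closure(self):
        cfg = _small_cfg(rise_tau_s=1.7)
        _, truth = fl.simulate_ultrafast_stack(cfg, SMALL_PROTOCOL)
        assert truth.theoretical_rise_time_s == pytest.approx(1.7 * np.log(9), rel=1e-12)
        assert truth.cbv_rate_hz == pytest.approx(2.5)


class TestHistologyGenerator:
    def test_noise_free_sections_exact(self):
        spec = fl.HistologySpec(
            region_intensity={"cortex": 100, "background": 10},
            intensity_noise_sd=0.0, sections_per_animal=1, shape=(64, 64),
        )
        img, masks, labels = fl.generate_histology_sections(spec)[0]
        assert np.all(img[masks == labels["cortex"]] == 100)
        assert np.all(img[masks == labels["background"]] == 10)

    def test_determinism(self):
        spec = dict(region_intensity={"cortex": 120, "background": 20},
                    intensity_noise_sd=5.0, sections_per_animal=2, seed=3)
        a = fl.generate_histology_sections(fl.HistologySpec(**spec))
        b = fl.generate_histology_sections(fl.HistologySpec(**spec))
        assert all(np.array_equal(x[0], y[0]) for x, y in zip(a, b))

    def test_region_mean_within_clt_bound(self):
        spec = fl.HistologySpec(
            region_intensity={"thalamus": 130, "background": 20},
            intensity_noise_sd=5.0, sections_per_animal=1, seed=11,
        )
        img, masks, labels = fl.generate_histology_sections(spec)[0]
        sel = masks == labels["thalamus"]
        n = int(sel.sum())
        # quantisation adds at most 0.5 gray level of extra slack
        assert img[sel].mean() == pytest.approx(130, abs=3 * 5 / np.sqrt(n) + 0.5)

    def test_background_disjoint_from_tissue(self):
        spec = fl.HistologySpec(region_intensity={"cortex": 100, "background": 10})
        _, masks, labels = fl.generate_histology_sections(spec)[0]
        bg = masks == labels["background"]
        tissue = np.isin(masks, [labels[r] for r in fl.synthetic.HISTOLOGY_REGIONS])
        assert not np.any(bg & tissue)

    def test_intensity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fl.HistologySpec(region_intensity={"cortex": 300})


def _cohort_spec(**kw):
    defaults = dict(
        groups=[
            fl.GroupSpec("control", 8, 114.0, 2.0),
            fl.GroupSpec("demyelinated", 8, 106.0, 2.0),
        ],
        link_coefficients={"s1bf": (120.0, 0.0, 0.0, -1.57)},
        residual_sd=1.0,
        seed=0,
    )
    defaults.update(kw)
    return fl.CohortSpec(**defaults)


class TestGenerateCohort:
    def test_exact_link_with_zero_residual(self):
        # only the rise-time coefficient is non-zero: myelin must equal
        # intercept - 1.57 * rise_time exactly, row by row
        spec = _cohort_spec(residual_sd=0.0)
        table = fl.generate_cohort(spec)
        expect = 120.0 - 1.57 * table["rise_time_s"]
        assert np.allclose(table["mbp_s1bf"], expect, atol=1e-9)

    def test_null_link_independence(self):
        spec = _cohort_spec(
            groups=[fl.GroupSpec("g", 400, 110.0, 3.0)],
            link_coefficients={"s1bf": (110.0, 0.0, 0.0, 0.0)},
            residual_sd=0.5, seed=5,
        )
        table = fl.generate_cohort(spec)
        for col in fl.synthetic.DESCRIPTOR_COLUMNS:
            r = np.corrcoef(table[col], table["mbp_s1bf"])[0, 1]
            assert abs(r) < 3 / np.sqrt(len(table))

    def test_ols_recovers_coefficients(self):
        import statsmodels.api as sm

        spec = _cohort_spec(
            groups=[fl.GroupSpec("g", 200, 110.0, 6.0)],
            link_coefficients={"s1bf": (120.0, 0.01, -0.3, -1.57)},
            residual_sd=0.5, seed=2,
        )
        table = fl.generate_cohort(spec)
        x = sm.add_constant(table[list(fl.synthetic.DESCRIPTOR_COLUMNS)].astype(float))
        res = sm.OLS(table["mbp_s1bf"], x).fit()
        for name, true in zip(
            ["const", *fl.synthetic.DESCRIPTOR_COLUMNS], [120.0, 0.01, -0.3, -1.57]
        ):
            assert abs(res.params[name] - true) < 2 * res.bse[name] + 1e-9

    def test_unbiased_over_replicates(self):
        # full-model OLS over 100 generated cohorts: mean estimate of the
        # rise coefficient inside its Monte-Carlo confidence interval
        import statsmodels.api as sm

        estimates = []
        for seed in range(100):
            table = fl.generate_cohort(_cohort_spec(seed=seed))
            x = sm.add_constant(table[list(fl.synthetic.DESCRIPTOR_COLUMNS)].astype(float))
            estimates.append(sm.OLS(table["mbp_s1bf"], x).fit().params["rise_time_s"])
        mean, se = np.mean(estimates), np.std(estimates, ddof=1) / 10
        assert abs(mean - (-1.57)) < 3 * se

    def test_multi_region_links_forward_consistent(self):
        spec = _cohort_spec(
            link_coefficients={
                "s1bf": (120.0, 0.0, 0.0, -1.57),
                "internal_capsule": (100.0, 0.0, 0.0, -2.26),
            },
            residual_sd=0.0,
        )
        table = fl.generate_cohort(spec)
        assert np.allclose(table["mbp_internal_capsule"],
                           100.0 - 2.26 * table["rise_time_s"], atol=1e-9)

    def test_determinism(self):
        a = fl.generate_cohort(_cohort_spec(seed=9))
        b = fl.generate_cohort(_cohort_spec(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            fl.GroupSpec("g", 1, 100.0, 1.0)
        with pytest.raises(ValueError):
            _cohort_spec(link_coefficients={"s1bf": (np.inf, 0, 0, -1)})
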