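"""Synthetic-study generator: preset values, seeding contracts, calibration."""

import dataclasses

import numpy as np
import pytest

from visdcm.dynamics import is_stable, simulate_bold
from visdcm.synth import (generate_roi_voxels, generate_study,
                          generate_subject_params, sample_vividness)


class TestPreset:
    def test_text_anchored_couplings(self, gt):
        occ = gt.spec.node_index("OCC")
        ips = gt.spec.node_index("IPS")
        assert gt.group_params.A[ips, occ] == pytest.approx(0.05)
        total = gt.group_params.A[ips, occ] + gt.group_params.B["perception"][ips, occ]
        assert total == pytest.approx(0.94)

    def test_imagery_more_than_triples_frontal_to_occipital(self, gt):
        occ = gt.spec.node_index("OCC")
        ifg = gt.spec.node_index("IFG")
        base = gt.group_params.A[occ, ifg]
        with_imagery = base + gt.group_params.B["imagery"][occ, ifg]
        assert base > 0
        assert with_imagery > 3 * base

    def test_no_bottom_up_imagery_modulation(self, gt):
        from visdcm.pipeline import BOTTOM_UP_CONNECTIONS
        B = gt.group_params.B["imagery"]
        for tgt, src in BOTTOM_UP_CONNECTIONS:
            assert B[gt.spec.node_index(tgt), gt.spec.node_index(src)] == 0.0

    def test_vividness_acts_only_on_occipital_input(self, gt):
        B = gt.group_params.B["vividness"]
        occ = gt.spec.node_index("OCC")
        nz = np.argwhere(B != 0)
        assert len(nz) > 0
        assert all(t == occ for t, _ in nz)
        assert B[occ, gt.spec.node_index("IPS")] > 0    # disinhibition path
        assert B[occ, gt.spec.node_index("FG")] < 0     # sharpening path
        assert B[occ, occ] < 0                          # reduced self-inhibition

    def test_vividness_distribution(self, gt):
        assert gt.vividness_distribution.sum() == pytest.approx(1.0)
        assert gt.vividness_mean == pytest.approx(2.969, abs=2e-3)

    def test_preset_is_stable_and_produces_finite_bold(self, gt, micro_inputs):
        assert is_stable(gt.group_params)
        _, inputs = micro_inputs
        out = simulate_bold(gt.spec, gt.group_params, inputs, tr=2.0, seed=0)
        assert np.all(np.isfinite(out.y))
        assert out.y.std() > 0


class TestSubjectParams:
    def test_zero_sd_copies_group_mean(self, gt):
        g = dataclasses.replace(gt, between_subject_sd=0.0)
        p = generate_subject_params(g, seed=5)
        np.testing.assert_array_equal(p.A, gt.group_params.A)
        np.testing.assert_array_equal(p.C, gt.group_params.C)

    def test_seeding_contract(self, gt):
        a = generate_subject_params(gt, seed=1)
        b = generate_subject_params(gt, seed=1)
        c = generate_subject_params(gt, seed=2)
        np.testing.assert_array_equal(a.A, b.A)
        assert np.any(a.A != c.A)

    def test_draw_dispersion_matches_requested_sd(self, gt):
        """Sample sd of a drawn parameter is within 10% of the nominal sd
        (stability rejection truncates the tails only mildly)."""
        occ, fg = gt.spec.node_index("OCC"), gt.spec.node_index("FG")
        draws = np.array([
            generate_subject_params(gt, seed=1000 + k).A[fg, occ]
            for k in range(1000)
        ])
        assert abs(draws.std() - gt.between_subject_sd) / gt.between_subject_sd < 0.10
        assert draws.mean() == pytest.approx(gt.group_params.A[fg, occ], abs=0.02)

    def test_every_accepted_draw_is_stable(self, gt):
        for k in range(50):
            assert is_stable(generate_subject_params(gt, seed=2000 + k))

    def test_impossible_stability_raises(self, gt):
        g = dataclasses.replace(gt, between_subject_sd=5.0)
        with pytest.raises(RuntimeError):
            generate_subject_params(g, seed=0, max_attempts=10)


class TestStudy:
    def test_study_structure_and_determinism(self, gt):
        a = generate_study(gt, n_subjects=2, n_trials=3, seed=9)
        b = generate_study(gt, n_subjects=2, n_trials=3, seed=9)
        assert a.n_subjects == 2
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(sa.bold.y, sb.bold.y)
            np.testing.assert_array_equal(sa.vividness, sb.vividness)
        c = generate_study(gt, n_subjects=2, n_trials=3, seed=10)
        ya, yc = a.subjects[0].bold.y, c.subjects[0].bold.y
        assert ya.shape != yc.shape or np.any(ya != yc)

    def test_subjects_differ_within_study(self, gt):
        ds = generate_study(gt, n_subjects=3, n_trials=3, seed=4)
        y0, y1 = ds.subjects[0].bold.y, ds.subjects[1].bold.y
        assert y0.shape[1] == y1.shape[1]
        assert np.any(ds.subjects[0].vividness != ds.subjects[1].vividness) or \
            np.any(ds.subjects[0].true_params.A != ds.subjects[1].true_params.A)

    def test_provenance_carries_seeds_and_config(self, gt):
        ds = generate_study(gt, n_subjects=1, n_trials=2, seed=123)
        prov = ds.provenance
        assert prov["seed"] == 123
        assert prov["n_trials"] == 2 and prov["n_subjects"] == 1
        assert prov["noise_sd"] == gt.noise_sd

    def test_pooled_vividness_mean_matches_published_value(self, gt):
        """26 subjects x 180 trials of ratings pool to a mean near 2.97."""
        rng_seeds = np.random.SeedSequence(55).spawn(26)
        ratings = np.concatenate([
            sample_vividness(gt, 180, seed=s) for s in rng_seeds])
        assert ratings.mean() == pytest.approx(2.97, abs=0.03)

    def test_categorical_sampler_matches_probabilities(self, gt):
        draws = sample_vividness(gt, 10_000, seed=8)
        for level, p in zip([1, 2, 3, 4], gt.vividness_distribution):
            frac = np.mean(draws == level)
            # three binomial standard errors
            assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 10_000)


class TestRoiVoxels:
    def test_single_voxel_zero_noise_is_proportional(self):
        signal = np.sin(np.linspace(0, 6, 120))
        vox = generate_roi_voxels(signal, n_voxels=1, seed=0, snr=0)
        r = np.corrcoef(vox[0], signal)[0, 1]
        assert r == pytest.approx(1.0)

    def test_first_pc_tracks_signal_at_moderate_snr(self):
        from visdcm.pipeline import extract_eigenvariate
        signal = np.sin(np.linspace(0, 12, 300))
        vox = generate_roi_voxels(signal, n_voxels=50, seed=1, snr=2.0)
        ev = extract_eigenvariate(vox)
        assert abs(np.corrcoef(ev, signal)[0, 1]) > 0.95

    def test_zero_loadings_give_pure_noise(self):
        from visdcm.pipeline import extract_eigenvariate
        signal = np.sin(np.linspace(0, 12, 300))
        vox = generate_roi_voxels(signal, n_voxels=40, seed=2, snr=1.0,
                                  loading_range=(0.0, 0.0))
        ev = extract_eigenvariate(vox)
        assert abs(np.corrcoef(ev, signal)[0, 1]) < 0.3

    def test_nuisance_contributions_added(self):
        signal = np.sin(np.linspace(0, 12, 200))
        nuis = np.cos(np.linspace(0, 3, 200))[:, None]
        with_n = generate_roi_voxels(signal, n_voxels=5, nuisance=nuis,
                                     seed=3, snr=0)
        without = generate_roi_voxels(signal, n_voxels=5, seed=3, snr=0)
        assert np.any(with_n != without)
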