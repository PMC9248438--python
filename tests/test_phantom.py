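"""Phantom generator: geometry, marginals, couplings, signal synthesis."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import hypoximap as hm
from hypoximap.config import PhantomConfig
from hypoximap.phantom import (BACKGROUND, CALCIFICATION, NECROSIS, NORMAL,
                               TUMOR, TUMOR_CODES, VESSEL, add_rician_noise)

from conftest import TUMOR_MEANS


class TestLabelVolume:
    def test_deterministic_for_fixed_seed(self):
        cfg = PhantomConfig(seed=5)
        a = hm.generate_label_volume(cfg)
        b = hm.generate_label_volume(cfg)
        assert np.array_equal(a.labels, b.labels)

    def test_zero_component_fractions_gives_pure_tumor(self, small_phantom_config):
        cfg = small_phantom_config.model_copy(update={
            "vessel_fraction": 0.0, "necrosis_fraction": 0.0,
            "calcification_fraction": 0.0})
        lab = hm.generate_label_volume(cfg)
        tumor_codes = np.unique(lab.labels[lab.tumor_mask()])
        assert list(tumor_codes) == [TUMOR]

    def test_tumor_volume_recovered(self):
        # independent oracle: voxel count * voxel volume
        cfg = PhantomConfig(seed=3, tumor_volume_mm3=458.0)
        lab = hm.generate_label_volume(cfg)
        vol = int(lab.tumor_mask().sum()) * np.prod(cfg.voxel_size_mm)
        assert abs(vol / 458.0 - 1.0) < 0.02

    def test_component_fractions_within_one_point(self):
        cfg = PhantomConfig(seed=9, vessel_fraction=0.05,
                            necrosis_fraction=0.10, calcification_fraction=0.02)
        lab = hm.generate_label_volume(cfg)
        n_tumor = lab.tumor_mask().sum()
        for code, frac in ((VESSEL, 0.05), (NECROSIS, 0.10), (CALCIFICATION, 0.02)):
            got = (lab.labels == code).sum() / n_tumor
            assert abs(got - frac) < 0.01

    def test_components_only_inside_tumor(self):
        lab = hm.generate_label_volume(PhantomConfig(seed=2))
        comp = np.isin(lab.labels, (VESSEL, NECROSIS, CALCIFICATION))
        assert np.all(lab.tumor_mask()[comp])

    def test_tumor_outside_brain_rejected(self, small_phantom_config):
        cfg = small_phantom_config.model_copy(
            update={"tumor_center_offset_mm": (-4.0, 0.0, 0.0)})
        with pytest.raises(ValueError):
            hm.generate_label_volume(cfg)


@pytest.fixture(scope="module")
def white_cfg():
    # spatially independent fields isolate the marginal calibration
    return PhantomConfig(seed=21, latent_smooth_mm=0.0)


@pytest.fixture(scope="module")
def white_truth(white_cfg):
    lab = hm.generate_label_volume(white_cfg)
    return lab, hm.generate_truth_maps(lab, white_cfg)


class TestTruthMaps:
    def test_hif_tissue_means_recovered(self, white_truth):
        lab, truth = white_truth
        tumor_mean = truth.hif[lab.tumor_mask()].mean()
        normal_mean = truth.hif[lab.labels == NORMAL].mean()
        assert abs(tumor_mean / 123.73 - 1.0) < 0.05
        assert abs(normal_mean / 21.13 - 1.0) < 0.05

    def test_parameter_means_and_sds_recovered(self, white_truth):
        lab, truth = white_truth
        mask = lab.tumor_mask()
        assert mask.sum() > 5000
        for name, mean, sd in (("d", 419.50e-6, 81.97e-6),
                               ("r2star", 38.24, 8.76)):
            vals = getattr(truth, name)[mask]
            se = sd / np.sqrt(mask.sum())
            assert abs(vals.mean() - mean) < 4 * se + 0.01 * mean
            assert abs(vals.std() / sd - 1.0) < 0.05

    def test_invariants(self, white_truth):
        lab, truth = white_truth
        tissue = lab.labels >= NORMAL
        assert np.all(truth.dstar[tissue] >= truth.d[tissue])
        assert truth.f.min() >= 0 and truth.f.max() <= 1
        assert np.all(truth.r2star[tissue] > 0)
        assert truth.hif.min() >= 0 and truth.hif.max() <= 300

    def test_zero_coupling_independence(self, white_cfg):
        cfg = white_cfg.model_copy(update={
            "coupling_r2star": 0.0, "coupling_dstar": 0.0, "seed": 31})
        lab = hm.generate_label_volume(cfg)
        truth = hm.generate_truth_maps(lab, cfg)
        m = lab.tumor_mask()
        assert m.sum() >= 5000
        rho = spearmanr(truth.hif[m], truth.r2star[m]).statistic
        assert abs(rho) < 0.1

    def test_positive_coupling_magnitude(self, white_cfg):
        # latent correlation 0.5 -> sample Spearman in (0.35, 0.65)
        cfg = white_cfg.model_copy(update={
            "coupling_r2star": 0.5, "coupling_dstar": 0.0,
            "hif_core_rim_gradient": 0.0, "seed": 33})
        lab = hm.generate_label_volume(cfg)
        truth = hm.generate_truth_maps(lab, cfg)
        m = lab.tumor_mask()
        rho = spearmanr(truth.hif[m], truth.r2star[m]).statistic
        assert 0.35 < rho < 0.65

    def test_coupling_signs_at_defaults(self, white_truth):
        lab, truth = white_truth
        m = lab.tumor_mask()
        assert spearmanr(truth.hif[m], truth.r2star[m]).statistic > 0.2
        assert spearmanr(truth.hif[m], truth.dstar[m]).statistic < -0.1

    def test_hif_core_exceeds_rim(self, white_cfg):
        from hypoximap.phantom import _grid_coords
        cfg = white_cfg
        lab = hm.generate_label_volume(cfg)
        truth = hm.generate_truth_maps(lab, cfg)
        x, y, z = _grid_coords(cfg)
        cx, cy, cz = cfg.tumor_center_offset_mm
        rnorm = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) \
            / cfg.tumor_radius_mm
        m = lab.tumor_mask()
        core = m & (rnorm < 0.5)
        rim = m & (rnorm > 0.8)
        assert truth.hif[core].mean() > truth.hif[rim].mean() + 20

    def test_invalid_coupling_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(coupling_r2star=0.9, coupling_dstar=-0.9)


class TestSignalSynthesis:
    def test_dwi_noiseless_matches_closed_form(self, small_phantom_config):
        cfg = small_phantom_config
        lab = hm.generate_label_volume(cfg)
        truth = hm.generate_truth_maps(lab, cfg)
        dwi = hm.synthesize_dwi(truth, hm.B_VALUES, sigma=0.0, seed=1)
        i, j, k = np.argwhere(lab.tumor_mask())[0]
        expected = truth.s0[i, j, k] * hm.ivim_signal(
            np.array(hm.B_VALUES), truth.d[i, j, k], truth.dstar[i, j, k],
            truth.f[i, j, k])
        np.testing.assert_allclose(dwi.data[i, j, k], expected, rtol=1e-12)
        # b = 0 returns S0 exactly
        b0 = list(hm.B_VALUES).index(0.0)
        np.testing.assert_allclose(dwi.data[..., b0], truth.s0, rtol=1e-12)

    def test_dwi_table_value_at_b1000(self):
        # high-precision closed-form evaluation at the tumor means
        val = hm.ivim_signal(1000.0, **{k: TUMOR_MEANS[k]
                                        for k in ("d", "dstar", "f")})
        assert abs(val - 0.351) < 5e-4

    def test_mege_closed_form(self, small_phantom_config):
        cfg = small_phantom_config
        lab = hm.generate_label_volume(cfg)
        truth = hm.generate_truth_maps(lab, cfg)
        te = (0.0034, 0.05, 0.0921)
        mege = hm.synthesize_mege(truth, te, sigma=0.0, seed=1)
        i, j, k = np.argwhere(lab.labels == NORMAL)[0]
        np.testing.assert_allclose(
            mege.data[i, j, k],
            truth.s0[i, j, k] * np.exp(-np.array(te) * truth.r2star[i, j, k]),
            rtol=1e-12)
        assert abs(hm.mege_signal(0.0921, 1.0, 38.24) - np.exp(-3.522)) < 1e-4

    def test_noise_determinism(self, small_phantom_config):
        cfg = small_phantom_config
        lab = hm.generate_label_volume(cfg)
        truth = hm.generate_truth_maps(lab, cfg)
        a = hm.synthesize_dwi(truth, hm.B_VALUES, sigma=0.05, seed=7)
        b = hm.synthesize_dwi(truth, hm.B_VALUES, sigma=0.05, seed=7)
        assert np.array_equal(a.data, b.data)

    def test_negative_sigma_rejected(self, small_phantom_config):
        cfg = small_phantom_config
        lab = hm.generate_label_volume(cfg)
        truth = hm.generate_truth_maps(lab, cfg)
        with pytest.raises(ValueError):
            hm.synthesize_dwi(truth, hm.B_VALUES, sigma=-0.1, seed=1)


class TestRicianNoise:
    def test_sigma_zero_is_identity(self, rng):
        x = rng.random((5, 7))
        assert np.array_equal(add_rician_noise(x, 0.0, rng), x)

    def test_zero_signal_is_rayleigh(self, rng):
        # Rayleigh mean = sigma * sqrt(pi/2)
        out = add_rician_noise(np.zeros(200_000), 2.0, rng)
        assert abs(out.mean() - 2.0 * np.sqrt(np.pi / 2)) < 0.02
        assert out.min() >= 0

    def test_high_snr_mean(self, rng):
        # E[magnitude] -> sqrt(s^2 + sigma^2) for s >> sigma
        s, sigma = 50.0, 1.0
        out = add_rician_noise(np.full(400_000, s), sigma, rng)
        assert abs(out.mean() / np.sqrt(s**2 + sigma**2) - 1.0) < 1e-3

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), -1.0)


class TestCellTable:
    def test_saturated_and_null_densities(self, small_phantom_config):
        cfg = small_phantom_config
        lab = hm.generate_label_volume(cfg)
        truth = hm.generate_truth_maps(lab, cfg)
        k = hm.select_largest_tumor_slice(lab)
        for level, expected in ((0.0, {0}), (300.0, {3})):
            t2 = hm.TruthMaps(d=truth.d, dstar=truth.dstar, f=truth.f,
                              r2star=truth.r2star,
                              hif=np.full_like(truth.hif, level),
                              s0=truth.s0, voxel_size_mm=truth.voxel_size_mm)
            cells = hm.synthesize_cell_table(t2, lab, k, 500.0, seed=3)
            assert set(cells["intensity"].unique()) == expected

    def test_cells_inside_tissue(self, small_phantom_config):
        cfg = small_phantom_config
        lab = hm.generate_label_volume(cfg)
        truth = hm.generate_truth_maps(lab, cfg)
        k = hm.select_largest_tumor_slice(lab)
        cells = hm.synthesize_cell_table(truth, lab, k, 800.0, seed=5)
        dx, dy, _ = cfg.voxel_size_mm
        ii = (cells["x_mm"] // dx).astype(int)
        jj = (cells["y_mm"] // dy).astype(int)
        assert np.all(lab.labels[ii, jj, k] >= NORMAL)

    def test_mean_score_matches_density(self, small_phantom_config):
        # uniform density 150 at high cell count -> ROI scores near 150
        from hypoximap.hif import score_roi
        cfg = small_phantom_config
        lab = hm.generate_label_volume(cfg)
        truth = hm.generate_truth_maps(lab, cfg)
        k = hm.select_largest_tumor_slice(lab)
        t2 = hm.TruthMaps(d=truth.d, dstar=truth.dstar, f=truth.f,
                          r2star=truth.r2star,
                          hif=np.full_like(truth.hif, 150.0),
                          s0=truth.s0, voxel_size_mm=truth.voxel_size_mm)
        cells = hm.synthesize_cell_table(t2, lab, k, 10_000.0, seed=4)
        score = score_roi(cells["intensity"].to_numpy()).score
        assert abs(score / 150.0 - 1.0) < 0.05

    def test_low_density_warns(self, small_phantom_config):
        cfg = small_phantom_config
        lab = hm.generate_label_volume(cfg)
        truth = hm.generate_truth_maps(lab, cfg)
        k = hm.select_largest_tumor_slice(lab)
        with pytest.warns(UserWarning):
            hm.synthesize_cell_table(truth, lab, k, 10.0, seed=4)
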