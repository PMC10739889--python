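import numpy as np
import pytest
from scipy import ndimage

from zygopolar.errors import FlatProfileError
from zygopolar.geometry import fit_ellipse_axis, max_intensity_projection, rotate_and_mask
from zygopolar.profile import axial_profile, resample_profile, zscore
from zygopolar.synthetic_data import (
    ProbeTemplate,
    SyntheticConfig,
    generate_arrays,
    planted_density,
    render_frame,
)


class TestPlantedDensity:
    def test_uniform_is_one(self):
        t = ProbeTemplate("uniform")
        u = np.linspace(0, 1, 11)
        assert np.allclose(planted_density(t, u, 0.436), 1.0)

    def test_logistic_midpoint_at_boundary(self):
        t = ProbeTemplate("basal_gradient", amplitude=1.0, baseline=0.2, width=0.07)
        val = planted_density(t, 0.436, 0.436)
        assert val == pytest.approx(0.2 + 0.5)

    def test_band_peaks_at_half_boundary(self):
        t = ProbeTemplate("apical_band", width=0.05)
        for b in (0.3, 0.436, 0.6):
            u = np.linspace(0, 1, 1001)
            d = planted_density(t, u, b)
            assert abs(u[np.argmax(d)] - b / 2) <= 1.0 / 1000

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            planted_density(ProbeTemplate("spiral"), 0.5, 0.4)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"boundary_fraction": 0.0},
            {"boundary_fraction": 1.0},
            {"length_initial": 10.0},
            {"noise_sd_frac": -0.1},
            {"k_timepoints": 1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestGenerateArrays:
    def test_seed_reproducibility_byte_identical(self, small_config):
        import dataclasses

        a = generate_arrays(small_config)
        b = generate_arrays(dataclasses.replace(small_config))
        for ma, mb in zip(a.movies, b.movies):
            assert np.array_equal(ma.stack, mb.stack)
            assert ma.angle_deg == mb.angle_deg
            assert ma.plane_fraction == mb.plane_fraction

    def test_shapes_and_metadata(self, small_config):
        ds = generate_arrays(small_config)
        assert len(ds.movies) == 4 * 3
        for m in ds.movies:
            assert m.stack.ndim == 4
            assert m.stack.shape[0] == small_config.k_timepoints
            assert m.stack.shape[1] == small_config.z_slices
            assert np.all(m.stack >= 0)
            assert len(m.masks) == small_config.k_timepoints

    def test_masks_simply_connected(self, small_config):
        ds = generate_arrays(small_config)
        for m in ds.movies[:3]:
            for msk in m.masks:
                n_fg = ndimage.label(msk)[1]
                n_bg = ndimage.label(~msk)[1]
                assert n_fg == 1 and n_bg == 1  # one blob, no holes

    def test_mip_of_noiseless_stack_equals_render(self):
        cfg = SyntheticConfig(
            length_initial=60, length_final=90, cell_width=24, z_slices=4,
            margin=8, noise_sd_frac=0.0, speckle_sd=0.0, seed=3,
        )
        ds = generate_arrays(cfg)
        from zygopolar.synthetic_data import _z_weights

        m = ds.movies[2]  # microtubules: structured, nonzero variance
        mip = max_intensity_projection(m.stack[0])
        assert mip.max() > 0
        # the z falloff is normalized to 1 at its peak slice, so the MIP of
        # the noiseless stack is exactly the 2D render
        peak = int(np.argmax(_z_weights(cfg.z_slices)))
        assert np.array_equal(mip, m.stack[0][peak])
        # and the MIP support is the mask
        assert np.array_equal(mip > 0, m.masks[0])

    def test_ground_truth_records_design(self, small_config):
        ds = generate_arrays(small_config)
        gt = ds.ground_truth()
        assert gt["boundary_pct"] == pytest.approx(43.6)
        assert len(gt["movies"]) == 12
        assert set(gt["templates"]) == set(small_config.probes)


class TestNoiselessContracts:
    def _clean_cfg(self, probes):
        return SyntheticConfig(
            probes=probes,
            n_replicates=1,
            length_initial=80, length_final=120, cell_width=30,
            z_slices=3, margin=8, noise_sd_frac=0.0, speckle_sd=0.0,
            angles={(p, "rep1"): 90.0 for p in probes},
            seed=0,
        )

    def test_uniform_template_noise_free_is_flat(self):
        cfg = self._clean_cfg({"mitochondria": ProbeTemplate("uniform")})
        ds = generate_arrays(cfg)
        m = ds.movies[0]
        cell = rotate_and_mask(
            max_intensity_projection(m.stack[0]), m.masks[0],
            fit_ellipse_axis(m.masks[0]), m.apex_hints[0],
        )
        prof = axial_profile(cell)
        with pytest.raises(FlatProfileError):
            zscore(resample_profile(prof, 110))

    def test_basal_gradient_monotone_increasing(self):
        t = ProbeTemplate("basal_gradient", amplitude=1.0, width=0.08)
        cfg = self._clean_cfg({"actin_filaments": t})
        ds = generate_arrays(cfg)
        m = ds.movies[0]
        cell = rotate_and_mask(
            max_intensity_projection(m.stack[-1]), m.masks[-1],
            fit_ellipse_axis(m.masks[-1]), m.apex_hints[-1],
        )
        vals = resample_profile(axial_profile(cell), 110)
        assert np.all(np.diff(vals) >= -1e-9)

    def test_profile_matches_planted_template_closed_form(self):
        """Noise-free vertical render: extracted normalized profile equals
        the z-scored template sampled at mask row centres, within
        rasterization tolerance."""
        t = ProbeTemplate("basal_gradient", amplitude=1.0, width=0.05)
        cfg = self._clean_cfg({"vacuolar_membranes": t})
        ds = generate_arrays(cfg)
        m = ds.movies[0]
        cell = rotate_and_mask(
            max_intensity_projection(m.stack[0]), m.masks[0],
            fit_ellipse_axis(m.masks[0]), m.apex_hints[0],
        )
        prof = axial_profile(cell)
        got = zscore(resample_profile(prof, 110))
        n = prof.length_px
        rows_u = (np.arange(n) + 0.5) / n
        want = zscore(resample_profile(planted_density(t, rows_u, 0.436), 110))
        assert np.max(np.abs(got - want)) < 1e-3


def test_render_frame_capsule_geometry():
    t = ProbeTemplate("uniform")
    img, mask, tip, base = render_frame((120, 120), (59.5, 59.5), 90, 30, 90, t, 0.4)
    rows = np.nonzero(mask.any(axis=1))[0]
    assert rows[-1] - rows[0] + 1 == pytest.approx(90, abs=2)
    assert np.hypot(tip[0] - base[0], tip[1] - base[1]) == pytest.approx(90)
    assert tip[0] < base[0]  # apex up for a 90-degree (vertical) cell
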