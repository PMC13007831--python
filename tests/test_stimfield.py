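import numpy as np
import pytest

from thalnet.io_core import Volume
from thalnet.stimfield import (
    ConductivityModel,
    ElectrodeModel,
    StimulationSetting,
    compute_vta,
    electric_field_magnitude,
    merge_vtas,
    parse_stim_string,
)

from conftest import make_grid


def _electrode(tip=(0.0, 0.0, 0.0), direction=(0.0, 0.0, 1.0), side="L"):
    return ElectrodeModel(np.asarray(tip, float), np.asarray(direction, float), side=side)


def _homog(sigma=0.14):
    return ConductivityModel(sigma_gray=sigma, sigma_white=sigma)


def _monopole_radius(i_amp, sigma_s_per_m=0.14, e_thresh=0.2):
    return np.sqrt(i_amp / (4 * np.pi * (sigma_s_per_m / 1000.0) * e_thresh))


class TestParseStimString:
    def test_single_side_fractional_amplitude(self):
        out = parse_stim_string("R: 0+-0 .5")
        assert len(out) == 1
        side, setting = out[0]
        assert side == "R"
        assert setting.polarity == "0+-0"
        assert setting.amplitude_ma == 0.5

    def test_unicode_minus_accepted(self):
        (_, setting), = parse_stim_string("R: 0+−0 .5")
        assert setting.polarity == "0+-0"

    def test_bilateral_clause(self):
        out = parse_stim_string("L: +-00 2 R: +-00 2")
        assert [s for s, _ in out] == ["L", "R"]
        assert all(st.amplitude_ma == 2.0 for _, st in out)

    def test_quadripolar_alternating(self):
        (_, setting), = parse_stim_string("L: +-+- 4")
        assert setting.contact_currents_ma().tolist() == [2.0, -2.0, 2.0, -2.0]

    def test_null_setting_has_zero_currents(self):
        setting = StimulationSetting("0000", 0.0, "L")
        assert np.all(setting.contact_currents_ma() == 0)

    @pytest.mark.parametrize("bad", ["L: +-0 2", "L: +x00 2", "L: +-00", ""])
    def test_malformed_strings_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_stim_string(bad)

    def test_active_setting_requires_a_cathode(self):
        with pytest.raises(ValueError, match="cathode"):
            StimulationSetting("+000", 2.0, "L")

    def test_current_split_within_polarity_groups(self):
        setting = StimulationSetting("-+-0", 3.0, "L")
        assert setting.contact_currents_ma().tolist() == [-1.5, 3.0, -1.5, 0.0]


class TestElectricField:
    def test_monopole_closed_form(self):
        elec = _electrode()
        setting = StimulationSetting("-000", 2.0, "L")
        for r in (1.0, 2.0, 3.5):
            mag = electric_field_magnitude(elec, setting, None, _homog(), np.array([r, 0.0, 0.0]))
            expected = 0.002 / (4 * np.pi * (0.14 / 1000) * r**2)
            assert np.isclose(mag, expected, rtol=1e-9)

    def test_threshold_radius_constant(self):
        # 2 mA cathode in white matter: |E| = 0.2 V/mm at r* ~ 2.38 mm
        assert np.isclose(_monopole_radius(0.002), 2.384, atol=2e-3)
        elec = _electrode()
        setting = StimulationSetting("-000", 2.0, "L")
        rstar = _monopole_radius(0.002)
        mag = electric_field_magnitude(elec, setting, None, _homog(), np.array([rstar, 0.0, 0.0]))
        assert np.isclose(mag, 0.2, rtol=1e-6)

    def test_zero_amplitude_zero_field(self):
        elec = _electrode()
        setting = StimulationSetting("0000", 0.0, "L")
        pts = np.random.default_rng(0).normal(size=(10, 3))
        assert np.all(electric_field_magnitude(elec, setting, None, _homog(), pts) == 0)

    def test_bipolar_mirror_symmetry(self):
        """|E| is symmetric under reflection across the bisector plane of a
        +/- contact pair."""
        elec = _electrode()
        setting = StimulationSetting("+-00", 2.0, "L")  # contacts at z=0 and z=3.5
        plane_z = 3.5 / 2
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y, dz = rng.uniform(-5, 5, 2).tolist() + [rng.uniform(0.3, 4)]
            above = electric_field_magnitude(
                elec, setting, None, _homog(), np.array([x, y, plane_z + dz])
            )
            below = electric_field_magnitude(
                elec, setting, None, _homog(), np.array([x, y, plane_z - dz])
            )
            assert np.isclose(above, below, rtol=1e-9)

    def test_field_linear_in_amplitude(self):
        elec = _electrode()
        pt = np.array([1.7, 0.4, 2.1])
        m1 = electric_field_magnitude(elec, StimulationSetting("+-00", 1.0, "L"), None, _homog(), pt)
        m3 = electric_field_magnitude(elec, StimulationSetting("+-00", 3.0, "L"), None, _homog(), pt)
        assert np.isclose(m3, 3 * m1, rtol=1e-9)

    def test_capped_at_contact_center(self):
        elec = _electrode()
        setting = StimulationSetting("-000", 2.0, "L")
        mag = electric_field_magnitude(elec, setting, None, _homog(), np.zeros(3))
        assert np.isfinite(mag)


class TestVTA:
    def test_sphere_volume_within_10pct_at_quarter_mm(self):
        grid = make_grid(32, voxel=0.25)
        elec = _electrode(tip=(0.03, -0.23, 0.11))
        setting = StimulationSetting("-000", 2.0, "L")
        vta = compute_vta(elec, setting, None, _homog(), grid)
        expected = 4 / 3 * np.pi * _monopole_radius(0.002) ** 3
        assert abs(vta.volume_mm3 - expected) / expected < 0.10

    def test_error_decreases_with_voxel_size(self):
        """Mean |volume error| over electrode positions shrinks as the grid
        refines (1.0 -> 0.5 -> 0.25 mm)."""
        rng = np.random.default_rng(0)
        tips = rng.uniform(-0.5, 0.5, size=(8, 3))
        expected = 4 / 3 * np.pi * _monopole_radius(0.002) ** 3
        means = []
        for voxel in (1.0, 0.5, 0.25):
            n = int(16 / voxel)
            grid = make_grid(n, voxel)
            errs = [
                abs(
                    compute_vta(
                        _electrode(tip=t), StimulationSetting("-000", 2.0, "L"), None, _homog(), grid
                    ).volume_mm3
                    - expected
                )
                / expected
                for t in tips
            ]
            means.append(np.mean(errs))
        assert means[0] > means[1] > means[2]

    def test_zero_amplitude_empty(self):
        grid = make_grid(16)
        vta = compute_vta(_electrode(), StimulationSetting("0000", 0.0, "L"), None, _homog(), grid)
        assert vta.volume_mm3 == 0

    def test_volume_monotone_in_amplitude(self):
        grid = make_grid(32, voxel=0.5)
        v1 = compute_vta(_electrode(), StimulationSetting("-000", 1.0, "L"), None, _homog(), grid)
        v2 = compute_vta(_electrode(), StimulationSetting("-000", 2.0, "L"), None, _homog(), grid)
        assert v2.volume_mm3 > v1.volume_mm3
        assert np.all(v1.mask.values <= v2.mask.values)

    def test_radius_scales_as_sqrt_amplitude(self):
        grid = make_grid(64, voxel=0.25)
        vols = []
        for amp in (1.0, 4.0):
            vols.append(
                compute_vta(_electrode(), StimulationSetting("-000", amp, "L"), None, _homog(), grid).volume_mm3
            )
        # r ~ sqrt(I) so volume ~ I^1.5: quadrupling I multiplies volume by 8
        assert np.isclose(vols[1] / vols[0], 8.0, rtol=0.15)

    def test_electrode_outside_grid_rejected(self):
        grid = make_grid(16)
        with pytest.raises(ValueError, match="outside"):
            compute_vta(
                _electrode(tip=(100.0, 0, 0)), StimulationSetting("-000", 2.0, "L"), None, _homog(), grid
            )

    def test_programmed_settings_give_plausible_volumes(self):
        """For every stimulation setting programmed in the cohort (0.5-6 mA),
        the single-side VTA volume stays in the 10-2000 mm^3 band of
        clinically reported VTAs."""
        from thalnet.fixtures import load_table2

        grid = make_grid(80, voxel=0.5)
        cond = ConductivityModel()  # S/m reading of the gray/white defaults
        for stim in load_table2()["stim_setting"]:
            for _, setting in parse_stim_string(stim):
                if setting.amplitude_ma == 0:
                    continue
                vta = compute_vta(_electrode(), setting, None, cond, grid)
                assert 10 <= vta.volume_mm3 <= 2000, stim

    def test_literal_s_per_mm_reading_gives_submillimetre_vta(self):
        grid = make_grid(32, voxel=0.25)
        cond = ConductivityModel(literal_s_per_mm=True)
        vta = compute_vta(_electrode(), StimulationSetting("-000", 2.0, "L"), None, cond, grid)
        assert vta.volume_mm3 < 1.0


class TestMergeVTAs:
    @staticmethod
    def _sphere_vta(center, radius, grid):
        from thalnet.io_core import Mask
        from thalnet.stimfield import VTA

        ii = np.indices(grid.shape).transpose(1, 2, 3, 0).astype(float)
        pts = ii * grid.affine[0, 0] + grid.affine[:3, 3]
        d = np.linalg.norm(pts - np.asarray(center), axis=-1)
        return VTA(Mask(d <= radius, grid.affine), 0.2, [])

    def test_disjoint_volumes_add(self):
        grid = make_grid(40, voxel=0.5)
        a = self._sphere_vta((-5, 0, 0), 2.0, grid)
        b = self._sphere_vta((5, 0, 0), 2.5, grid)
        merged = merge_vtas([a, b])
        assert np.isclose(merged.volume_mm3, a.volume_mm3 + b.volume_mm3)

    def test_identical_union_idempotent(self):
        grid = make_grid(40, voxel=0.5)
        a = self._sphere_vta((0, 0, 0), 2.0, grid)
        merged = merge_vtas([a, a])
        assert merged.volume_mm3 == a.volume_mm3

    def test_overlapping_spheres_subadditive(self):
        grid = make_grid(40, voxel=0.5)
        a = self._sphere_vta((-1, 0, 0), 2.0, grid)
        b = self._sphere_vta((1, 0, 0), 2.0, grid)
        merged = merge_vtas([a, b])
        assert merged.volume_mm3 < a.volume_mm3 + b.volume_mm3
        # geometric oracle: lens-corrected union of two r=2 spheres at d=2
        r, d = 2.0, 2.0
        lens = 2 * np.pi * (r - d / 2) ** 2 * (2 * r + d / 2) / 3
        expected = 2 * (4 / 3 * np.pi * r**3) - lens
        assert abs(merged.volume_mm3 - expected) / expected < 0.1

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            merge_vtas([])
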