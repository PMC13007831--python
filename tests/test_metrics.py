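import numpy as np
import pytest

from thalnet import io_core
from thalnet.fixtures import load_table2
from thalnet.io_core import Mask, Tract, Volume
from thalnet.metrics import (
    ActivationMetrics,
    PeakProbability,
    aggregate_patient,
    classify_pattern,
    peak_probability_in_vta,
    proportion_activated,
    round_half_away,
)
from thalnet.phantom import BundleSpec, PhantomConfig, build_phantom
from thalnet.probmap import ProbabilityMap
from thalnet.stimfield import VTA
from thalnet.tracking import TrackingParams, track_soz_to_thalamus

from conftest import make_grid


def _vta_from_box(grid, lo, hi):
    values = np.zeros(grid.shape, dtype=bool)
    values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return VTA(Mask(values, grid.affine), 0.2, [])


def _line(y, z, x0=-8.0, x1=8.0, step=0.5):
    xs = np.arange(x0, x1 + step / 2, step)
    return np.stack([xs, np.full_like(xs, y), np.full_like(xs, z)], axis=1)


class TestActivationMetrics:
    def test_rounded_percent_matches_printed_counts(self):
        assert ActivationMetrics(10000, 2883).percent_rounded == 29

    def test_percent_column_reproduced_for_all_rows(self):
        t2 = load_table2()
        recomputed = [
            ActivationMetrics(int(n), int(a)).percent_rounded
            for n, a in zip(t2["n_streamlines_total"], t2["n_streamlines_activated"])
        ]
        assert recomputed == t2["percent_activated"].astype(int).tolist()

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(4.696) == 5
        assert round_half_away(4.5) == 5
        assert round_half_away(4.4) == 4
        assert round_half_away(0.0) == 0

    def test_empty_vta_gives_zero(self):
        grid = make_grid(20)
        tract = Tract([_line(0, 0)], ["S"], 1)
        vta = _vta_from_box(grid, (0, 0, 0), (0, 0, 0))
        act = proportion_activated(tract, vta)
        assert act.n_activated == 0 and act.percent_rounded == 0

    def test_half_covered_tube_proportion(self):
        """VTA covering the y>0 half of a tube cross-section catches the
        geometric fraction of streamlines within tolerance."""
        rng = np.random.default_rng(4)
        grid = make_grid(20)
        lines, upper = [], 0
        for _ in range(400):
            r = 3.0 * np.sqrt(rng.random())
            th = rng.uniform(0, 2 * np.pi)
            y, z = r * np.cos(th), r * np.sin(th)
            upper += y > 0
            lines.append(_line(y, z))
        tract = Tract(lines, ["S"], 400)
        # slab covering all x/z but only y above the center plane
        vta = _vta_from_box(grid, (0, 10, 0), (20, 20, 20))
        act = proportion_activated(tract, vta)
        assert abs(act.proportion - upper / 400) <= 0.05

    def test_monotone_in_vta_inclusion(self):
        grid = make_grid(20)
        lines = [_line(y, 0.0) for y in np.linspace(-6, 6, 20)]
        tract = Tract(lines, ["S"], 20)
        small = _vta_from_box(grid, (8, 8, 8), (12, 12, 12))
        big = _vta_from_box(grid, (4, 4, 4), (16, 16, 16))
        assert (
            proportion_activated(tract, small).n_activated
            <= proportion_activated(tract, big).n_activated
        )

    def test_empty_tract_rejected(self):
        with pytest.raises(ValueError):
            proportion_activated(Tract([], [], 0), _vta_from_box(make_grid(8), (0, 0, 0), (2, 2, 2)))


class TestPeakProbability:
    @staticmethod
    def _pmap(values, grid):
        return ProbabilityMap(Volume(np.asarray(values, float), grid.affine), 10)

    def test_vta_superset_returns_global_max(self):
        grid = make_grid(6)
        vals = np.random.default_rng(0).random((6, 6, 6))
        pmap = self._pmap(vals, grid)
        vta = _vta_from_box(grid, (0, 0, 0), (6, 6, 6))
        assert peak_probability_in_vta(pmap, vta).peak == pytest.approx(vals.max())

    def test_disjoint_vta_returns_zero(self):
        grid = make_grid(6)
        vals = np.zeros((6, 6, 6))
        vals[0, 0, 0] = 0.8
        vta = _vta_from_box(grid, (3, 3, 3), (6, 6, 6))
        peak = peak_probability_in_vta(self._pmap(vals, grid), vta)
        assert peak.peak == 0.0 and peak.location is None

    def test_three_voxel_vta_exhaustive(self):
        grid = make_grid(6)
        vals = np.zeros((6, 6, 6))
        vals[1, 1, 1], vals[1, 1, 2], vals[1, 2, 1] = 0.11, 0.47, 0.23
        vals[4, 4, 4] = 0.99  # outside the VTA
        vta_vals = np.zeros((6, 6, 6), dtype=bool)
        for v in [(1, 1, 1), (1, 1, 2), (1, 2, 1)]:
            vta_vals[v] = True
        vta = VTA(Mask(vta_vals, grid.affine), 0.2, [])
        peak = peak_probability_in_vta(self._pmap(vals, grid), vta)
        assert peak.peak == pytest.approx(0.47)
        assert peak.location == (1, 1, 2)

    def test_monotone_in_vta_inclusion(self):
        grid = make_grid(6)
        vals = np.random.default_rng(1).random((6, 6, 6))
        small = _vta_from_box(grid, (2, 2, 2), (4, 4, 4))
        big = _vta_from_box(grid, (1, 1, 1), (5, 5, 5))
        pmap = self._pmap(vals, grid)
        assert peak_probability_in_vta(pmap, small).peak <= peak_probability_in_vta(pmap, big).peak


class TestAggregatePatient:
    def test_pooled_ratio(self):
        act, _ = aggregate_patient(
            [ActivationMetrics(5000, 500), ActivationMetrics(5000, 300)],
            [PeakProbability(0.1, None)],
        )
        assert act.n_total == 10000 and act.n_activated == 800
        assert act.proportion == pytest.approx(0.08)

    def test_single_side_identity(self):
        act, peak = aggregate_patient([ActivationMetrics(5000, 798)], [PeakProbability(0.16, None)])
        assert act.n_activated == 798 and peak.peak == 0.16

    def test_peak_is_max_across_sides(self):
        _, peak = aggregate_patient(
            [ActivationMetrics(1, 0)], [PeakProbability(0.23, None), PeakProbability(0.11, None)]
        )
        assert peak.peak == 0.23


class TestPatternClassifier:
    @staticmethod
    def _track_all(cfg, n=150):
        ph = build_phantom(cfg, 0)
        tracts = []
        for i, (name, m) in enumerate(sorted(ph.soz_masks.items())):
            tracts.append(
                track_soz_to_thalamus(
                    ph.field, m, ph.thalamus, ph.brainstem, TrackingParams(n_select=n, seed=i + 1), soz_id=name
                )
            )
        return ph, tracts

    def test_two_bundles_into_cm_are_convergent(self):
        ph, tracts = self._track_all(PhantomConfig(cohort_size=2, seed=3))
        result = classify_pattern(tracts, ph.labels)
        assert result.label == "convergent"
        assert set(result.dominant_nucleus.values()) == {"CM"}

    def test_ant_and_pulv_with_adjoining_routes_are_transthalamic(self):
        cfg = PhantomConfig(
            cohort_size=2,
            seed=3,
            bundles=[
                BundleSpec("SOZ1", io_core.THALAMUS_ANT, via_mm=(-14.0, 13.0, 7.0)),
                BundleSpec("SOZ2", io_core.THALAMUS_PULV, via_mm=(0.0, 3.0, 3.0)),
            ],
        )
        ph, tracts = self._track_all(cfg)
        result = classify_pattern(tracts, ph.labels)
        assert result.label == "transthalamic"
        assert set(result.dominant_nucleus.values()) == {"ANT", "Pulv"}
        assert result.overlap_voxels >= 1

    def test_one_tract_is_single(self):
        from thalnet.phantom import SOZSpec

        cfg = PhantomConfig(
            cohort_size=2,
            seed=3,
            sozs=[SOZSpec("SOZ1", (-24.0, 18.0, 10.0))],
            bundles=[BundleSpec("SOZ1", io_core.THALAMUS_CM, via_mm=(-14.0, 12.0, 8.0))],
        )
        ph, tracts = self._track_all(cfg)
        assert classify_pattern(tracts, ph.labels).label == "single"

    def test_labels_without_thalamus_rejected(self):
        from thalnet.io_core import LabelMap

        grid = make_grid(6)
        labels = LabelMap(
            np.zeros((6, 6, 6), dtype=np.int32), grid.affine, {0: "background", 1: "cortex"}
        )
        tract = Tract([_line(0, 0, -2, 2)], ["S"], 1)
        with pytest.raises(ValueError, match="thalamic"):
            classify_pattern([tract], labels)
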