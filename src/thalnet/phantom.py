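"""Synthetic patients with known ground truth.

Each phantom emulates the imaging inputs of a thalamic-neurostimulation
connectivity analysis on a small grid:

* a label map with cortex, white matter, a brainstem exclusion region, and a
  reduced thalamic segmentation (ANT, CM, MD, Pulv, other);
* cortical SOZ spheres (10 mm radius by default) joined to thalamic nuclei by
  curved white-matter bundles — tubes around cubic-spline centerlines — whose
  orientation lobes follow the centerline tangent (amplitude 1.0) while
  background voxels carry isotropic sub-cutoff lobes (0.05), so the tracker
  cannot leave a bundle;
* a quadripolar depth electrode (3.5 mm contact spacing) whose cathode is
  placed at a controlled offset from the bundle inside the target nucleus —
  the per-patient dial that varies how much of the tract the stimulation
  reaches; and
* a monotone outcome model: seizure reduction is a scaled logistic in the
  true activation proportion plus Gaussian noise, clamped to [0, 100].

Ground truth (centerlines, geometric activation proportion, noise-free
expected reduction) is returned alongside, enabling parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from . import io_core
from .io_core import LabelMap, Mask, Volume
from .stimfield import (
    ConductivityModel,
    ElectrodeModel,
    StimulationSetting,
    VTA,
    compute_vta,
)
from .tracking import OrientationField

__all__ = [
    "SOZSpec",
    "BundleSpec",
    "OutcomeModel",
    "PhantomConfig",
    "Phantom",
    "GroundTruth",
    "build_phantom",
    "generate_cohort",
]


@dataclasses.dataclass
class SOZSpec:
    """A spherical seizure-onset-zone ROI (cortex plus adjacent white matter)."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 10.0
    side: str = "R"


@dataclasses.dataclass
class BundleSpec:
    """A white-matter bundle: tube around a cubic-spline centerline from an
    SOZ to a thalamic nucleus."""

    soz_name: str
    target_label: int  # a thalamic nucleus id from io_core
    via_mm: tuple[float, float, float] | None = None  # optional mid control point
    tube_radius_mm: float = 3.0


@dataclasses.dataclass
class OutcomeModel:
    """Scaled-logistic link from activation proportion to expected seizure
    reduction (%), plus Gaussian noise and clamping to [0, 100].

    ``steepness = 0`` gives a flat link at 50% (a null effect)."""

    midpoint: float = 0.12
    steepness: float = 25.0
    noise_sd: float = 15.0

    def expected(self, proportion) -> np.ndarray:
        p = np.asarray(proportion, dtype=float)
        return 100.0 / (1.0 + np.exp(-self.steepness * (p - self.midpoint)))

    def sample(self, proportion, rng: np.random.Generator) -> np.ndarray:
        p = np.asarray(proportion, dtype=float)
        noisy = self.expected(p) + rng.normal(0.0, self.noise_sd, size=p.shape)
        return np.clip(noisy, 0.0, 100.0)


@dataclasses.dataclass
class PhantomConfig:
    """Study-condition parameters for the synthetic cohort."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_mm: float = 1.0
    sozs: list[SOZSpec] = dataclasses.field(
        default_factory=lambda: [
            SOZSpec("SOZ1", (-24.0, 18.0, 10.0)),
            SOZSpec("SOZ2", (22.0, 16.0, 8.0)),
        ]
    )
    bundles: list[BundleSpec] = dataclasses.field(
        default_factory=lambda: [
            BundleSpec("SOZ1", io_core.THALAMUS_CM, via_mm=(-14.0, 12.0, 8.0)),
            BundleSpec("SOZ2", io_core.THALAMUS_CM, via_mm=(12.0, 10.0, 6.0)),
        ]
    )
    bundle_amplitude: float = 1.0
    background_amplitude: float = 0.05  # below the 0.1 tracking cutoff
    electrode_amplitude_ma: float = 2.0
    electrode_polarity: str = "+-00"  # contact 1 anode, contact 2 cathode
    electrode_spacing_mm: float = 3.5
    max_electrode_offset_mm: float = 6.0
    outcome: OutcomeModel = dataclasses.field(default_factory=OutcomeModel)
    cohort_size: int = 12
    seed: int = 0

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_mm
        aff[:3, 3] = -(np.asarray(self.shape) - 1) / 2 * self.voxel_mm
        return aff


@dataclasses.dataclass
class Phantom:
    """One synthetic patient's imaging inputs."""

    labels: LabelMap
    field: OrientationField
    soz_masks: dict[str, Mask]
    thalamus: Mask
    brainstem: Mask
    electrodes: list[ElectrodeModel]
    settings: list[StimulationSetting]
    centerlines: dict[str, np.ndarray]  # per-bundle sampled centerline (mm)
    electrode_offset_mm: float


@dataclasses.dataclass
class GroundTruth:
    """Per-patient geometric truth for parameter-recovery tests."""

    centerlines: list[dict[str, np.ndarray]]
    true_proportion: np.ndarray
    expected_reduction: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.true_proportion)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("true activation proportions must lie in [0, 1]")


# Fixed nucleus geometry (mm, grid-centered world space): centers and radii of
# the reduced thalamic segmentation, plus the brainstem cylinder.
_NUCLEI: dict[int, tuple[tuple[float, float, float], float]] = {
    io_core.THALAMUS_ANT: ((-4.0, 7.0, 4.0), 4.5),
    io_core.THALAMUS_CM: ((-3.0, -4.0, 0.0), 4.5),
    io_core.THALAMUS_MD: ((1.0, 1.0, 2.0), 4.0),
    io_core.THALAMUS_PULV: ((4.0, -11.0, 2.0), 4.5),
    io_core.THALAMUS_OTHER: ((0.0, -2.0, -4.0), 4.0),
}
_BRAINSTEM_CENTER_XY = (0.0, -8.0)
_BRAINSTEM_RADIUS = 7.0
_BRAINSTEM_Z = (-32.0, -16.0)


def _voxel_centers_mm(config: PhantomConfig) -> np.ndarray:
    aff = config.affine()
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in config.shape], indexing="ij")
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    return vox @ aff[:3, :3].T + aff[:3, 3]


def _sample_centerline(config: PhantomConfig, bundle: BundleSpec, step_mm: float = 0.5) -> np.ndarray:
    soz = next(s for s in config.sozs if s.name == bundle.soz_name)
    target_center = np.asarray(_NUCLEI[bundle.target_label][0])
    ctrl = [np.asarray(soz.center_mm, dtype=float)]
    if bundle.via_mm is not None:
        ctrl.append(np.asarray(bundle.via_mm, dtype=float))
    else:
        ctrl.append((np.asarray(soz.center_mm) + target_center) / 2)
    ctrl.append(target_center)
    ctrl = np.asarray(ctrl)
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(ctrl, axis=0), axis=1))])
    spline = CubicSpline(chord, ctrl, axis=0)
    t = np.arange(0.0, chord[-1] + step_mm / 2, step_mm)
    return np.asarray(spline(t))


def build_phantom(config: PhantomConfig, patient_index: int = 0) -> Phantom:
    """Construct one synthetic patient deterministically from config + seed."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, patient_index]).generate_state(1)[0]
    )
    aff = config.affine()
    shape = tuple(config.shape)
    pts = _voxel_centers_mm(config)
    half_extent = (np.asarray(shape) - 0.5) / 2 * config.voxel_mm

    labels = np.zeros(shape, dtype=np.int32)
    flat = labels.ravel()

    # cortex: SOZ spheres
    soz_masks: dict[str, Mask] = {}
    for soz in config.sozs:
        d = np.linalg.norm(pts - np.asarray(soz.center_mm), axis=1)
        inside = d <= soz.radius_mm
        if not inside.any():
            raise ValueError(f"SOZ {soz.name} lies outside the grid")
        flat[inside & (flat == 0)] = io_core.CORTEX
        soz_masks[soz.name] = Mask(inside.reshape(shape), aff)

    # white-matter bundles + orientation field: one lobe slot per bundle so
    # converging bundles coexist in shared voxels (lobe 0 is the sub-cutoff
    # isotropic background)
    n_lobes = 1 + len(config.bundles)
    directions = np.zeros(shape + (n_lobes, 3))
    amplitudes = np.zeros(shape + (n_lobes,))
    amplitudes[..., 0] = config.background_amplitude
    bg_dirs = rng.normal(size=(int(np.prod(shape)), 3))
    bg_dirs /= np.linalg.norm(bg_dirs, axis=1, keepdims=True)
    directions.reshape(-1, n_lobes, 3)[:, 0, :] = bg_dirs

    centerlines: dict[str, np.ndarray] = {}
    for bi, bundle in enumerate(config.bundles):
        line = _sample_centerline(config, bundle)
        if np.any(np.abs(line) > half_extent):
            raise ValueError(f"bundle {bundle.soz_name} leaves the grid")
        centerlines[bundle.soz_name] = line
        tangents = np.gradient(line, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        tree = cKDTree(line)
        dist, nearest = tree.query(pts, distance_upper_bound=bundle.tube_radius_mm)
        in_tube = np.isfinite(dist)
        idx = np.flatnonzero(in_tube)
        directions.reshape(-1, n_lobes, 3)[idx, 1 + bi] = tangents[nearest[idx]]
        amplitudes.reshape(-1, n_lobes)[idx, 1 + bi] = config.bundle_amplitude
        flat[idx] = io_core.WHITE_MATTER

    # thalamic nuclei (override bundles inside the thalamus) — first label wins
    for label, (center, radius) in _NUCLEI.items():
        d = np.linalg.norm(pts - np.asarray(center), axis=1)
        sel = (d <= radius) & ~np.isin(flat, list(_NUCLEI))
        flat[sel] = label

    # brainstem cylinder
    dxy = np.linalg.norm(pts[:, :2] - np.asarray(_BRAINSTEM_CENTER_XY), axis=1)
    bs = (dxy <= _BRAINSTEM_RADIUS) & (pts[:, 2] >= _BRAINSTEM_Z[0]) & (pts[:, 2] <= _BRAINSTEM_Z[1])
    flat[bs] = io_core.BRAINSTEM

    labelmap = LabelMap(labels, aff)
    thalamus = labelmap.thalamus_mask()
    brainstem = labelmap.mask(io_core.BRAINSTEM)
    field = OrientationField(directions, amplitudes, aff)

    # electrode: cathode placed at a per-patient offset from the target
    # nucleus center, perpendicular to the local bundle direction
    first_bundle = config.bundles[0]
    target_center = np.asarray(_NUCLEI[first_bundle.target_label][0])
    end_tangent = centerlines[first_bundle.soz_name][-1] - centerlines[first_bundle.soz_name][-5]
    end_tangent /= np.linalg.norm(end_tangent)
    elec_dir = np.array([0.15, 0.1, 1.0])
    elec_dir /= np.linalg.norm(elec_dir)
    perp = np.cross(end_tangent, elec_dir)
    perp /= np.linalg.norm(perp)
    if config.cohort_size > 1:
        offset_mm = config.max_electrode_offset_mm * patient_index / (config.cohort_size - 1)
    else:
        offset_mm = 0.0
    cathode_idx = config.electrode_polarity.index("-") if "-" in config.electrode_polarity else 0
    cathode_pos = target_center + offset_mm * perp
    tip = cathode_pos - cathode_idx * config.electrode_spacing_mm * elec_dir
    electrode = ElectrodeModel(tip, elec_dir, side="R", spacing_mm=config.electrode_spacing_mm)
    setting = StimulationSetting(
        config.electrode_polarity, config.electrode_amplitude_ma, side="R"
    )

    return Phantom(
        labels=labelmap,
        field=field,
        soz_masks=soz_masks,
        thalamus=thalamus,
        brainstem=brainstem,
        electrodes=[electrode],
        settings=[setting],
        centerlines=centerlines,
        electrode_offset_mm=offset_mm,
    )


def true_activation_proportion(
    phantom: Phantom,
    vta: VTA,
    config: PhantomConfig,
    n_samples_per_bundle: int = 200,
    seed: int = 12345,
) -> float:
    """Geometric ground truth: the fraction of centerline-parallel curves
    (uniform offsets across the tube cross-section) that pass through the VTA.
    Independent of the tracker."""
    rng = np.random.default_rng(seed)
    total = 0
    hits = 0
    shape = np.asarray(vta.mask.shape)
    for bundle in config.bundles:
        line = phantom.centerlines[bundle.soz_name]
        e1, e2 = _transported_frame(line)
        # effective cross-section: trajectories within half a voxel of the
        # tube wall cannot be sustained by the voxelized corridor (a step at
        # the rough wall exits into sub-cutoff territory), so the corridor's
        # survivable radius is the tube radius minus half a voxel
        r_eff = max(bundle.tube_radius_mm - config.voxel_mm / 2, bundle.tube_radius_mm / 2)
        r = r_eff * np.sqrt(rng.random(n_samples_per_bundle))
        theta = rng.uniform(0, 2 * np.pi, n_samples_per_bundle)
        tan0 = line[0] - line[1]
        tan0 /= np.linalg.norm(tan0)
        tan1 = line[-1] - line[-2]
        tan1 /= np.linalg.norm(tan1)
        for ri, ti in zip(r, theta):
            # offset carried in the rotation-minimizing normal frame, so the
            # curve stays at constant radius inside the curved tube; the tube
            # (a union of balls around centerline samples) has hemispherical
            # end caps, so each curve is extended through them
            curve = line + ri * (np.cos(ti) * e1 + np.sin(ti) * e2)
            # half-voxel shortening: corridor membership is by voxel center
            cap = np.sqrt(max(bundle.tube_radius_mm**2 - ri**2, 0.0))
            cap = max(cap - config.voxel_mm / 2, 0.0)
            n_ext = max(int(cap / 0.5), 1)
            ext0 = curve[0] + tan0[None, :] * np.linspace(0.5, cap, n_ext)[:, None]
            ext1 = curve[-1] + tan1[None, :] * np.linspace(0.5, cap, n_ext)[:, None]
            curve = np.vstack([ext0[::-1], curve, ext1])
            vox = io_core.nearest_voxel(vta.mask, curve)
            ok = np.all((vox >= 0) & (vox < shape), axis=1)
            v = vox[ok]
            hits += bool(vta.mask.values[v[:, 0], v[:, 1], v[:, 2]].any())
            total += 1
    return hits / total


def _transported_frame(line: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-minimizing normal frame (e1, e2) along a polyline."""
    tangents = np.gradient(line, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    e1 = np.empty_like(line)
    a = np.array([1.0, 0.0, 0.0])
    if abs(tangents[0] @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    v = np.cross(tangents[0], a)
    e1[0] = v / np.linalg.norm(v)
    for i in range(1, len(line)):
        v = e1[i - 1] - (e1[i - 1] @ tangents[i]) * tangents[i]
        e1[i] = v / np.linalg.norm(v)
    e2 = np.cross(tangents, e1)
    return e1, e2


def generate_cohort(
    config: PhantomConfig,
    conductivity: ConductivityModel | None = None,
) -> tuple[list[Phantom], pd.DataFrame, GroundTruth]:
    """Build the synthetic cohort and its outcome table.

    Per-patient variation in engagement comes from the electrode offset; the
    outcome is the configured monotone link of the geometric activation
    proportion plus noise (noise sd 0 makes reduction strictly increasing in
    the proportion).
    """
    if config.cohort_size < 1:
        raise ValueError("cohort size must be >= 1")
    conductivity = conductivity or ConductivityModel()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0xC0]).generate_state(1)[0]
    )
    phantoms: list[Phantom] = []
    rows = []
    proportions = []
    for i in range(config.cohort_size):
        ph = build_phantom(config, i)
        phantoms.append(ph)
        vta = compute_vta(
            ph.electrodes[0], ph.settings[0], ph.labels, conductivity, ph.labels
        )
        proportions.append(true_activation_proportion(ph, vta, config))
    proportions = np.asarray(proportions)
    expected = config.outcome.expected(proportions)
    reductions = config.outcome.sample(proportions, rng)
    for i, (p, red) in enumerate(zip(proportions, reductions)):
        pre = 10.0
        post = pre * (1 - red / 100.0)
        rows.append(
            {
                "patient_id": f"P{i + 1:02d}",
                "true_proportion": p,
                "electrode_offset_mm": phantoms[i].electrode_offset_mm,
                "pre_per_month": pre,
                "post_per_month": post,
                "reduction_percent": red,
            }
        )
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        centerlines=[ph.centerlines for ph in phantoms],
        true_proportion=proportions,
        expected_reduction=expected,
    )
    return phantoms, table, truth
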