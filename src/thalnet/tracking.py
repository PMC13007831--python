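"""Probabilistic streamline tractography from SOZ seeds to the thalamus.

The tracker walks an orientation field (per-voxel fiber lobes, the synthetic
stand-in for CSD fiber orientation distributions): at each point the candidate
lobes are those with amplitude at or above the cutoff whose (sign-resolved)
direction lies within the maximum turning angle of the incoming direction; the
next direction is sampled with probability proportional to lobe amplitude.
Tracking is bidirectional from each seed point and a streamline is retained
only if it intersects the thalamus waypoint mask and does not end inside the
brainstem exclusion mask.

Lobes are axial (a fiber runs both ways), so each lobe contributes its
direction and its negation as candidates; the one better aligned with the
incoming direction is used.  Lobe lookup is nearest-voxel, no interpolation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_core import Mask, Tract, Volume, nearest_voxel

__all__ = ["OrientationField", "TrackingParams", "track_soz_to_thalamus", "merge_tracts"]


@dataclasses.dataclass
class OrientationField:
    """Per-voxel fiber lobes: unit directions and non-negative amplitudes.

    ``directions`` has shape (X, Y, Z, L, 3) with L lobes per voxel (unused
    lobes get amplitude 0); ``amplitudes`` has shape (X, Y, Z, L).
    """

    directions: np.ndarray
    amplitudes: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.directions.ndim != 5 or self.directions.shape[-1] != 3:
            raise ValueError("directions must have shape (X, Y, Z, L, 3)")
        if self.amplitudes.shape != self.directions.shape[:4]:
            raise ValueError("amplitudes must have shape (X, Y, Z, L)")
        if not np.all(np.isfinite(self.amplitudes)) or np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be finite and non-negative")
        norms = np.linalg.norm(self.directions, axis=-1)
        active = self.amplitudes > 0
        if np.any(np.abs(norms[active] - 1.0) > 1e-6):
            raise ValueError("active lobe directions must be unit-norm")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.directions.shape[:3]  # type: ignore[return-value]

    @property
    def grid(self) -> Volume:
        return Volume(np.zeros(self.shape, dtype=np.uint8), self.affine)

    def max_amplitude(self) -> float:
        return float(self.amplitudes.max())


@dataclasses.dataclass
class TrackingParams:
    """Tractography controls.  Defaults follow common probabilistic-tracking
    practice; the streamline count and amplitude cutoff are the study's."""

    n_select: int = 5000
    amplitude_cutoff: float = 0.1
    step_mm: float = 0.5
    max_angle_deg: float = 45.0
    max_length_mm: float = 250.0
    max_seed_attempts_factor: int = 100
    seed: int = 0

    def validate(self, field: OrientationField) -> None:
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        if not 0 < self.amplitude_cutoff < field.max_amplitude():
            raise ValueError("amplitude_cutoff must lie in (0, max field amplitude)")
        voxel = np.linalg.norm(field.affine[:3, :3], axis=0).min()
        if not 0 < self.step_mm <= voxel:
            raise ValueError("step must be positive and at most the smallest voxel size")
        if not 0 < self.max_angle_deg < 90:
            raise ValueError("max turning angle must be in (0, 90) degrees")


def _propagate(
    field: OrientationField,
    starts: np.ndarray,
    init_dirs: np.ndarray,
    params: TrackingParams,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Walk all streamlines in lockstep; returns per-streamline point arrays
    (start point included, possibly length 1 if immediately terminated)."""
    n = len(starts)
    max_steps = int(params.max_length_mm / params.step_mm)
    cos_max = np.cos(np.radians(params.max_angle_deg))
    inv = np.linalg.inv(field.affine)
    shape = np.asarray(field.shape)

    pos = starts.copy()
    direc = init_dirs.copy()
    alive = np.ones(n, dtype=bool)
    history = np.empty((max_steps + 1, n, 3))
    history[0] = starts
    lengths = np.ones(n, dtype=int)

    for step in range(max_steps):
        if not alive.any():
            break
        idx = np.flatnonzero(alive)
        vox = np.floor(pos[idx] @ inv[:3, :3].T + inv[:3, 3] + 0.5).astype(int)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        # grid exit: terminate and drop the out-of-grid point
        exited = idx[~inside]
        alive[exited] = False
        lengths[exited] = np.maximum(lengths[exited] - 1, 1)
        idx = idx[inside]
        if idx.size == 0:
            break
        vox = vox[inside]
        amps = field.amplitudes[vox[:, 0], vox[:, 1], vox[:, 2]]  # (m, L)
        dirs = field.directions[vox[:, 0], vox[:, 1], vox[:, 2]]  # (m, L, 3)
        dots = np.einsum("mld,md->ml", dirs, direc[idx])
        signed = np.where(dots[..., None] < 0, -dirs, dirs)
        ok = (amps >= params.amplitude_cutoff) & (np.abs(dots) >= cos_max)
        weights = np.where(ok, amps, 0.0)
        tot = weights.sum(axis=1)
        dead = tot <= 0
        alive[idx[dead]] = False
        live = ~dead
        if not live.any():
            continue
        sub = idx[live]
        w = weights[live] / tot[live, None]
        # inverse-CDF sampling of one lobe per streamline
        cdf = np.cumsum(w, axis=1)
        u = rng.random(len(sub))
        choice = (u[:, None] > cdf).sum(axis=1)
        newdir = signed[live][np.arange(len(sub)), choice]
        direc[sub] = newdir
        pos[sub] = pos[sub] + params.step_mm * newdir
        history[step + 1, sub] = pos[sub]
        lengths[sub] = step + 2

    return [history[: lengths[i], i].copy() for i in range(n)]


def _mask_lookup(mask: Mask, points: np.ndarray) -> np.ndarray:
    """Boolean per point: does the point fall in a True voxel of ``mask``."""
    vox = nearest_voxel(mask, points)
    shape = np.asarray(mask.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    out = np.zeros(len(points), dtype=bool)
    v = vox[inside]
    out[inside] = mask.values[v[:, 0], v[:, 1], v[:, 2]]
    return out


def track_soz_to_thalamus(
    field: OrientationField,
    seed: Mask,
    thalamus: Mask,
    brainstem: Mask | None,
    params: TrackingParams,
    soz_id: str = "SOZ",
) -> Tract:
    """Seed in the SOZ mask, keep streamlines that visit the thalamus and do
    not terminate in the brainstem.

    Generation proceeds in batches of seed points until ``n_select``
    streamlines are retained or ``max_seed_attempts_factor * n_select`` seeds
    have been tried.  A seed lying in sub-cutoff territory simply produces no
    retained streamline; a fully sub-cutoff seed region yields an empty tract.
    """
    params.validate(field)
    for m, name in ((seed, "seed"), (thalamus, "thalamus")):
        if tuple(m.shape) != tuple(field.shape) or not np.allclose(m.affine, field.affine):
            raise ValueError(f"{name} mask is not on the orientation-field grid")
    if seed.n_voxels == 0:
        raise ValueError("seed mask is empty")

    rng = np.random.default_rng(params.seed)
    seed_vox = np.argwhere(seed.values)
    grid = field.grid
    retained: list[np.ndarray] = []
    attempts = 0
    max_attempts = params.max_seed_attempts_factor * params.n_select
    batch = max(64, min(params.n_select, 2048))

    while len(retained) < params.n_select and attempts < max_attempts:
        nb = min(batch, max_attempts - attempts)
        attempts += nb
        picks = seed_vox[rng.integers(0, len(seed_vox), size=nb)]
        # jitter uniformly within the voxel so seeds fill the ROI volume
        cont = picks + rng.uniform(-0.5, 0.5, size=(nb, 3))
        starts = cont @ field.affine[:3, :3].T + field.affine[:3, 3]
        # initial direction: sample among supra-cutoff lobes ∝ amplitude
        amps = field.amplitudes[picks[:, 0], picks[:, 1], picks[:, 2]]
        dirs = field.directions[picks[:, 0], picks[:, 1], picks[:, 2]]
        ok = amps >= params.amplitude_cutoff
        tot = np.where(ok, amps, 0.0).sum(axis=1)
        viable = tot > 0
        if not viable.any():
            continue
        starts = starts[viable]
        w = np.where(ok, amps, 0.0)[viable] / tot[viable, None]
        cdf = np.cumsum(w, axis=1)
        u = rng.random(len(starts))
        choice = (u[:, None] > cdf).sum(axis=1)
        init = dirs[viable][np.arange(len(starts)), choice]

        fwd = _propagate(field, starts, init, params, rng)
        bwd = _propagate(field, starts, -init, params, rng)
        for f, b in zip(fwd, bwd):
            line = np.vstack([b[::-1], f[1:]]) if len(b) > 1 else f
            if len(line) < 2:
                continue
            if not _mask_lookup(thalamus, line).any():
                continue
            if brainstem is not None and (
                _mask_lookup(brainstem, line[:1])[0] or _mask_lookup(brainstem, line[-1:])[0]
            ):
                continue
            retained.append(line)
            if len(retained) >= params.n_select:
                break

    return Tract(retained, soz_ids=[soz_id], n_requested=params.n_select, step_mm=params.step_mm)


def merge_tracts(tracts: list[Tract]) -> Tract:
    """Pool per-SOZ tracts into the single per-patient tract used downstream."""
    if not tracts:
        raise ValueError("cannot merge an empty list of tracts")
    steps = {t.step_mm for t in tracts}
    if len(steps) > 1:
        raise ValueError("tracts use different step lengths")
    lines: list[np.ndarray] = []
    ids: list[str] = []
    n_req = 0
    for t in tracts:
        lines.extend(t.streamlines)
        ids.extend(t.soz_ids)
        n_req += t.n_requested
    return Tract(lines, soz_ids=ids, n_requested=n_req, step_mm=tracts[0].step_mm)
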