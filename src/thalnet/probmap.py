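"""Track-density probability-of-connectivity maps and the 95% mass threshold.

The probability of connectivity at a voxel is the fraction of the tract's
streamlines with at least one point in that voxel (distinct-streamline
counting, so values stay in [0, 1]).  Thresholding "at 95%" retains the
top-valued voxels that together carry 95% of the total visitation mass and
zeroes the diffuse tail; a percentile interpretation (zero voxels below the
5th percentile of nonzero values) is available as an alternative.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_core import Tract, Volume, nearest_voxel

__all__ = ["ProbabilityMap", "tract_to_probability_map", "threshold_map"]


@dataclasses.dataclass
class ProbabilityMap:
    """Voxelwise streamline-visitation fraction for one tract."""

    volume: Volume
    n_streamlines: int
    thresholded: bool = False
    threshold_mass: float | None = None
    raw_total_mass: float | None = None  # visitation mass of the raw map

    @property
    def values(self) -> np.ndarray:
        return self.volume.values

    def peak(self) -> float:
        return float(self.values.max())


def tract_to_probability_map(tract: Tract, grid: Volume) -> ProbabilityMap:
    """Raw visitation-fraction map: value(v) = #streamlines visiting v / n."""
    if tract.n_retained < 1:
        raise ValueError("cannot build a probability map from an empty tract")
    counts = np.zeros(grid.shape, dtype=np.int64)
    shape = np.asarray(grid.shape)
    for line in tract.streamlines:
        vox = nearest_voxel(grid, line)
        vox = vox[np.all((vox >= 0) & (vox < shape), axis=1)]
        if len(vox) == 0:
            continue
        uniq = np.unique(vox, axis=0)
        counts[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    values = counts / tract.n_retained
    return ProbabilityMap(
        Volume(values, grid.affine), tract.n_retained, raw_total_mass=float(values.sum())
    )


def threshold_map(pmap: ProbabilityMap, mass: float = 0.95) -> ProbabilityMap:
    """Retain the smallest set of top-valued voxels carrying >= ``mass`` of the
    total visitation mass; ties at the boundary value are all retained."""
    if not 0 < mass <= 1:
        raise ValueError("mass must lie in (0, 1]")
    values = pmap.values
    flat = values.ravel()
    # the mass target is relative to the *raw* map's total so that
    # re-thresholding an already-thresholded map at the same mass is a no-op
    total = pmap.raw_total_mass if pmap.raw_total_mass is not None else float(flat.sum())
    if total == 0 or flat.sum() == 0:
        raise ValueError("probability map has no visitation mass")
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, mass * total - 1e-12)) + 1
    k = min(k, len(flat))
    boundary = flat[order[k - 1]]
    keep = flat >= boundary if boundary > 0 else flat > 0
    out = np.where(keep.reshape(values.shape), values, 0.0)
    return ProbabilityMap(
        Volume(out, pmap.volume.affine),
        pmap.n_streamlines,
        thresholded=True,
        threshold_mass=mass,
        raw_total_mass=total,
    )


def threshold_map_percentile(pmap: ProbabilityMap, percentile: float = 5.0) -> ProbabilityMap:
    """Alternative reading of the 95% rule: zero voxels whose value falls below
    the given percentile of the nonzero values."""
    values = pmap.values
    nz = values[values > 0]
    if nz.size == 0:
        raise ValueError("probability map has no visitation mass")
    cut = np.percentile(nz, percentile)
    out = np.where(values >= cut, values, 0.0)
    return ProbabilityMap(
        Volume(out, pmap.volume.affine),
        pmap.n_streamlines,
        thresholded=True,
        threshold_mass=None,
    )
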