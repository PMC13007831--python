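"""Volumetric, streamline, and tabular data model shared by all pipeline stages.

Conventions
-----------
* World space is RAS millimetres; voxel indices are 0-based.
* The affine maps *voxel-center* coordinates to mm: world = A @ (i, j, k, 1).
* A continuous point belongs to the voxel whose center is nearest, i.e. its
  continuous voxel coordinates rounded half up (``floor(x + 0.5)``).

Files are NIfTI-1 for volumes and label maps, TCK for streamlines, CSV for
tables.  All readers/writers are thin wrappers over nibabel.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "Mask",
    "LabelMap",
    "Streamline",
    "Tract",
    "world_to_voxel",
    "voxel_to_world",
    "nearest_voxel",
    "read_volume",
    "write_volume",
    "read_streamlines",
    "write_streamlines",
    "VolumeParseError",
]

# Canonical tissue / nucleus labels used by the phantoms.  The dictionary is
# open: phantoms may add labels, but these ids are stable.
BACKGROUND = 0
CORTEX = 1
WHITE_MATTER = 2
BRAINSTEM = 3
THALAMUS_ANT = 10
THALAMUS_CM = 11
THALAMUS_MD = 12
THALAMUS_PULV = 13
THALAMUS_OTHER = 14

DEFAULT_LABELS: dict[int, str] = {
    BACKGROUND: "background",
    CORTEX: "cortex",
    WHITE_MATTER: "white_matter",
    BRAINSTEM: "brainstem",
    THALAMUS_ANT: "ANT",
    THALAMUS_CM: "CM",
    THALAMUS_MD: "MD",
    THALAMUS_PULV: "Pulv",
    THALAMUS_OTHER: "other",
}

THALAMIC_LABELS = (
    THALAMUS_ANT,
    THALAMUS_CM,
    THALAMUS_MD,
    THALAMUS_PULV,
    THALAMUS_OTHER,
)


class VolumeParseError(ValueError):
    """Raised when a volume file cannot be parsed; names the offending field."""


@dataclasses.dataclass
class Volume:
    """A 3-D scalar grid with an affine mapping voxel indices to mm (RAS)."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(f"expected a nonempty 3-D grid, got shape {self.values.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("volume values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "Volume") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def empty_like(self, dtype=float) -> "Volume":
        return Volume(np.zeros(self.shape, dtype=dtype), self.affine.copy())


class Mask(Volume):
    """Boolean volume on a reference grid (SOZ ROI, thalamus, brainstem, VTA)."""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        super().__post_init__()

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3


@dataclasses.dataclass
class LabelMap(Volume):
    """Integer-labelled volume with an open label dictionary."""

    labels: dict[int, str] = dataclasses.field(default_factory=lambda: dict(DEFAULT_LABELS))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("label map values must be integers")
        if self.values.min() < 0:
            raise ValueError("labels must be non-negative")
        super().__post_init__()
        present = set(np.unique(self.values)) - {0}
        missing = present - set(self.labels)
        if missing:
            raise ValueError(f"labels {sorted(missing)} present in map but not in dictionary")

    def mask(self, *label_ids: int) -> Mask:
        return Mask(np.isin(self.values, label_ids), self.affine)

    def thalamus_mask(self) -> Mask:
        return self.mask(*THALAMIC_LABELS)


def world_to_voxel(volume: Volume, points_mm: np.ndarray) -> np.ndarray:
    """Map world-space point(s) in mm to continuous 0-based voxel coordinates."""
    inv = np.linalg.inv(volume.affine)
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    out = pts @ inv[:3, :3].T + inv[:3, 3]
    return out[0] if np.asarray(points_mm).ndim == 1 else out


def voxel_to_world(volume: Volume, voxel: np.ndarray) -> np.ndarray:
    """Map continuous voxel coordinates to world mm."""
    vox = np.atleast_2d(np.asarray(voxel, dtype=float))
    out = vox @ volume.affine[:3, :3].T + volume.affine[:3, 3]
    return out[0] if np.asarray(voxel).ndim == 1 else out


def nearest_voxel(volume: Volume, points_mm: np.ndarray) -> np.ndarray:
    """Integer voxel index of the voxel whose center is nearest (round half up)."""
    cont = np.atleast_2d(world_to_voxel(volume, points_mm))
    idx = np.floor(cont + 0.5).astype(int)
    return idx[0] if np.asarray(points_mm).ndim == 1 else idx


@dataclasses.dataclass
class Streamline:
    """An ordered polyline in mm space with a nominal step length."""

    points: np.ndarray
    step_mm: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2 or self.points.shape[1] != 3:
            raise ValueError("a streamline needs >= 2 points in 3-D")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("streamline coordinates must be finite")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(np.abs(seg - self.step_mm) > 0.1 * self.step_mm):
            raise ValueError("consecutive-point spacing deviates > 10% from step length")

    def __len__(self) -> int:
        return len(self.points)


@dataclasses.dataclass
class Tract:
    """Streamlines from one (or, after merging, several) SOZ ROI(s) that
    reached the thalamus, with provenance."""

    streamlines: list[np.ndarray]
    soz_ids: list[str]
    n_requested: int
    step_mm: float = 0.5

    @property
    def n_retained(self) -> int:
        return len(self.streamlines)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.streamlines)


# ---------------------------------------------------------------------------
# File round-trip
# ---------------------------------------------------------------------------

def write_volume(path: str | Path, volume: Volume) -> None:
    data = volume.values
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, volume.affine)
    nib.save(img, str(path))


def read_volume(path: str | Path, kind: str = "volume", labels: dict[int, str] | None = None) -> Volume:
    """Read a NIfTI volume.

    ``kind`` selects the returned type: ``volume`` | ``mask`` | ``labels``.
    Malformed files raise :class:`VolumeParseError` naming the bad header field.
    """
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # noqa: BLE001 - reraised with context
        raise VolumeParseError(f"cannot parse {path}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeParseError(f"{path}: header field 'dim' is {data.ndim}-D, expected 3-D")
    if affine is None or abs(np.linalg.det(np.asarray(affine)[:3, :3])) < 1e-12:
        raise VolumeParseError(f"{path}: header field 'affine' (srow/qform) is singular")
    if kind == "mask":
        return Mask(data.astype(bool), affine)
    if kind == "labels":
        return LabelMap(data.astype(np.int32), affine, labels or dict(DEFAULT_LABELS))
    return Volume(data, affine)


def write_streamlines(path: str | Path, tract: Tract) -> None:
    """Write a tract to TCK, preserving order; empty tracts give a valid
    zero-track file."""
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in tract.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    tck = nib.streamlines.TckFile(tractogram)
    tck.save(str(path))


def read_streamlines(path: str | Path, step_mm: float = 0.5) -> Tract:
    tck = nib.streamlines.load(str(path))
    lines = [np.asarray(s, dtype=float) for s in tck.streamlines]
    return Tract(lines, soz_ids=[], n_requested=len(lines), step_mm=step_mm)


def write_manifest(run_dir: str | Path, entries: dict, seed: int, config_hash: str) -> Path:
    """Record run artifacts with checksums for reproducibility audits."""
    import hashlib

    run_dir = Path(run_dir)
    manifest = {"seed": seed, "config_hash": config_hash, "artifacts": {}}
    for name, rel in entries.items():
        p = run_dir / rel
        digest = hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None
        manifest["artifacts"][name] = {"path": str(rel), "sha256": digest}
    out = run_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2))
    return out
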