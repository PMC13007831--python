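"""Engagement metrics linking the SOZ→thalamus tract to the stimulation field.

Two per-patient quantities drive the outcome analyses:

* the *activation proportion* — the fraction of the merged tract's
  streamlines with at least one point inside the (merged) VTA; and
* the *peak probability* — the maximum probability-of-connectivity value of
  the (thresholded) map inside the VTA.

A heuristic classifier also labels multi-SOZ connectivity patterns as
``convergent`` (several tracts dominated by the same thalamic nucleus),
``transthalamic`` (different dominant nuclei whose thalamic footprints touch),
``single``, or ``unclassified``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import io_core
from .io_core import LabelMap, Tract, nearest_voxel
from .probmap import ProbabilityMap
from .stimfield import VTA

__all__ = [
    "ActivationMetrics",
    "PeakProbability",
    "PatternLabel",
    "proportion_activated",
    "peak_probability_in_vta",
    "aggregate_patient",
    "classify_pattern",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round half away from zero (so 4.5 -> 5), unlike banker's rounding."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


@dataclasses.dataclass
class ActivationMetrics:
    n_total: int
    n_activated: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_activated <= self.n_total:
            raise ValueError("need 0 <= n_activated <= n_total")

    @property
    def proportion(self) -> float:
        return self.n_activated / self.n_total

    @property
    def percent_rounded(self) -> int:
        return round_half_away(100 * self.proportion)


@dataclasses.dataclass
class PeakProbability:
    peak: float
    location: tuple[int, int, int] | None

    def __post_init__(self) -> None:
        if not 0 <= self.peak <= 1:
            raise ValueError("peak probability must be in [0, 1]")


@dataclasses.dataclass
class PatternLabel:
    label: str  # convergent | transthalamic | single | unclassified
    dominant_nucleus: dict[str, str]  # per-tract dominant thalamic nucleus name
    overlap_voxels: int  # shared thalamic visitation voxels across tracts


def _streamline_in_mask(tract: Tract, mask_values: np.ndarray, grid) -> np.ndarray:
    """Per-streamline bool: any point inside a True voxel."""
    shape = np.asarray(mask_values.shape)
    hits = np.zeros(tract.n_retained, dtype=bool)
    for i, line in enumerate(tract.streamlines):
        vox = nearest_voxel(grid, line)
        vox = vox[np.all((vox >= 0) & (vox < shape), axis=1)]
        if len(vox) and mask_values[vox[:, 0], vox[:, 1], vox[:, 2]].any():
            hits[i] = True
    return hits


def proportion_activated(tract: Tract, vta: VTA) -> ActivationMetrics:
    """Count streamlines with any point inside the VTA."""
    if tract.n_retained == 0:
        raise ValueError("tract has no streamlines")
    hits = _streamline_in_mask(tract, vta.mask.values, vta.mask)
    return ActivationMetrics(n_total=tract.n_retained, n_activated=int(hits.sum()))


def peak_probability_in_vta(pmap: ProbabilityMap, vta: VTA) -> PeakProbability:
    """Highest connectivity-probability value inside the VTA; 0 if the VTA
    misses the map's support.  Ties resolve to the lowest voxel index."""
    if tuple(pmap.volume.shape) != tuple(vta.mask.shape):
        raise ValueError("probability map and VTA are not on a shared grid")
    inside = np.where(vta.mask.values, pmap.values, 0.0)
    peak = float(inside.max()) if inside.size else 0.0
    if peak <= 0:
        return PeakProbability(0.0, None)
    loc = np.unravel_index(int(np.argmax(inside)), inside.shape)  # argmax = lowest flat index
    return PeakProbability(peak, tuple(int(v) for v in loc))


def aggregate_patient(
    activations: list[ActivationMetrics], peaks: list[PeakProbability]
) -> tuple[ActivationMetrics, PeakProbability]:
    """Pool per-side/per-tract metrics into one number per patient: summed
    counts for the proportion, max across sides for the peak."""
    if not activations or not peaks:
        raise ValueError("need at least one per-side metric")
    pooled = ActivationMetrics(
        n_total=sum(a.n_total for a in activations),
        n_activated=sum(a.n_activated for a in activations),
    )
    best = max(peaks, key=lambda p: p.peak)
    return pooled, best


def classify_pattern(tracts: list[Tract], labels: LabelMap) -> PatternLabel:
    """Heuristic multi-SOZ connectivity taxonomy.

    Dominant nucleus per tract = the thalamic label whose voxels the tract's
    streamlines visit most.  Two or more tracts sharing a dominant nucleus ->
    convergent; all distinct dominant nuclei but overlapping thalamic
    footprints -> transthalamic; one tract -> single; else unclassified.
    """
    thal_ids = [i for i in io_core.THALAMIC_LABELS if i in labels.labels]
    if not thal_ids:
        raise ValueError("label map has no thalamic nucleus labels")
    if any(t.n_retained == 0 for t in tracts):
        raise ValueError("all tracts must have retained streamlines")
    if len(tracts) == 1:
        return PatternLabel("single", _dominant_nuclei(tracts, labels, thal_ids), 0)

    dom = _dominant_nuclei(tracts, labels, thal_ids)
    footprints = [_thalamic_footprint(t, labels, thal_ids) for t in tracts]
    names = list(dom.values())
    overlap = 0
    for i in range(len(footprints)):
        for j in range(i + 1, len(footprints)):
            overlap += int((footprints[i] & footprints[j]).sum())
    if len(set(names)) < len(names):
        return PatternLabel("convergent", dom, overlap)
    if overlap >= 1:
        return PatternLabel("transthalamic", dom, overlap)
    return PatternLabel("unclassified", dom, overlap)


def _thalamic_footprint(tract: Tract, labels: LabelMap, thal_ids: list[int]) -> np.ndarray:
    thal = np.isin(labels.values, thal_ids)
    visited = np.zeros(labels.shape, dtype=bool)
    shape = np.asarray(labels.shape)
    for line in tract.streamlines:
        vox = nearest_voxel(labels, line)
        vox = vox[np.all((vox >= 0) & (vox < shape), axis=1)]
        visited[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return visited & thal


def _dominant_nuclei(tracts: list[Tract], labels: LabelMap, thal_ids: list[int]) -> dict[str, str]:
    """Dominant nucleus per tract: the thalamic label holding the most
    streamline *endpoints*; if no endpoint lands in the thalamus (e.g. tracts
    passing through), the label with the most visited points."""
    out: dict[str, str] = {}
    shape = np.asarray(labels.shape)
    for t in tracts:
        end_counts = {i: 0 for i in thal_ids}
        visit_counts = {i: 0 for i in thal_ids}
        for line in t.streamlines:
            vox = nearest_voxel(labels, line)
            ok = np.all((vox >= 0) & (vox < shape), axis=1)
            lab = labels.values[vox[ok, 0], vox[ok, 1], vox[ok, 2]]
            for i in thal_ids:
                visit_counts[i] += int((lab == i).sum())
            for end in (0, -1):
                if ok[end]:
                    v = vox[end]
                    li = int(labels.values[v[0], v[1], v[2]])
                    if li in end_counts:
                        end_counts[li] += 1
        counts = end_counts if any(end_counts.values()) else visit_counts
        best = max(counts, key=counts.get)  # type: ignore[arg-type]
        key = "+".join(t.soz_ids) if t.soz_ids else f"tract{len(out)}"
        out[key] = labels.labels[best]
    return out
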