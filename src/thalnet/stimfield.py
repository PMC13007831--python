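"""Electrode model, stimulation-setting notation, electric field, and VTA.

The electric field is an analytic point-source superposition: each active
contact is a monopole carrying a share of the programmed current, and the
field magnitude at r is

    |E|(r) = || sum_k  I_k (r - c_k) / (4 pi sigma(r) ||r - c_k||^3) ||

with I_k the signed contact current (cathodes share -amplitude, anodes share
+amplitude equally) and sigma(r) the scalar conductivity of the tissue at r
(gray or white matter).  The binary volume of tissue activated (VTA) is the
set of voxels whose center field magnitude reaches the activation threshold,
0.2 V/mm by default.  For a single cathode in homogeneous tissue this gives
a sphere of radius r* = sqrt(I / (4 pi sigma E*)), which is the closed-form
oracle used by the tests.

This is a deliberately simple forward model — no finite elements, electrode
encapsulation, or anisotropic conductivity — chosen so every output can be
checked against closed forms.
"""

from __future__ import annotations

import dataclasses
import re

import numpy as np

from .io_core import LabelMap, Mask, Volume, voxel_to_world
from . import io_core

__all__ = [
    "ElectrodeModel",
    "StimulationSetting",
    "ConductivityModel",
    "VTA",
    "parse_stim_string",
    "electric_field_magnitude",
    "compute_vta",
    "merge_vtas",
]

N_CONTACTS = 4
DEFAULT_SPACING_MM = 3.5
DEFAULT_E_THRESHOLD = 0.2  # V/mm
# |E| is capped at this value when evaluated at a contact center, where the
# point-source expression diverges
FIELD_CAP_V_PER_MM = 1e6


@dataclasses.dataclass
class ElectrodeModel:
    """Quadripolar depth electrode; contact 1 is the most distal."""

    tip_mm: np.ndarray
    direction: np.ndarray
    side: str
    spacing_mm: float = DEFAULT_SPACING_MM
    n_contacts: int = N_CONTACTS

    def __post_init__(self) -> None:
        self.tip_mm = np.asarray(self.tip_mm, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if norm < 1e-12:
            raise ValueError("electrode direction must be nonzero")
        self.direction = self.direction / norm
        if self.spacing_mm <= 0:
            raise ValueError("contact spacing must be positive")
        if self.side not in ("L", "R"):
            raise ValueError("side must be 'L' or 'R'")

    def contact_centers(self) -> np.ndarray:
        """(n_contacts, 3) contact-center positions, distal to proximal."""
        offsets = np.arange(self.n_contacts) * self.spacing_mm
        return self.tip_mm[None, :] + offsets[:, None] * self.direction[None, :]


@dataclasses.dataclass
class StimulationSetting:
    """One side's programmed stimulation: per-contact polarity and current."""

    polarity: str  # 4 chars from {+, -, 0}; index 0 = contact 1 (distal)
    amplitude_ma: float  # total cathodic current
    side: str
    pulse_width_us: float | None = None  # metadata, unused by the field model
    frequency_hz: float | None = None

    def __post_init__(self) -> None:
        if len(self.polarity) != N_CONTACTS:
            raise ValueError(f"polarity string must have {N_CONTACTS} characters")
        if set(self.polarity) - set("+-0"):
            raise ValueError(f"unknown polarity character in {self.polarity!r}")
        if self.amplitude_ma < 0:
            raise ValueError("amplitude must be >= 0")
        if self.amplitude_ma > 0 and "-" not in self.polarity:
            raise ValueError("an active setting needs at least one cathode")

    def contact_currents_ma(self) -> np.ndarray:
        """Signed per-contact currents: cathodes share -amplitude, anodes
        share +amplitude, each split equally within its polarity group."""
        currents = np.zeros(N_CONTACTS)
        if self.amplitude_ma == 0:
            return currents
        cathodes = [i for i, c in enumerate(self.polarity) if c == "-"]
        anodes = [i for i, c in enumerate(self.polarity) if c == "+"]
        for i in cathodes:
            currents[i] = -self.amplitude_ma / len(cathodes)
        for i in anodes:
            currents[i] = self.amplitude_ma / len(anodes)
        return currents


@dataclasses.dataclass
class ConductivityModel:
    """Scalar tissue conductivities.  The defaults are the standard gray- and
    white-matter values; ``literal_s_per_mm`` interprets them as S/mm instead
    of S/m (three orders of magnitude more conductive, giving sub-millimetre
    activation volumes)."""

    sigma_gray: float = 0.33  # S/m
    sigma_white: float = 0.14  # S/m
    literal_s_per_mm: bool = False

    def __post_init__(self) -> None:
        if self.sigma_gray <= 0 or self.sigma_white <= 0:
            raise ValueError("conductivities must be positive")

    def sigma_s_per_mm(self, is_gray: np.ndarray) -> np.ndarray:
        """Conductivity in S/mm at each query point (bool array: gray?)."""
        sigma = np.where(is_gray, self.sigma_gray, self.sigma_white)
        return sigma if self.literal_s_per_mm else sigma / 1000.0


@dataclasses.dataclass
class VTA:
    """Binary activation volume for one (or a union of) stimulation setting(s)."""

    mask: Mask
    threshold_v_per_mm: float
    settings: list[StimulationSetting]

    @property
    def volume_mm3(self) -> float:
        return self.mask.volume_mm3


def parse_stim_string(text: str) -> list[tuple[str, StimulationSetting]]:
    """Parse the per-side polarity/amplitude notation, e.g. ``"L: +-00 2 R: 0+-0 .5"``.

    Each clause is ``SIDE: PPPP AMP`` with P in {+, -, 0} (contact 1 first)
    and AMP the total cathodic current in mA.  Unicode minus is accepted.
    """
    if not text or not text.strip():
        raise ValueError("empty stimulation string")
    cleaned = text.replace("−", "-").replace("‐", "-")
    out: list[tuple[str, StimulationSetting]] = []
    for m in re.finditer(r"([LR])\s*:\s*(\S+)\s+(\S+)", cleaned):
        side, pol, amp_txt = m.group(1), m.group(2), m.group(3)
        if len(pol) != N_CONTACTS:
            raise ValueError(
                f"polarity string {pol!r} at position {m.start(2)} has length "
                f"{len(pol)}, expected {N_CONTACTS}"
            )
        bad = set(pol) - set("+-0")
        if bad:
            raise ValueError(f"unknown polarity character {bad.pop()!r} at position {m.start(2)}")
        try:
            amp = float(amp_txt)
        except ValueError:
            raise ValueError(f"missing or malformed amplitude {amp_txt!r} at position {m.start(3)}") from None
        out.append((side, StimulationSetting(pol, amp, side)))
    if not out:
        raise ValueError(f"no 'SIDE: PPPP AMP' clause found in {text!r} (position 0)")
    return out


def _is_gray(labels: LabelMap | None, points_mm: np.ndarray) -> np.ndarray:
    """Gray-matter query: cortex and thalamic nuclei count as gray; everything
    else (white matter, background, outside the grid) as white."""
    if labels is None:
        return np.zeros(len(points_mm), dtype=bool)
    vox = io_core.nearest_voxel(labels, points_mm)
    shape = np.asarray(labels.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    out = np.zeros(len(points_mm), dtype=bool)
    v = vox[inside]
    lab = labels.values[v[:, 0], v[:, 1], v[:, 2]]
    gray = (lab == io_core.CORTEX) | np.isin(lab, io_core.THALAMIC_LABELS)
    out[inside] = gray
    return out


def electric_field_magnitude(
    electrode: ElectrodeModel,
    setting: StimulationSetting,
    labels: LabelMap | None,
    conductivity: ConductivityModel,
    points_mm: np.ndarray,
) -> np.ndarray:
    """|E| in V/mm at the query point(s) for the point-source superposition."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    currents = setting.contact_currents_ma() / 1000.0  # A
    sigma = conductivity.sigma_s_per_mm(_is_gray(labels, pts))  # S/mm
    field = np.zeros((len(pts), 3))
    for c, i_k in zip(electrode.contact_centers(), currents):
        if i_k == 0:
            continue
        d = pts - c[None, :]
        r = np.linalg.norm(d, axis=1)
        r3 = np.where(r > 1e-9, r**3, np.inf)  # at the contact: contribution capped below
        field += i_k * d / (4 * np.pi * sigma[:, None] * r3[:, None])
    mag = np.linalg.norm(field, axis=1)
    at_contact = np.zeros(len(pts), dtype=bool)
    if setting.amplitude_ma > 0:
        for c, i_k in zip(electrode.contact_centers(), currents):
            if i_k != 0:
                at_contact |= np.linalg.norm(pts - c[None, :], axis=1) <= 1e-9
    mag = np.where(at_contact, FIELD_CAP_V_PER_MM, np.minimum(mag, FIELD_CAP_V_PER_MM))
    return mag[0] if np.asarray(points_mm).ndim == 1 else mag


def compute_vta(
    electrode: ElectrodeModel,
    setting: StimulationSetting,
    labels: LabelMap | None,
    conductivity: ConductivityModel,
    grid: Volume,
    threshold_v_per_mm: float = DEFAULT_E_THRESHOLD,
) -> VTA:
    """Binary VTA: voxels whose center field magnitude reaches the threshold."""
    inv = np.linalg.inv(grid.affine)
    tip_vox = np.asarray(electrode.tip_mm) @ inv[:3, :3].T + inv[:3, 3]
    if np.any(tip_vox < -0.5) or np.any(tip_vox > np.asarray(grid.shape) - 0.5):
        raise ValueError("electrode tip lies outside the grid")
    if setting.amplitude_ma == 0:
        return VTA(Mask(np.zeros(grid.shape, dtype=bool), grid.affine), threshold_v_per_mm, [setting])
    # evaluate only within a generous bounding box around the contacts
    centers = electrode.contact_centers()
    currents = setting.contact_currents_ma() / 1000.0
    sigma_min = min(conductivity.sigma_gray, conductivity.sigma_white)
    sigma_min = sigma_min if conductivity.literal_s_per_mm else sigma_min / 1000.0
    i_max = np.abs(currents).sum()
    r_max = np.sqrt(i_max / (4 * np.pi * sigma_min * threshold_v_per_mm)) * 2 + 2
    lo_mm = centers.min(axis=0) - r_max
    hi_mm = centers.max(axis=0) + r_max
    corners_vox = np.array(
        [np.array(c) @ inv[:3, :3].T + inv[:3, 3] for c in
         [[x, y, z] for x in (lo_mm[0], hi_mm[0]) for y in (lo_mm[1], hi_mm[1]) for z in (lo_mm[2], hi_mm[2])]]
    )
    lo = np.maximum(np.floor(corners_vox.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(corners_vox.max(axis=0)).astype(int) + 1, np.asarray(grid.shape))
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]), indexing="ij"
    )
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    pts = voxel_to_world(grid, vox.astype(float))
    mag = electric_field_magnitude(electrode, setting, labels, conductivity, pts)
    active = mag >= threshold_v_per_mm
    values = np.zeros(grid.shape, dtype=bool)
    v = vox[active]
    values[v[:, 0], v[:, 1], v[:, 2]] = True
    return VTA(Mask(values, grid.affine), threshold_v_per_mm, [setting])


def merge_vtas(vtas: list[VTA]) -> VTA:
    """Voxelwise union of per-side VTAs (bilateral stimulation)."""
    if not vtas:
        raise ValueError("cannot merge an empty list of VTAs")
    ref = vtas[0].mask
    union = np.zeros(ref.shape, dtype=bool)
    settings: list[StimulationSetting] = []
    for v in vtas:
        if not v.mask.same_grid(ref):
            raise ValueError("VTAs are not on a shared grid")
        union |= v.mask.values
        settings.extend(v.settings)
    return VTA(Mask(union, ref.affine), vtas[0].threshold_v_per_mm, settings)
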