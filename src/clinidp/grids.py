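"""Voxel-grid containers shared by all imaging operators.

Every map consumed here (tissue partial-volume estimates, lesion and
structure masks, diffusion scalar maps, tract density maps) lives on one
common voxel grid -- spatial registration happens upstream and is not
re-done.  :class:`VolumeGrid` is that shared unit: a 3D scalar field plus
its voxel dimensions in millimetres, from which all volumes are computed
as (weighted) voxel counts times the voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "SubjectImagery", "AtlasBundle"]


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D scalar field on a regular grid.

    Parameters
    ----------
    data:
        3D array of finite values.  Binary masks hold {0, 1}; partial-volume
        maps hold fractions in [0, 1]; diffusion maps hold physical units
        (MD in mm^2/s, MO unitless in [-1, 1]).
    voxel_size:
        Edge lengths of one voxel in mm, strictly positive.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"VolumeGrid data must be 3D, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("VolumeGrid data must be finite")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive numbers, got {self.voxel_size}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "voxel_size", vs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0.0, 1.0)).all())

    def is_fractional(self) -> bool:
        return bool((self.data >= 0.0).all() and (self.data <= 1.0).all())

    def compatible_with(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size, other.voxel_size
        )

    def require_compatible(self, other: "VolumeGrid", what: str = "grid") -> None:
        if not self.compatible_with(other):
            raise ValueError(
                f"incompatible {what}: shape/voxel_size "
                f"{other.shape}/{other.voxel_size} vs {self.shape}/{self.voxel_size}"
            )

    # --- NIfTI round trip -------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.voxel_size) + [1.0])
        return nib.Nifti1Image(self.data.astype(np.float32), affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "VolumeGrid":
        voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj, dtype=float), voxel_size)

    @classmethod
    def load(cls, path: str | Path) -> "VolumeGrid":
        return cls.from_nifti(nib.load(str(path)))


def _require_mask(grid: VolumeGrid, name: str) -> None:
    if not grid.is_binary():
        raise ValueError(f"{name} must be a binary mask")


def _require_fraction(grid: VolumeGrid, name: str) -> None:
    if not grid.is_fractional():
        raise ValueError(f"{name} values must lie in [0, 1]")


@dataclass
class SubjectImagery:
    """Per-subject preprocessed maps, all on one grid.

    ``structure_masks`` carries the subcortical segmentations (left/right
    hippocampus and amygdala); ``tract_density`` carries streamline-density
    maps normalised to [0, 1].  ``bold`` is an optional 4D resting-state
    series (x, y, z, t).
    """

    gm_pve: VolumeGrid
    wmh_mask: VolumeGrid
    csf_map: VolumeGrid
    structure_masks: dict[str, VolumeGrid]
    md_map: VolumeGrid
    mo_map: VolumeGrid
    skeleton_mask: VolumeGrid
    tract_density: dict[str, VolumeGrid]
    bold: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        ref = self.gm_pve
        _require_fraction(self.gm_pve, "gm_pve")
        _require_mask(self.wmh_mask, "wmh_mask")
        _require_fraction(self.csf_map, "csf_map")
        _require_mask(self.skeleton_mask, "skeleton_mask")
        if self.mo_map.data.min() < -1 or self.mo_map.data.max() > 1:
            raise ValueError("mo_map values must lie in [-1, 1]")
        for name, m in self.structure_masks.items():
            _require_mask(m, f"structure mask {name!r}")
            ref.require_compatible(m, f"structure mask {name!r}")
        for name, d in self.tract_density.items():
            _require_fraction(d, f"tract density {name!r}")
            ref.require_compatible(d, f"tract density {name!r}")
        for name, g in (
            ("wmh_mask", self.wmh_mask),
            ("csf_map", self.csf_map),
            ("md_map", self.md_map),
            ("mo_map", self.mo_map),
            ("skeleton_mask", self.skeleton_mask),
        ):
            ref.require_compatible(g, name)
        if self.bold is not None:
            bold = np.asarray(self.bold, dtype=float)
            if bold.ndim != 4 or bold.shape[:3] != ref.shape:
                raise ValueError("bold must be 4D on the shared grid")
            self.bold = bold

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.gm_pve.voxel_size


@dataclass
class AtlasBundle:
    """Named region masks defining which IDPs exist.

    ``lobar_masks``: 4 lobes (frontal, parietal, temporal, occipital);
    ``wm_tract_masks``: the 48-region white-matter tract atlas used for
    tract-wise lesion volumes; ``nbm_masks``: left/right nucleus basalis
    of Meynert; ``gm_roi_masks``: cortical grey-matter ROIs for regional
    diffusion metrics; ``tractography_tract_names`` lists the
    tractography-defined tracts whose volumes are measured from subject
    density maps.
    """

    lobar_masks: dict[str, VolumeGrid]
    wm_tract_masks: dict[str, VolumeGrid]
    nbm_masks: dict[str, VolumeGrid]
    gm_roi_masks: dict[str, VolumeGrid]
    tractography_tract_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        groups: Mapping[str, dict[str, VolumeGrid]] = {
            "lobar": self.lobar_masks,
            "wm_tract": self.wm_tract_masks,
            "nbm": self.nbm_masks,
            "gm_roi": self.gm_roi_masks,
        }
        seen: set[str] = set()
        ref: VolumeGrid | None = None
        for group, masks in groups.items():
            for name, m in masks.items():
                if name in seen:
                    raise ValueError(f"duplicate mask name {name!r}")
                seen.add(name)
                _require_mask(m, f"{group} mask {name!r}")
                if m.data.sum() == 0:
                    raise ValueError(f"{group} mask {name!r} is empty")
                if ref is None:
                    ref = m
                else:
                    ref.require_compatible(m, f"{group} mask {name!r}")
        if len(set(self.tractography_tract_names)) != len(self.tractography_tract_names):
            raise ValueError("tractography tract names must be unique")

    def require_compatible(self, subject: SubjectImagery) -> None:
        any_mask = next(iter(self.lobar_masks.values()))
        subject.gm_pve.require_compatible(any_mask, "atlas")
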