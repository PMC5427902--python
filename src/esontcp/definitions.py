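"""The four esophagus structure definitions on a 1-D axial voxel grid.

The definitions differ only longitudinally (cranio-caudal): the whole organ
from cricoid to gastroesophageal junction, the portion within the treatment
field, and each of those with the primary tumor excluded.  Structures are
therefore modelled as axial intervals crossed with a constant cross-section
(cc per mm of length), which captures every volume and dose quantity the
definition comparison needs without 3-D contouring.

Conventions: half-open intervals ``[start, end)`` in millimetres, origin at
the cricoid end of the esophagus.  A voxel belongs to an interval when its
centre does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dvh import VoxelDoseMap
from .errors import GridMismatchError

DEFINITION_NAMES = ("ESO_whole", "ESO_infield", "ESO_infield-tumor", "ESO_whole-tumor")


@dataclass(frozen=True)
class AxialInterval:
    """Half-open longitudinal interval [start_mm, end_mm)."""

    start_mm: float
    end_mm: float

    def __post_init__(self) -> None:
        if not self.end_mm > self.start_mm:
            raise ValueError("interval requires end > start")

    @property
    def length_mm(self) -> float:
        return self.end_mm - self.start_mm

    def contains(self, z_mm: np.ndarray) -> np.ndarray:
        z_mm = np.asarray(z_mm, dtype=float)
        return (z_mm >= self.start_mm) & (z_mm < self.end_mm)

    def expanded(self, margin_mm: float) -> "AxialInterval":
        return AxialInterval(self.start_mm - margin_mm, self.end_mm + margin_mm)

    def overlaps(self, other: "AxialInterval") -> bool:
        return self.start_mm < other.end_mm and other.start_mm < self.end_mm


@dataclass(frozen=True)
class EsophagusGeometry:
    """Axial intervals for esophagus, primary tumor and treatment field.

    ``tumor=None`` means no intratumoral esophagus (tumor absent); the
    tumor-excluded definitions then coincide with their parents.  The field is
    the largest-field longitudinal extent and may protrude beyond the organ.
    """

    esophagus: AxialInterval
    tumor: AxialInterval | None
    field: AxialInterval
    voxel_length_mm: float = 1.0
    cross_section_cc_per_mm: float = 0.15

    def __post_init__(self) -> None:
        if not (0 < self.voxel_length_mm <= 5.0):
            raise ValueError("voxel_length_mm must be in (0, 5] mm")
        if self.cross_section_cc_per_mm <= 0:
            raise ValueError("cross_section_cc_per_mm must be > 0")
        if self.tumor is not None and not (
            self.tumor.start_mm >= self.esophagus.start_mm
            and self.tumor.end_mm <= self.esophagus.end_mm
        ):
            raise ValueError("tumor interval must be contained in the esophagus")
        if not self.field.overlaps(self.esophagus):
            warnings.warn(
                "treatment field does not overlap the esophagus; "
                "in-field structures will be empty",
                stacklevel=2,
            )

    @property
    def n_voxels(self) -> int:
        return int(round(self.esophagus.length_mm / self.voxel_length_mm))

    @property
    def voxel_centers_mm(self) -> np.ndarray:
        return self.esophagus.start_mm + (np.arange(self.n_voxels) + 0.5) * self.voxel_length_mm

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_length_mm * self.cross_section_cc_per_mm


@dataclass(frozen=True)
class StructureMaskSet:
    """Boolean masks over the esophagus voxel grid for the four definitions."""

    whole: np.ndarray
    infield: np.ndarray
    infield_minus_tumor: np.ndarray
    whole_minus_tumor: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "ESO_whole": self.whole,
            "ESO_infield": self.infield,
            "ESO_infield-tumor": self.infield_minus_tumor,
            "ESO_whole-tumor": self.whole_minus_tumor,
        }


def build_definitions(geom: EsophagusGeometry) -> StructureMaskSet:
    """Construct the four definition masks from the geometry.

    The in-field extent is the treatment-field interval intersected with the
    esophagus; tumor-excluded variants remove voxels whose centre lies inside
    the tumor interval.
    """
    z = geom.voxel_centers_mm
    whole = np.ones_like(z, dtype=bool)
    infield = geom.field.contains(z)
    if not infield.any():
        warnings.warn("in-field structure is empty (field does not cover the organ)")
    tumor = geom.tumor.contains(z) if geom.tumor is not None else np.zeros_like(whole)
    return StructureMaskSet(
        whole=whole,
        infield=infield,
        infield_minus_tumor=infield & ~tumor,
        whole_minus_tumor=whole & ~tumor,
    )


def masked_dose_map(
    full_map: VoxelDoseMap, mask: np.ndarray, structure_id: str | None = None
) -> VoxelDoseMap:
    """Restrict a whole-organ dose map to the voxels selected by ``mask``.

    Masking changes membership only; per-voxel volumes and doses are
    untouched.  An all-false mask raises ``EmptyStructureError`` (via the
    VoxelDoseMap invariant).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != full_map.dose_gy.shape:
        raise GridMismatchError(
            f"mask has {mask.size} voxels but map has {full_map.n_voxels}"
        )
    return VoxelDoseMap(
        patient_id=full_map.patient_id,
        plan_id=full_map.plan_id,
        structure_id=structure_id if structure_id is not None else full_map.structure_id,
        voxel_volume_cc=full_map.voxel_volume_cc[mask],
        dose_gy=full_map.dose_gy[mask],
    )
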