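"""Dose-volume histograms: construction from voxel dose maps, metrics, text I/O.

The differential DVH bins structure volume by absorbed dose on a fixed grid of
half-open bins ``[edge, edge + width)`` starting at 0 Gy.  The cumulative view
gives the volume receiving at least a threshold dose and is the basis of the
``V_x`` metrics (volume receiving >= x Gy, in cc or percent of the structure).

Doses are physical Gy unless a DVH is tagged ``dose_kind="EQD2"`` after
fractionation correction; volumes are always cc.  There is no unit
autodetection.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DVHParseError, EmptyStructureError

DOSE_KIND_PHYSICAL = "physical"
DOSE_KIND_EQD2 = "EQD2"

DEFAULT_BIN_WIDTH_GY = 0.1


@dataclass
class VoxelDoseMap:
    """Per-voxel volume and absorbed dose for one structure under one plan.

    Parameters
    ----------
    patient_id, plan_id, structure_id
        Identifiers; ``plan_id`` is typically ``"SIB"`` or ``"SD"``.
    voxel_volume_cc
        Positive volume of each voxel, cc.
    dose_gy
        Non-negative finite absorbed dose of each voxel, Gy.
    """

    patient_id: str
    plan_id: str
    structure_id: str
    voxel_volume_cc: np.ndarray
    dose_gy: np.ndarray

    def __post_init__(self) -> None:
        self.voxel_volume_cc = np.asarray(self.voxel_volume_cc, dtype=float)
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        if self.voxel_volume_cc.size == 0:
            raise EmptyStructureError(
                f"empty structure: {self.structure_id!r} for patient "
                f"{self.patient_id!r} has no voxels"
            )
        if self.voxel_volume_cc.shape != self.dose_gy.shape:
            raise ValueError("voxel_volume_cc and dose_gy must have equal length")
        if not np.all(self.voxel_volume_cc > 0):
            raise ValueError("all voxel volumes must be > 0")
        if not (np.all(np.isfinite(self.dose_gy)) and np.all(self.dose_gy >= 0)):
            raise ValueError("all doses must be finite and >= 0")

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_volume_cc.size)

    @property
    def total_volume_cc(self) -> float:
        return float(self.voxel_volume_cc.sum())


@dataclass
class DVH:
    """Differential dose-volume histogram on a fixed half-open bin grid.

    ``diff_volume_cc[i]`` is the volume whose dose lies in
    ``[i * bin_width_gy, (i + 1) * bin_width_gy)``.
    """

    patient_id: str
    plan_id: str
    structure_id: str
    bin_width_gy: float
    diff_volume_cc: np.ndarray
    dose_kind: str = DOSE_KIND_PHYSICAL

    def __post_init__(self) -> None:
        self.diff_volume_cc = np.asarray(self.diff_volume_cc, dtype=float)
        if self.bin_width_gy <= 0:
            raise ValueError("bin_width_gy must be > 0")
        if self.diff_volume_cc.size == 0:
            raise EmptyStructureError("DVH has no bins")
        if np.any(self.diff_volume_cc < 0):
            raise ValueError("differential volumes must be >= 0")
        if self.dose_kind not in (DOSE_KIND_PHYSICAL, DOSE_KIND_EQD2):
            raise ValueError(f"unknown dose_kind {self.dose_kind!r}")

    @property
    def n_bins(self) -> int:
        return int(self.diff_volume_cc.size)

    @property
    def bin_lower_edges_gy(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width_gy

    @property
    def bin_midpoints_gy(self) -> np.ndarray:
        return self.bin_lower_edges_gy + 0.5 * self.bin_width_gy

    @property
    def total_volume_cc(self) -> float:
        return float(self.diff_volume_cc.sum())

    def key(self) -> tuple[str, str, str]:
        return (self.patient_id, self.plan_id, self.structure_id)


def dvh_from_voxels(
    dose_map: VoxelDoseMap,
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
    dose_kind: str = DOSE_KIND_PHYSICAL,
) -> DVH:
    """Bin a voxel dose map into a differential DVH, conserving total volume.

    Each voxel's volume is assigned to the half-open bin containing its dose.
    """
    if bin_width_gy <= 0:
        raise ValueError("bin_width_gy must be > 0")
    idx = np.floor(dose_map.dose_gy / bin_width_gy).astype(np.int64)
    diff = np.bincount(idx, weights=dose_map.voxel_volume_cc, minlength=int(idx.max()) + 1)
    return DVH(
        patient_id=dose_map.patient_id,
        plan_id=dose_map.plan_id,
        structure_id=dose_map.structure_id,
        bin_width_gy=float(bin_width_gy),
        diff_volume_cc=diff,
        dose_kind=dose_kind,
    )


def cumulative_view(dvh: DVH) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative DVH evaluated at every bin lower edge.

    Returns ``(dose_threshold_gy, volume_at_or_above_cc)``; the volume is the
    amount receiving a dose >= the threshold, non-increasing, equal to the
    total volume at 0 Gy.
    """
    suffix = np.cumsum(dvh.diff_volume_cc[::-1])[::-1]
    return dvh.bin_lower_edges_gy.copy(), suffix


def v_at_dose(dvh: DVH, x_gy: float, mode: str = "absolute_cc") -> float:
    """Volume receiving at least ``x_gy``, in cc or percent of the structure.

    Linear interpolation is used within the bin containing ``x_gy`` (the
    bin's volume is assumed uniformly spread over the bin).
    """
    if x_gy < 0:
        raise ValueError("dose threshold must be >= 0")
    if mode not in ("absolute_cc", "percent"):
        raise ValueError(f"unknown mode {mode!r}")
    i = int(np.floor(x_gy / dvh.bin_width_gy))
    if i >= dvh.n_bins:
        vol = 0.0
    else:
        suffix = float(dvh.diff_volume_cc[i:].sum())
        frac = (x_gy - i * dvh.bin_width_gy) / dvh.bin_width_gy
        vol = suffix - frac * float(dvh.diff_volume_cc[i])
    if mode == "percent":
        return 100.0 * vol / dvh.total_volume_cc
    return vol


def dose_stats(dvh: DVH) -> tuple[float, float]:
    """Return ``(d_mean_gy, d_max_gy)``.

    ``d_mean`` is the volume-weighted mean of bin midpoints.  ``d_max`` is the
    upper edge of the highest occupied bin — the DVH-level convention; the
    exact maximum is available only from the voxel map.
    """
    total = dvh.total_volume_cc
    if total <= 0:
        return 0.0, 0.0
    d_mean = float(np.dot(dvh.diff_volume_cc, dvh.bin_midpoints_gy) / total)
    occupied = np.nonzero(dvh.diff_volume_cc > 0)[0]
    d_max = float((occupied[-1] + 1) * dvh.bin_width_gy)
    return d_mean, d_max


# --------------------------------------------------------------------------
# Text format: CSV with header
#   patient_id,plan_id,structure_id,dose_kind,bin_lower_gy,bin_width_gy,diff_volume_cc
# one row per occupied bin; rows for one (patient, plan, structure) contiguous
# and dose-sorted.  This is the only persisted DVH format.
# --------------------------------------------------------------------------

_COLUMNS = [
    "patient_id",
    "plan_id",
    "structure_id",
    "dose_kind",
    "bin_lower_gy",
    "bin_width_gy",
    "diff_volume_cc",
]


def write_dvh_file(dvhs: list[DVH], path) -> None:
    """Write a collection of DVHs to the CSV dialect (6-decimal fixed point)."""
    buf = io.StringIO()
    buf.write(",".join(_COLUMNS) + "\n")
    for dvh in dvhs:
        edges = dvh.bin_lower_edges_gy
        for i in np.nonzero(dvh.diff_volume_cc > 0)[0]:
            buf.write(
                f"{dvh.patient_id},{dvh.plan_id},{dvh.structure_id},{dvh.dose_kind},"
                f"{edges[i]:.6f},{dvh.bin_width_gy:.6f},{dvh.diff_volume_cc[i]:.6f}\n"
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_dvh_file(path) -> list[DVH]:
    """Read a DVH CSV file, validating the dialect row by row.

    Raises
    ------
    DVHParseError
        Naming the first offending line for a bad header, negative volume,
        unsorted/duplicated bin edges, inconsistent bin width within a block,
        or an off-grid edge.
    """
    try:
        table = pd.read_csv(path, dtype={c: str for c in _COLUMNS[:4]})
    except Exception as exc:  # malformed CSV structure
        raise DVHParseError(f"cannot parse {path}: {exc}") from exc
    if list(table.columns) != _COLUMNS:
        raise DVHParseError(
            f"bad header {list(table.columns)}; expected {_COLUMNS}", line=1
        )
    dvhs: list[DVH] = []
    seen: set[tuple[str, str, str]] = set()
    for key, group in table.groupby(
        ["patient_id", "plan_id", "structure_id"], sort=False
    ):
        rows = group.index.to_numpy()
        if np.any(np.diff(rows) != 1):
            raise DVHParseError(
                f"rows for {key} are not contiguous", line=int(rows[0]) + 2
            )
        if key in seen:
            raise DVHParseError(f"duplicate block {key}", line=int(rows[0]) + 2)
        seen.add(key)
        width = float(group["bin_width_gy"].iloc[0])
        if width <= 0:
            raise DVHParseError("bin width must be > 0", line=int(rows[0]) + 2)
        if not np.allclose(group["bin_width_gy"].to_numpy(dtype=float), width):
            raise DVHParseError(
                f"inconsistent bin width within block {key}", line=int(rows[0]) + 2
            )
        edges = group["bin_lower_gy"].to_numpy(dtype=float)
        if np.any(np.diff(edges) <= 0):
            bad = int(rows[int(np.argmax(np.diff(edges) <= 0)) + 1]) + 2
            raise DVHParseError("bin edges not strictly ascending", line=bad)
        vols = group["diff_volume_cc"].to_numpy(dtype=float)
        if np.any(vols < 0):
            bad = int(rows[int(np.argmax(vols < 0))]) + 2
            raise DVHParseError("negative differential volume", line=bad)
        idx = np.rint(edges / width).astype(np.int64)
        if not np.allclose(idx * width, edges, atol=1e-6):
            bad = int(rows[int(np.argmax(~np.isclose(idx * width, edges, atol=1e-6)))]) + 2
            raise DVHParseError("bin edge not a multiple of bin width", line=bad)
        diff = np.zeros(int(idx[-1]) + 1)
        diff[idx] = vols
        kinds = group["dose_kind"].unique()
        if len(kinds) != 1:
            raise DVHParseError(
                f"inconsistent dose_kind within block {key}", line=int(rows[0]) + 2
            )
        dvhs.append(
            DVH(
                patient_id=key[0],
                plan_id=key[1],
                structure_id=key[2],
                bin_width_gy=width,
                diff_volume_cc=diff,
                dose_kind=str(kinds[0]),
            )
        )
    return dvhs
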