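"""Seeded synthetic cohort: paired SIB/SD dose distributions over the esophagus.

Emulates the planning study's conditions: 21 patients, a standard-dose (SD)
plan prescribing 50.4 Gy in 28 fractions to the elective field and a
simultaneous-integrated-boost (SIB) plan additionally raising the dose over
the tumor plus a boost margin to 64.8 Gy in the same 28 fractions.  The axial
dose profile is a flat plateau inside each interval with a half-Gaussian
penumbra of scale ``penumbra_sigma_mm`` outside, decaying to a small
out-of-field floor.  A hotspot factor (default 1.03) lifts the plateaus to
the clinically typical maxima (~52.5 Gy SD, ~66.7 Gy SIB).

Multiplicative voxel noise is shared between the two plans of a patient, so
the defining structural property SIB(z) >= SD(z) holds at every voxel by
construction.  The whole cohort is a pure function of (config, seed): patient
``i`` draws from an RNG stream spawned from ``SeedSequence(seed, spawn_key=(i,))``,
so extending the cohort never reshuffles existing patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .definitions import AxialInterval, EsophagusGeometry, build_definitions, masked_dose_map
from .dvh import DVH, VoxelDoseMap, dvh_from_voxels, write_dvh_file

PLAN_SIB = "SIB"
PLAN_SD = "SD"


@dataclass(frozen=True)
class GeometryPriors:
    """Sampling ranges for per-patient geometry, millimetres.

    The tumor centre is placed at a uniform fraction of the organ length in
    ``tumor_center_frac`` so that the treatment field (tumor + boost margin +
    field margin on each side) stays within the organ, as for mid/upper
    thoracic primaries.  ``field_margin_mm`` is calibrated so the in-field
    portion is roughly two thirds of the whole organ, the ratio implied by
    typical whole vs in-field mean doses in this setting.
    """

    esophagus_length_mm: tuple[float, float] = (220.0, 260.0)
    tumor_length_mm: tuple[float, float] = (40.0, 80.0)
    tumor_center_frac: tuple[float, float] = (0.40, 0.60)
    boost_margin_mm: float = 5.0
    field_margin_mm: float = 45.0
    voxel_length_mm: float = 1.0
    cross_section_cc_per_mm: float = 0.15


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort."""

    n_patients: int = 21
    seed: int = 0
    n_fractions: int = 28
    dose_sd_gy: float = 50.4
    dose_sib_gy: float = 64.8
    hotspot_factor: float = 1.03
    penumbra_sigma_mm: float = 6.0
    out_of_field_floor_gy: float = 1.5
    noise_rel_sd: float = 0.01
    bin_width_gy: float = 0.1
    priors: GeometryPriors = field(default_factory=GeometryPriors)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.dose_sib_gy > self.dose_sd_gy:
            raise ValueError("boost prescription must exceed the standard dose")
        if self.hotspot_factor < 1:
            raise ValueError("hotspot_factor must be >= 1")
        if self.penumbra_sigma_mm <= 0 or self.noise_rel_sd < 0:
            raise ValueError("penumbra_sigma_mm > 0 and noise_rel_sd >= 0 required")

    @staticmethod
    def from_dict(d: dict) -> "CohortConfig":
        d = dict(d)
        priors = d.pop("priors", None)
        if priors is not None:
            priors = GeometryPriors(
                **{
                    k: tuple(v) if isinstance(v, (list, tuple)) else v
                    for k, v in priors.items()
                }
            )
            d["priors"] = priors
        return CohortConfig(**d)

    @staticmethod
    def from_yaml(path) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            return CohortConfig.from_dict(yaml.safe_load(fh)["cohort"])


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient: geometry plus whole-organ SIB and SD dose maps."""

    patient_id: str
    geometry: EsophagusGeometry
    dose_sib: VoxelDoseMap
    dose_sd: VoxelDoseMap

    def dose_map(self, plan: str) -> VoxelDoseMap:
        if plan == PLAN_SIB:
            return self.dose_sib
        if plan == PLAN_SD:
            return self.dose_sd
        raise KeyError(f"unknown plan {plan!r}")


def _plateau_shape(z_mm: np.ndarray, interval: AxialInterval, sigma_mm: float) -> np.ndarray:
    """1 inside the interval, half-Gaussian falloff of scale sigma outside."""
    z_mm = np.asarray(z_mm, dtype=float)
    dist = np.maximum.reduce(
        [interval.start_mm - z_mm, z_mm - interval.end_mm, np.zeros_like(z_mm)]
    )
    return np.exp(-0.5 * (dist / sigma_mm) ** 2)


def boost_interval(geom: EsophagusGeometry, config: CohortConfig) -> AxialInterval:
    if geom.tumor is None:
        raise ValueError("boost requires a tumor interval")
    return geom.tumor.expanded(config.priors.boost_margin_mm)


def dose_profile(
    z_mm: np.ndarray, plan: str, geom: EsophagusGeometry, config: CohortConfig
) -> np.ndarray:
    """Noise-free axial dose, Gy, for one plan at positions ``z_mm``.

    SD: ``floor + (hotspot * 50.4 - floor) * S_field``; SIB adds
    ``hotspot * (64.8 - 50.4) * S_boost`` where each ``S`` is a flat plateau
    with half-Gaussian penumbrae.  Since the field contains the boost region,
    the SIB plateau tops out at exactly ``hotspot * 64.8`` and
    SIB(z) >= SD(z) everywhere.
    """
    z_mm = np.asarray(z_mm, dtype=float)
    floor = config.out_of_field_floor_gy
    sd_plateau = config.hotspot_factor * config.dose_sd_gy
    sd = floor + (sd_plateau - floor) * _plateau_shape(z_mm, geom.field, config.penumbra_sigma_mm)
    if plan == PLAN_SD:
        return sd
    if plan != PLAN_SIB:
        raise KeyError(f"unknown plan {plan!r}")
    boost = config.hotspot_factor * (config.dose_sib_gy - config.dose_sd_gy)
    return sd + boost * _plateau_shape(
        z_mm, boost_interval(geom, config), config.penumbra_sigma_mm
    )


def _patient_rng(config: CohortConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(index,)))


# Split of the relative noise amplitude between a patient-level calibration
# scalar and voxelwise jitter.  Plan-dose uncertainty is dominated by a
# whole-plan output factor (so the hottest spot is nearly the same whichever
# sub-structure contains it — Dmax is near-identical across definitions),
# with only a small spatially local component.
_NOISE_SCALAR_FRAC = 0.8
_NOISE_JITTER_FRAC = 0.2


def _noise_factor(
    rng: np.random.Generator, n_voxels: int, config: CohortConfig
) -> np.ndarray:
    """Multiplicative dose-error field, shared between a patient's two plans.

    ``(1 + g) * (1 + j_z)`` with g ~ N(0, 0.8 * noise_rel_sd) per patient and
    j_z ~ N(0, 0.2 * noise_rel_sd) per voxel, each truncated at 3 sigma, so
    the overall factor never exceeds ~``1 + 3 * noise_rel_sd`` and the jitter
    spread across sub-structures stays well under 1 Gy at plateau doses.
    """
    if config.noise_rel_sd == 0:
        return np.ones(n_voxels)
    s_scalar = _NOISE_SCALAR_FRAC * config.noise_rel_sd
    s_jitter = _NOISE_JITTER_FRAC * config.noise_rel_sd
    g = np.clip(rng.normal(0.0, s_scalar), -3 * s_scalar, 3 * s_scalar)
    j = np.clip(
        rng.normal(0.0, s_jitter, n_voxels), -3 * s_jitter, 3 * s_jitter
    )
    return (1.0 + g) * (1.0 + j)


def simulate_patient(config: CohortConfig, index: int) -> PatientRecord:
    """Draw one patient's geometry and paired dose maps, deterministically.

    The same multiplicative noise field multiplies both plans, preserving
    voxelwise SIB >= SD.
    """
    rng = _patient_rng(config, index)
    p = config.priors
    length = rng.uniform(*p.esophagus_length_mm)
    tumor_len = rng.uniform(*p.tumor_length_mm)
    center = rng.uniform(*p.tumor_center_frac) * length
    tumor = AxialInterval(center - tumor_len / 2, center + tumor_len / 2)
    field_iv = tumor.expanded(p.boost_margin_mm + p.field_margin_mm)
    geom = EsophagusGeometry(
        esophagus=AxialInterval(0.0, length),
        tumor=tumor,
        field=field_iv,
        voxel_length_mm=p.voxel_length_mm,
        cross_section_cc_per_mm=p.cross_section_cc_per_mm,
    )
    z = geom.voxel_centers_mm
    factor = _noise_factor(rng, z.size, config)
    volumes = np.full(z.size, geom.voxel_volume_cc)
    pid = f"P{index + 1:02d}"
    maps = {}
    for plan in (PLAN_SIB, PLAN_SD):
        maps[plan] = VoxelDoseMap(
            patient_id=pid,
            plan_id=plan,
            structure_id="ESO_whole",
            voxel_volume_cc=volumes.copy(),
            dose_gy=dose_profile(z, plan, geom, config) * factor,
        )
    return PatientRecord(
        patient_id=pid, geometry=geom, dose_sib=maps[PLAN_SIB], dose_sd=maps[PLAN_SD]
    )


def patient_dvhs(record: PatientRecord, bin_width_gy: float) -> list[DVH]:
    """Differential DVHs for all four definitions x both plans of one patient."""
    masks = build_definitions(record.geometry)
    out = []
    for plan in (PLAN_SIB, PLAN_SD):
        full = record.dose_map(plan)
        for name, mask in masks.as_dict().items():
            out.append(dvh_from_voxels(masked_dose_map(full, mask, name), bin_width_gy))
    return out


def simulate_cohort(
    config: CohortConfig, out_dir: str | Path | None = None
) -> list[PatientRecord]:
    """Simulate the cohort; optionally persist DVH files and a manifest.

    When ``out_dir`` is given, writes ``dvh.csv`` (the 4 definitions x 2 plans
    per patient in the DVH CSV dialect) and ``manifest.yaml`` echoing the
    config and per-patient geometry.
    """
    records = [simulate_patient(config, i) for i in range(config.n_patients)]
    if out_dir is not None:
        out_dir = Path(out_dir)
        try:
            out_dir.mkdir(parents=True, exist_ok=True)
            all_dvhs: list[DVH] = []
            for rec in records:
                all_dvhs.extend(patient_dvhs(rec, config.bin_width_gy))
            write_dvh_file(all_dvhs, out_dir / "dvh.csv")
            manifest = {
                "config": _config_to_dict(config),
                "patients": [
                    {
                        "patient_id": r.patient_id,
                        "esophagus_mm": [r.geometry.esophagus.start_mm, r.geometry.esophagus.end_mm],
                        "tumor_mm": [r.geometry.tumor.start_mm, r.geometry.tumor.end_mm],
                        "field_mm": [r.geometry.field.start_mm, r.geometry.field.end_mm],
                    }
                    for r in records
                ],
            }
            with open(out_dir / "manifest.yaml", "w", encoding="utf-8") as fh:
                yaml.safe_dump(manifest, fh, sort_keys=False)
        except OSError as exc:
            raise OSError(f"failed writing cohort outputs under {out_dir}: {exc}") from exc
    return records


def _config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["priors"] = {
        k: list(v) if isinstance(v, tuple) else v for k, v in d["priors"].items()
    }
    return d
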