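"""Radiobiological models: EQD2 conversion, gEUD, LKB and logistic-V50 NTCP.

EQD2 (equieffective dose in 2-Gy fractions) under the linear-quadratic model:

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta),   d = D / n_fractions,

applied element-wise with each voxel's (or DVH bin midpoint's) own total dose
D, holding the plan's nominal fraction count fixed — the standard DVH-wise
conversion.  alpha/beta is ~10 Gy for acute endpoints, ~3 Gy for late.

gEUD (generalized equivalent uniform dose):

    gEUD = ( sum_i (v_i / V) * D_i^(1/n) )^n,

with n ~ 1 giving mean-dose (parallel organ) and n -> 0 giving max-dose
(serial organ) behaviour.  LKB NTCP = Phi((gEUD - TD50) / (m * TD50)), with
Phi the standard normal CDF evaluated via erfc for far-tail accuracy.  The
logistic V50 model maps the volume receiving >= 50 Gy through a logistic
curve; its coefficients must be supplied explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml
from scipy.special import erfc, expit, logsumexp

from .dvh import DOSE_KIND_EQD2, DOSE_KIND_PHYSICAL, DVH, VoxelDoseMap, dvh_from_voxels, v_at_dose
from .errors import ModelConfigError


@dataclass(frozen=True)
class FractionationScheme:
    """Prescription total dose and fraction count for one plan."""

    total_prescription_gy: float
    n_fractions: int

    def __post_init__(self) -> None:
        if self.total_prescription_gy <= 0 or self.n_fractions < 1:
            raise ValueError("prescription and fraction count must be positive")

    @property
    def dose_per_fraction_gy(self) -> float:
        return self.total_prescription_gy / self.n_fractions


@dataclass(frozen=True)
class EQD2Params:
    alpha_beta_gy: float

    def __post_init__(self) -> None:
        if self.alpha_beta_gy <= 0:
            raise ValueError("alpha/beta must be > 0")


@dataclass(frozen=True)
class LKBParams:
    """Volume-effect exponent n, slope m, and 50%-complication dose TD50 (Gy)."""

    n: float
    m: float
    td50_gy: float

    def __post_init__(self) -> None:
        if min(self.n, self.m, self.td50_gy) <= 0:
            raise ValueError("LKB parameters must all be > 0")


@dataclass(frozen=True)
class LogisticV50Params:
    intercept: float
    slope: float
    v50_mode: str = "percent"  # percent | cc

    def __post_init__(self) -> None:
        if not (math.isfinite(self.intercept) and math.isfinite(self.slope)):
            raise ValueError("logistic coefficients must be finite")
        if self.v50_mode not in ("percent", "cc"):
            raise ValueError("v50_mode must be 'percent' or 'cc'")


@dataclass(frozen=True)
class NTCPModelSpec:
    """A named complication model: family, endpoint, alpha/beta and parameters."""

    name: str
    family: str  # "lkb" | "logistic_v50"
    endpoint: str
    eqd2: EQD2Params
    lkb: LKBParams | None = None
    logistic: LogisticV50Params | None = None

    def __post_init__(self) -> None:
        if self.family == "lkb":
            if self.lkb is None or self.logistic is not None:
                raise ModelConfigError(f"model {self.name!r}: lkb family needs LKBParams only")
        elif self.family == "logistic_v50":
            if self.lkb is not None:
                raise ModelConfigError(
                    f"model {self.name!r}: logistic_v50 family must not carry LKBParams"
                )
        else:
            raise ModelConfigError(f"model {self.name!r}: unknown family {self.family!r}")


def eqd2_per_voxel(dose_gy, n_fractions: int, alpha_beta_gy: float):
    """Element-wise EQD2 of a total dose delivered in ``n_fractions``."""
    dose_gy = np.asarray(dose_gy, dtype=float)
    out = dose_gy * (dose_gy / n_fractions + alpha_beta_gy) / (2.0 + alpha_beta_gy)
    return float(out) if out.ndim == 0 else out


def eqd2_transform(container, scheme: FractionationScheme, params: EQD2Params):
    """Convert a physical-dose DVH or voxel map to EQD2.

    Volumes are untouched; the result is tagged EQD2.  A DVH is converted by
    treating each bin as a pseudo-voxel at its midpoint dose and re-binning at
    the original bin width.  Converting an already-EQD2 container is an error.
    """
    if isinstance(container, DVH):
        if container.dose_kind == DOSE_KIND_EQD2:
            raise ValueError("DVH is already in EQD2; double conversion refused")
        occupied = container.diff_volume_cc > 0
        pseudo = VoxelDoseMap(
            patient_id=container.patient_id,
            plan_id=container.plan_id,
            structure_id=container.structure_id,
            voxel_volume_cc=container.diff_volume_cc[occupied],
            dose_gy=eqd2_per_voxel(
                container.bin_midpoints_gy[occupied],
                scheme.n_fractions,
                params.alpha_beta_gy,
            ),
        )
        return dvh_from_voxels(pseudo, container.bin_width_gy, dose_kind=DOSE_KIND_EQD2)
    if isinstance(container, VoxelDoseMap):
        return VoxelDoseMap(
            patient_id=container.patient_id,
            plan_id=container.plan_id,
            structure_id=container.structure_id,
            voxel_volume_cc=container.voxel_volume_cc.copy(),
            dose_gy=eqd2_per_voxel(
                container.dose_gy, scheme.n_fractions, params.alpha_beta_gy
            ),
        )
    raise TypeError(f"cannot EQD2-transform {type(container).__name__}")


def geud(dvh: DVH, n: float) -> float:
    """Generalized equivalent uniform dose of a DVH at volume exponent ``n``.

    Evaluated in the log domain (``logsumexp``) so serial-organ exponents
    (1/n ~ 30) do not overflow.  Zero-dose bins contribute nothing to the
    power sum; an all-zero-dose DVH returns 0.
    """
    if n <= 0:
        raise ValueError("volume exponent n must be > 0")
    mid = dvh.bin_midpoints_gy
    w = dvh.diff_volume_cc / dvh.total_volume_cc
    pos = (w > 0) & (mid > 0)
    if not pos.any():
        return 0.0
    log_sum = logsumexp(np.log(mid[pos]) / n, b=w[pos])
    return float(np.exp(n * log_sum))


def lkb_ntcp(eud_gy: float, params: LKBParams) -> float:
    """LKB complication probability Phi((EUD - TD50) / (m * TD50))."""
    if eud_gy < 0:
        raise ValueError("EUD must be >= 0")
    t = (eud_gy - params.td50_gy) / (params.m * params.td50_gy)
    return float(0.5 * erfc(-t / math.sqrt(2.0)))


def lkb_d50_from_curve(
    params: LKBParams,
    lo: float = 0.0,
    hi: float = 150.0,
    target: float = 0.5,
    tol: float = 1e-10,
) -> float:
    """Uniform whole-organ EQD2 dose at which the LKB model hits ``target``.

    For a uniform dose the gEUD equals the dose at any volume exponent
    (homogeneity identity), so the dose-response curve is inverted by
    bisecting ``lkb_ntcp`` until the probability is within ``tol`` of the
    target.  With ``target=0.5`` this recovers TD50 from the curve.
    """
    f_lo = lkb_ntcp(lo, params) - target
    f_hi = lkb_ntcp(hi, params) - target
    if f_lo > 0 or f_hi < 0:
        raise ValueError("target probability not bracketed by [lo, hi]")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = lkb_ntcp(mid, params) - target
        if abs(f_mid) <= tol:
            return mid
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def kwint_ntcp(v50_value: float, params: LogisticV50Params | None) -> float:
    """Logistic complication probability 1 / (1 + exp(-(a + b * V50)))."""
    if params is None:
        raise ModelConfigError(
            "logistic V50 coefficients required: this model ships without "
            "defaults; supply intercept and slope in the model registry"
        )
    if v50_value < 0:
        raise ValueError("V50 must be >= 0")
    return float(expit(params.intercept + params.slope * v50_value))


def predict_toxicity(
    dvh_physical: DVH, scheme: FractionationScheme, spec: NTCPModelSpec
) -> float:
    """Complication probability (fraction) for a physical-dose DVH.

    Pipeline: EQD2-convert at the model's alpha/beta; then gEUD -> probit for
    LKB models, or V50 (in the declared mode) -> logistic for V50 models.
    """
    if dvh_physical.dose_kind != DOSE_KIND_PHYSICAL:
        raise ValueError("predict_toxicity expects a physical-dose DVH")
    dvh_eqd2 = eqd2_transform(dvh_physical, scheme, spec.eqd2)
    if spec.family == "lkb":
        return lkb_ntcp(geud(dvh_eqd2, spec.lkb.n), spec.lkb)
    mode = "percent" if spec.logistic is None else (
        "percent" if spec.logistic.v50_mode == "percent" else "absolute_cc"
    )
    v50 = v_at_dose(dvh_eqd2, 50.0, mode=mode)
    return kwint_ntcp(v50, spec.logistic)


# --------------------------------------------------------------------------
# Model registry
# --------------------------------------------------------------------------

def published_registry(
    kwint_g2: LogisticV50Params | None = None,
    kwint_g3: LogisticV50Params | None = None,
) -> dict[str, NTCPModelSpec]:
    """The four esophageal-toxicity models with their published parameters.

    LKB parameter sets: Wijsman grade>=2 acute (n=1.04, m=0.65, D50=32.84 Gy,
    alpha/beta=10) and Chen late toxicity (n=0.03, m=0.03, TD50=76.1 Gy,
    alpha/beta=3).  The two logistic V50 models (grade>=2 and grade>=3 acute)
    are registered without coefficients — the source publication for this
    comparison does not print them — and raise until parameterized.
    """
    return {
        "kwint_g2": NTCPModelSpec(
            name="kwint_g2",
            family="logistic_v50",
            endpoint="grade>=2 acute esophageal toxicity",
            eqd2=EQD2Params(10.0),
            logistic=kwint_g2,
        ),
        "kwint_g3": NTCPModelSpec(
            name="kwint_g3",
            family="logistic_v50",
            endpoint="grade>=3 acute esophageal toxicity",
            eqd2=EQD2Params(10.0),
            logistic=kwint_g3,
        ),
        "wijsman_g2": NTCPModelSpec(
            name="wijsman_g2",
            family="lkb",
            endpoint="grade>=2 acute esophageal toxicity",
            eqd2=EQD2Params(10.0),
            lkb=LKBParams(n=1.04, m=0.65, td50_gy=32.84),
        ),
        "chen_let": NTCPModelSpec(
            name="chen_let",
            family="lkb",
            endpoint="late esophageal toxicity",
            eqd2=EQD2Params(3.0),
            lkb=LKBParams(n=0.03, m=0.03, td50_gy=76.1),
        ),
    }


def registry_from_yaml(path) -> dict[str, NTCPModelSpec]:
    """Load a model registry from YAML (see analysis/config/models.yaml)."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    registry: dict[str, NTCPModelSpec] = {}
    for name, m in doc["models"].items():
        family = m["family"]
        lkb = logistic = None
        if family == "lkb":
            p = m["lkb"]
            lkb = LKBParams(n=p["n"], m=p["m"], td50_gy=p["td50_gy"])
        elif family == "logistic_v50":
            p = m.get("logistic")
            if p is not None and p.get("intercept") is not None:
                logistic = LogisticV50Params(
                    intercept=p["intercept"],
                    slope=p["slope"],
                    v50_mode=p.get("v50_mode", "percent"),
                )
        registry[name] = NTCPModelSpec(
            name=name,
            family=family,
            endpoint=m.get("endpoint", name),
            eqd2=EQD2Params(m["alpha_beta_gy"]),
            lkb=lkb,
            logistic=logistic,
        )
    return registry


def registry_to_yaml(registry: dict[str, NTCPModelSpec], path) -> None:
    doc = {"models": {}}
    for name, spec in registry.items():
        entry: dict = {"family": spec.family, "endpoint": spec.endpoint,
                       "alpha_beta_gy": spec.eqd2.alpha_beta_gy}
        if spec.lkb is not None:
            entry["lkb"] = {"n": spec.lkb.n, "m": spec.lkb.m, "td50_gy": spec.lkb.td50_gy}
        if spec.family == "logistic_v50":
            if spec.logistic is None:
                entry["logistic"] = {"intercept": None, "slope": None, "v50_mode": "percent"}
            else:
                entry["logistic"] = {
                    "intercept": spec.logistic.intercept,
                    "slope": spec.logistic.slope,
                    "v50_mode": spec.logistic.v50_mode,
                }
        doc["models"][name] = entry
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
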