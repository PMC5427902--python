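# Methods

## Problem

When a simultaneous-integrated-boost (SIB) plan escalates the dose inside an
esophageal tumor, how much the *esophagus itself* appears to suffer depends on
which portion of the organ is scored as the organ at risk. Four definitions
are compared: the whole organ (`ESO_whole`), the portion inside the treatment
field (`ESO_infield`), and each of those with the primary tumor excluded
(`ESO_infield-tumor`, `ESO_whole-tumor`). The pipeline quantifies, per
definition, how dose metrics and model-predicted toxicity change when moving
from a standard-dose (SD) plan (50.4 Gy / 28 fx) to an SIB plan (64.8 Gy
boost / 28 fx), and whether those changes differ between definitions.

## Geometry model

The four definitions differ only along the organ's long axis, so structures
are modelled in 1-D: half-open axial intervals (mm, origin at the cricoid
end) crossed with a constant cross-section (default 0.15 cc/mm). A voxel
(default 1 mm) belongs to a structure when its centre lies in the interval.
This reproduces every volume and dose quantity the comparison uses; radial
margin growth, contour import and multifocal tumors are out of scope. The
excluded "tumor" is the primary tumor interval only (nodal disease lies
outside the esophageal wall); the exclusion interval is configurable.

## Synthetic cohort

No planning data are distributed with this package; the cohort generator
produces dose distributions with the *structural* properties of paired
SIB/SD planning studies, not any particular patient set. Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 21 | cohort size |
| `n_fractions` | 28 | both plans |
| `dose_sd_gy` / `dose_sib_gy` | 50.4 / 64.8 | prescriptions, Gy |
| `hotspot_factor` | 1.03 | plateau lift giving Dmax ≈ 52.5 / 66.7 Gy |
| `penumbra_sigma_mm` | 6 | field-edge falloff scale |
| `out_of_field_floor_gy` | 1.5 | scatter dose far outside the field |
| `noise_rel_sd` | 0.01 | relative dose-error amplitude |
| esophagus length | U(220, 260) mm | prior |
| tumor length | U(40, 80) mm | prior |
| tumor centre | U(0.40, 0.60) × length | prior |
| `boost_margin_mm` | 5 | boost = tumor + margin (PTV-style) |
| `field_margin_mm` | 45 | field = boost + margin per side |

The axial dose profile is a flat plateau inside an interval with a
half-Gaussian falloff of scale `penumbra_sigma_mm` outside, decaying to the
floor: SD = floor + (1.03·50.4 − floor)·S_field; SIB adds 1.03·(64.8 −
50.4)·S_boost over the tumor + boost margin. Because the field contains the
boost region, the SIB plateau tops out at exactly 1.03 × 64.8 = 66.744 Gy and
SIB(z) ≥ SD(z) everywhere by construction.

`field_margin_mm = 45` makes the in-field portion roughly two thirds of the
organ, the ratio implied by typical whole-organ vs in-field mean doses in
this setting; it also makes the per-patient ordering of the SIB−SD mean-dose
increase (infield > whole > infield−tumor > whole−tumor) hold for essentially
all draws, which is the qualitative pattern such comparisons report. The
tumor-centre prior keeps the treatment field longitudinally inside the organ,
as for mid/upper-thoracic primaries; placing tumors at the organ ends would
clip the field and distort the in-field definitions.

Dose noise is multiplicative and *shared between a patient's two plans* (so
plan dominance survives noise) and is split into a patient-level calibration
scalar (0.8 of the amplitude) times small voxelwise jitter (0.2), each
truncated at ±3σ. The scalar dominates because plan-dose uncertainty is
mostly a whole-plan output factor; consequently the hottest-spot dose is
nearly the same whichever sub-structure contains it (Dmax agrees across
definitions to well under 1 Gy), while the truncation bounds every plan's
maximum at plateau × (1 + 3·noise_rel_sd). Patient *i* draws from
`SeedSequence(seed, spawn_key=(i,))`, so the cohort is a pure function of
(config, seed) and extending it never reshuffles existing patients.

What the generator does **not** emulate: optimizer behaviour and
plan-to-plan heterogeneity of real IMRT, 3-D dose shapes, setup/breathing
uncertainty, inter-metric correlations beyond those induced by geometry.
Passing tests therefore validate the pipeline's arithmetic and the
comparison's structural logic, not clinical dose distributions.

## DVH conventions

Differential DVHs use half-open bins `[edge, edge + width)` from 0 Gy,
default width 0.1 Gy (configurable; typical export resolution). `V_x` is
reported in cc by default (percent is first-class too) with linear
interpolation inside the bin containing `x`. `Dmean` is the volume-weighted
mean of bin midpoints; `Dmax` from a DVH is the upper edge of the highest
occupied bin (the exact maximum is only available voxel-side) — so
DVH-derived `Dmax` overestimates the voxel maximum by at most one bin width.
The only persisted format is the documented CSV dialect; DICOM-RT is not
parsed.

## Radiobiology

Physical doses are converted per element (voxel or bin midpoint) to EQD2
with that element's own total dose and the plan's nominal 28 fractions:
`EQD2 = D (D/n + α/β) / (2 + α/β)`; α/β = 10 Gy for acute endpoints, 3 Gy
for late. gEUD is computed in the log domain (`logsumexp`) so serial-organ
exponents (1/n ≈ 33 for n = 0.03) cannot overflow. LKB NTCP uses
Φ(t) = erfc(−t/√2)/2, accurate in the far tail where late-toxicity
predictions for ~50 Gy EQD2 plateaus land (~10⁻²⁷).

Registered models: Wijsman LKB (n = 1.04, m = 0.65, D50 = 32.84 Gy, acute
grade ≥ 2), Chen LKB (n = 0.03, m = 0.03, TD50 = 76.1 Gy, late), and two
logistic V50 models (grade ≥ 2 / ≥ 3 acute). The logistic V50 is evaluated
on the EQD2 (α/β = 10) DVH in percent of the structure volume by default
(configurable to cc) — an assumption, since the convention is not fixed by
the parameter source. Its coefficients are mandatory configuration: the
registry ships them empty and raises rather than inventing values;
`analysis/config/models.yaml` carries clearly-labelled synthetic placeholders
(intercept −2 / −3.5, slope 0.05) for demonstration and testing only.

## Statistics

Paired SIB−SD differences per patient are summarized as mean ± sample SD
(n−1). Definition dependence is tested with the Friedman test (tie-corrected
chi-square statistic; exact within-row permutation p by dynamic programming
for n ≤ 6 blocks, chi-square tail above), and the two pre-specified contrasts
(whole vs whole−tumor, infield vs infield−tumor) with the two-sided Wilcoxon
signed-rank test (zeros dropped with a warning, midranks on |d|, exact
enumeration of the 2ⁿ sign assignments for effective n ≤ 12, tie-corrected
normal approximation above; all-zero input returns p = 1 by convention).
α = 0.05, two-sided, no multiple-testing correction. Differences within
1e-9 relative tolerance of zero are snapped to exactly zero before testing:
analytically tied pairs (e.g. two saturated V50 percentages) otherwise leave
±1e-14 round-off residue that would corrupt signed ranks.

## Numerical choices and degenerate inputs

- Dose exactly on a bin edge belongs to that bin (half-open convention).
- Empty structures raise immediately (`EmptyStructureError`); an organ with
  no field overlap yields an empty in-field mask with a warning.
- gEUD of an unirradiated structure is 0 up to the midpoint convention
  (≤ width/2).
- The D50 curve inversion bisects the uniform whole-organ dose-response
  (uniform-dose gEUD equals the dose at any exponent) to a probability
  tolerance of 1e-10.
- Report cells print one decimal, switching to scientific notation below 0.1
  so late-toxicity values at 10⁻²⁶ % remain legible.

## Problem sizes

Default analyses use the 21-patient cohort at 1 mm voxels (~240 voxels per
organ) and 0.1 Gy bins; the full simulate→metrics→NTCP→statistics chain runs
in a few seconds on one core. Exact-enumeration statistical oracles are
exercised at n ≤ 6 where the permutation spaces are small.

## Known limitations

- 1-D geometry cannot represent radial dose gradients across the esophageal
  wall or non-coaxial field arrangements.
- The logistic V50 predictions distributed here use placeholder coefficients
  and are not clinically interpretable until published coefficients are
  transcribed.
- EQD2 conversion assumes every voxel receives its dose in the plan's nominal
  fraction count; partial-course and adaptive scenarios are out of scope.
- DVH-derived Dmax depends on bin width; voxel-side statistics should be used
  when exact maxima matter.
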