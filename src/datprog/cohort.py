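"""Synthetic longitudinal DaTscan cohorts.

Emulates a Parkinson's-disease cohort with the statistical structure the
prognosis pipeline assumes: each patient carries a latent motor-severity
trajectory s(t) = s0 + rho*t that simultaneously drives the MDS-UPDRS-III
motor score (positively) and the striatal binding ratios and rendered
DaTscan uptake volumes (negatively, reflecting dopaminergic loss).  Year-0
and Year-1 observations are the predictors; the Year-4 score is the
regression target.

Default parameters reproduce the demographic and outcome moments of a
198-patient de-novo PD cohort: 144 men / 54 women, age 67.60 +/- 9.96
years, Year-4 MDS-UPDRS-III 30.65 +/- 10.53.  Baseline severity is drawn
from a Gamma distribution so the outcome distribution is right-skewed and
strictly positive, as observed motor scores are.

All generation is a pure function of the spec (including its seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "SBRQuadruple",
    "StriatalVolume",
    "PatientRecord",
    "CohortSpec",
    "CohortIOError",
    "TIMEPOINTS",
    "UPDRS3_MAX",
    "generate_cohort",
    "render_striatal_volume",
    "split_cohort",
    "write_cohort",
    "read_cohort",
]

TIMEPOINTS = ("Y0", "Y1")
UPDRS3_MAX = 132.0
SBR_FLOOR = 0.05
_TIME_OF = {"Y0": 0.0, "Y1": 1.0}


class CohortIOError(Exception):
    """Raised when cohort files on disk are missing or inconsistent."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SBRQuadruple:
    """Striatal binding ratios of the four striatal subregions."""

    left_caudate: float
    right_caudate: float
    left_putamen: float
    right_putamen: float

    def __post_init__(self):
        for name, v in self.as_dict().items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"SBR {name} must be finite and >= 0, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            "left_caudate": self.left_caudate,
            "right_caudate": self.right_caudate,
            "left_putamen": self.left_putamen,
            "right_putamen": self.right_putamen,
        }

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.left_caudate, self.right_caudate, self.left_putamen, self.right_putamen]
        )


@dataclass
class StriatalVolume:
    """A 3D uptake grid with voxel spacing in mm.

    Axis convention: axis 0 = left-right (the mid-sagittal plane sits at its
    center), axis 1 = anterior-posterior, axis 2 = inferior-superior; axial
    (transaxial) slices are planes of constant axis-2 index.
    """

    intensities: np.ndarray
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self):
        a = np.asarray(self.intensities, dtype=np.float32)
        if a.ndim != 3:
            raise ValueError("intensities must be a 3D grid")
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ValueError("intensities must be finite and >= 0")
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be three positive reals")
        self.intensities = a
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, StriatalVolume)
            and self.voxel_spacing == other.voxel_spacing
            and np.array_equal(self.intensities, other.intensities)
        )


@dataclass
class PatientRecord:
    """One patient's two-timepoint predictors and Year-4 outcome."""

    patient_id: str
    age_years: float
    sex: str
    years_since_diagnosis: float
    years_since_symptom_onset: float
    volumes: dict[str, StriatalVolume]
    sbr: dict[str, SBRQuadruple]
    updrs3: dict[str, float]
    outcome_y4: float | None = None

    def __post_init__(self):
        if not 18.0 <= self.age_years <= 110.0:
            raise ValueError(f"{self.patient_id}: age {self.age_years} outside [18, 110]")
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.patient_id}: sex must be 'male' or 'female'")
        if self.years_since_diagnosis < 0:
            raise ValueError(f"{self.patient_id}: negative years_since_diagnosis")
        if self.years_since_symptom_onset < self.years_since_diagnosis:
            raise ValueError(
                f"{self.patient_id}: symptom onset precedes diagnosis interval"
            )
        for mapping, label in ((self.volumes, "volumes"), (self.sbr, "sbr"), (self.updrs3, "updrs3")):
            if set(mapping) != set(TIMEPOINTS):
                raise ValueError(f"{self.patient_id}: {label} must be keyed by exactly {TIMEPOINTS}")
        for tp, score in self.updrs3.items():
            _check_score(score, f"{self.patient_id} updrs3[{tp}]")
        if self.outcome_y4 is not None:
            _check_score(self.outcome_y4, f"{self.patient_id} outcome_y4")

    def __eq__(self, other) -> bool:
        if not isinstance(other, PatientRecord):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.age_years == other.age_years
            and self.sex == other.sex
            and self.years_since_diagnosis == other.years_since_diagnosis
            and self.years_since_symptom_onset == other.years_since_symptom_onset
            and self.volumes == other.volumes
            and self.sbr == other.sbr
            and self.updrs3 == other.updrs3
            and self.outcome_y4 == other.outcome_y4
        )


def _check_score(score: float, label: str) -> None:
    if not math.isfinite(score) or not 0.0 <= score <= UPDRS3_MAX:
        raise ValueError(f"{label}: score {score} outside [0, {UPDRS3_MAX}]")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the generative cohort model.

    The latent severity is s(t) = s0 + rho*t with s0 ~ Gamma(mean, sd) and
    rho ~ Normal(mean, sd); scores are score_offset + score_scale*s(t) plus
    Gaussian noise, clipped to the MDS-UPDRS-III scale; each SBR component
    is sbr_offset - sbr_slope*s(t) plus noise, floored at 0.05.
    """

    n_patients: int = 198
    seed: int = 0
    volume_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    male_fraction: float = 144 / 198
    age_mean: float = 67.60
    age_sd: float = 9.96
    severity_baseline_mean: float = 20.0
    severity_baseline_sd: float = 9.0
    progression_rate_mean: float = 2.6625
    progression_rate_sd: float = 1.25
    score_scale: float = 1.0
    score_offset: float = 0.0
    sbr_offset: float = 2.5
    sbr_slope: float = 0.04
    score_noise_sd: float = 2.0
    sbr_noise_sd: float = 0.15
    image_noise_sd: float = 0.05

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        for name in ("age_sd", "severity_baseline_sd", "progression_rate_sd",
                     "score_noise_sd", "sbr_noise_sd", "image_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in dataclasses.fields(self):
            v = getattr(self, name.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ValueError(f"{name.name} must be finite")
        object.__setattr__(self, "volume_shape", tuple(int(s) for s in self.volume_shape))
        object.__setattr__(self, "voxel_spacing", tuple(float(s) for s in self.voxel_spacing))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# volume rendering
# ---------------------------------------------------------------------------

# fractional blob centers (left-right, anterior-posterior, inferior-superior):
# caudate heads anterior-medial, putamina posterior-lateral, mirror pairs
# about the mid-sagittal plane.
_BLOB_CENTERS = {
    "left_caudate": (0.36, 0.40, 0.50),
    "right_caudate": (0.64, 0.40, 0.50),
    "left_putamen": (0.28, 0.62, 0.50),
    "right_putamen": (0.72, 0.62, 0.50),
}
_BLOB_SIGMA_FRAC = 0.055
_BACKGROUND = 0.1
_REGION_ORDER = ("left_caudate", "right_caudate", "left_putamen", "right_putamen")


@lru_cache(maxsize=8)
def _blob_templates(shape: tuple[int, int, int]) -> np.ndarray:
    """Unit-amplitude Gaussian blob per region, stacked (4, *shape)."""
    grids = np.indices(shape).astype(np.float64)
    templates = []
    for region in _REGION_ORDER:
        q = np.zeros(shape)
        for ax, frac in enumerate(_BLOB_CENTERS[region]):
            center = frac * (shape[ax] - 1)
            sigma = max(_BLOB_SIGMA_FRAC * shape[ax], 0.75)
            q += ((grids[ax] - center) / sigma) ** 2
        templates.append(np.exp(-0.5 * q))
    return np.stack(templates)


def render_striatal_volume(
    sbr: SBRQuadruple,
    shape: tuple[int, int, int] = (32, 32, 16),
    noise_sd: float = 0.05,
    seed: int = 0,
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> StriatalVolume:
    """Render a synthetic uptake volume: four Gaussian blobs at the striatal
    subregion positions, each with peak amplitude equal to its binding ratio,
    over a uniform low background, plus seeded Gaussian noise clipped at 0."""
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 8 for s in shape):
        raise ValueError("volume shape must have three components, each >= 8")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    amps = sbr.as_array()
    vol = _BACKGROUND + np.tensordot(amps, _blob_templates(shape), axes=1)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd, size=shape)
    return StriatalVolume(np.clip(vol, 0.0, None), voxel_spacing)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a full synthetic cohort from the generative model in CohortSpec.

    Deterministic: identical specs (including seed) yield identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    records: list[PatientRecord] = []
    if n == 0:
        return records

    ages = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18.0, 110.0)
    male = rng.random(n) < spec.male_fraction
    yrs_diag = rng.uniform(0.4, 2.2, n)
    yrs_onset = yrs_diag + rng.uniform(0.2, 2.5, n)

    # latent severity: Gamma baseline (right-skewed, positive), Normal slope
    if spec.severity_baseline_sd > 0:
        k = (spec.severity_baseline_mean / spec.severity_baseline_sd) ** 2
        theta = spec.severity_baseline_sd**2 / spec.severity_baseline_mean
        s0 = rng.gamma(k, theta, n)
    else:
        s0 = np.full(n, spec.severity_baseline_mean)
    rho = rng.normal(spec.progression_rate_mean, spec.progression_rate_sd, n)

    times = np.array([0.0, 1.0, 4.0])
    sev = s0[:, None] + rho[:, None] * times[None, :]  # (n, 3)
    scores = np.clip(
        spec.score_offset
        + spec.score_scale * sev
        + rng.normal(0.0, spec.score_noise_sd, sev.shape),
        0.0,
        UPDRS3_MAX,
    )
    sbr_vals = np.maximum(
        SBR_FLOOR,
        spec.sbr_offset
        - spec.sbr_slope * sev[:, :2, None]
        + rng.normal(0.0, spec.sbr_noise_sd, (n, 2, 4)),
    )
    vol_seeds = rng.integers(0, 2**31 - 1, size=(n, 2))

    width = max(3, len(str(n - 1)))
    for i in range(n):
        sbr = {
            tp: SBRQuadruple(*sbr_vals[i, j]) for j, tp in enumerate(TIMEPOINTS)
        }
        volumes = {
            tp: render_striatal_volume(
                sbr[tp],
                spec.volume_shape,
                spec.image_noise_sd,
                seed=int(vol_seeds[i, j]),
                voxel_spacing=spec.voxel_spacing,
            )
            for j, tp in enumerate(TIMEPOINTS)
        }
        records.append(
            PatientRecord(
                patient_id=f"P{i:0{width}d}",
                age_years=float(ages[i]),
                sex="male" if male[i] else "female",
                years_since_diagnosis=float(yrs_diag[i]),
                years_since_symptom_onset=float(yrs_onset[i]),
                volumes=volumes,
                sbr=sbr,
                updrs3={tp: float(scores[i, j]) for j, tp in enumerate(TIMEPOINTS)},
                outcome_y4=float(scores[i, 2]),
            )
        )
    return records


def split_cohort(
    records: list[PatientRecord],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list[PatientRecord], list[PatientRecord], list[PatientRecord]]:
    """Randomly partition a cohort into (train, validation, test).

    Validation and test receive round(n * fraction) records each (half-up
    rounding); training receives the remainder, so 198 patients under a
    60/20/20 split give (118, 40, 40).
    """
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive reals")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    _, f_val, f_test = fractions
    n_val = int(math.floor(n * f_val + 0.5))
    n_test = int(math.floor(n * f_test + 0.5))
    if n_val + n_test >= n:
        raise ValueError("validation+test fractions leave no training records")
    perm = np.random.default_rng(seed).permutation(n)
    test = [records[i] for i in perm[:n_test]]
    val = [records[i] for i in perm[n_test : n_test + n_val]]
    train = [records[i] for i in perm[n_test + n_val :]]
    return train, val, test


# ---------------------------------------------------------------------------
# cohort I/O (NIfTI volumes + CSV tables)
# ---------------------------------------------------------------------------


def write_cohort(records: list[PatientRecord], directory: str | Path) -> dict:
    """Write a cohort to a directory: one NIfTI volume per patient-timepoint
    plus clinical.csv, sbr.csv, updrs.csv, outcomes.csv and a manifest.json.
    Returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    clinical, sbr_rows, updrs_rows, outcome_rows = [], [], [], []
    volume_files = {}
    for rec in records:
        clinical.append(
            {
                "patient_id": rec.patient_id,
                "age_years": rec.age_years,
                "sex": rec.sex,
                "years_since_diagnosis": rec.years_since_diagnosis,
                "years_since_symptom_onset": rec.years_since_symptom_onset,
            }
        )
        for tp in TIMEPOINTS:
            sbr_rows.append(
                {"patient_id": rec.patient_id, "timepoint": tp, **rec.sbr[tp].as_dict()}
            )
            updrs_rows.append(
                {"patient_id": rec.patient_id, "timepoint": tp, "updrs3": rec.updrs3[tp]}
            )
            vol = rec.volumes[tp]
            fname = f"{rec.patient_id}_{tp}.nii.gz"
            affine = np.diag(list(vol.voxel_spacing) + [1.0])
            nib.save(nib.Nifti1Image(vol.intensities, affine), directory / fname)
            volume_files[f"{rec.patient_id}_{tp}"] = fname
        if rec.outcome_y4 is not None:
            outcome_rows.append({"patient_id": rec.patient_id, "outcome_y4": rec.outcome_y4})
    pd.DataFrame(clinical).to_csv(directory / "clinical.csv", index=False)
    pd.DataFrame(sbr_rows).to_csv(directory / "sbr.csv", index=False)
    pd.DataFrame(updrs_rows).to_csv(directory / "updrs.csv", index=False)
    pd.DataFrame(outcome_rows).to_csv(directory / "outcomes.csv", index=False)
    manifest = {
        "n_patients": len(records),
        "patient_ids": [r.patient_id for r in records],
        "volume_files": volume_files,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_cohort(directory: str | Path) -> list[PatientRecord]:
    """Read a cohort written by write_cohort; validates schema, score ranges
    and cross-table patient-id consistency, naming the offending record."""
    directory = Path(directory)
    try:
        # round_trip parsing: CSV floats must restore bit-exactly
        clinical = pd.read_csv(directory / "clinical.csv", float_precision="round_trip")
        sbr_tab = pd.read_csv(directory / "sbr.csv", float_precision="round_trip")
        updrs_tab = pd.read_csv(directory / "updrs.csv", float_precision="round_trip")
        outcomes = pd.read_csv(directory / "outcomes.csv", float_precision="round_trip")
    except FileNotFoundError as exc:
        raise CohortIOError(f"missing cohort table: {exc.filename}") from exc

    ids = list(clinical["patient_id"])
    for tab, name in ((sbr_tab, "sbr.csv"), (updrs_tab, "updrs.csv")):
        extra = set(tab["patient_id"]) - set(ids)
        if extra:
            raise CohortIOError(f"{name} contains unknown patient_id {sorted(extra)[0]}")
    outcome_map = dict(zip(outcomes["patient_id"], outcomes["outcome_y4"]))

    records = []
    for _, row in clinical.iterrows():
        pid = row["patient_id"]
        volumes, sbrs, scores = {}, {}, {}
        for tp in TIMEPOINTS:
            path = directory / f"{pid}_{tp}.nii.gz"
            if not path.exists():
                raise CohortIOError(f"missing volume file for patient {pid}, timepoint {tp}")
            img = nib.load(path)
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
            volumes[tp] = StriatalVolume(np.asarray(img.dataobj, dtype=np.float32), spacing)
            srow = sbr_tab[(sbr_tab.patient_id == pid) & (sbr_tab.timepoint == tp)]
            urow = updrs_tab[(updrs_tab.patient_id == pid) & (updrs_tab.timepoint == tp)]
            if len(srow) != 1 or len(urow) != 1:
                raise CohortIOError(f"patient {pid} timepoint {tp} missing from SBR/UPDRS tables")
            sbrs[tp] = SBRQuadruple(
                float(srow.left_caudate.iloc[0]),
                float(srow.right_caudate.iloc[0]),
                float(srow.left_putamen.iloc[0]),
                float(srow.right_putamen.iloc[0]),
            )
            scores[tp] = float(urow.updrs3.iloc[0])
        try:
            records.append(
                PatientRecord(
                    patient_id=pid,
                    age_years=float(row["age_years"]),
                    sex=str(row["sex"]),
                    years_since_diagnosis=float(row["years_since_diagnosis"]),
                    years_since_symptom_onset=float(row["years_since_symptom_onset"]),
                    volumes=volumes,
                    sbr=sbrs,
                    updrs3=scores,
                    outcome_y4=float(outcome_map[pid]) if pid in outcome_map else None,
                )
            )
        except ValueError as exc:
            raise CohortIOError(f"invalid record for patient {pid}: {exc}") from exc
    return records
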