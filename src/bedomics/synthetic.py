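"""Seeded synthetic cohorts for exercising the pipeline end to end.

Two generators are provided:

* image-level breast phantoms — half-ellipsoid breasts with a fat/gland
  texture, a spherical PTV respecting a skin margin, a PTV-conformal dose
  with sigmoidal penumbra and optional hot spots, and a binary fibrosis
  outcome drawn from a logistic model on named BED/RED features;
* direct feature tables — class-conditional multivariate normal rows with a
  mean shift planted on named columns, for fast testing of the
  augmentation, selection and evaluation stages.

Defaults emulate the clinical cohort structure the analysis assumes:
165 patients, 24.8% positive prevalence, and the three iso-effective
hypo-fractionation schemes 40 Gy/10, 35 Gy/7 and 28 Gy/4 in proportions
73/60/32.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from scipy.special import expit

from ._rng import stage_rng
from .grids import ROIMask, VolumeGrid, resample, resample_mask
from .preprocess import (
    CalibrationCurve,
    FilterSpec,
    FractionationScheme,
    apply_filter,
    default_calibration_curve,
    discretize,
    dose_to_bed,
    hu_to_red,
)

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticPatient",
    "DEFAULT_SCHEME_MIX",
    "DEFAULT_EFFECTS",
    "GRADE_COUNTS",
    "generate_phantom",
    "prepare_patient",
    "planted_features",
    "assign_outcome",
    "assign_outcomes",
    "generate_cohort",
    "generate_feature_table",
    "feature_columns",
]

#: fractionation schemes (total dose Gy, n fractions, cohort weight)
DEFAULT_SCHEME_MIX: tuple[tuple[float, int, float], ...] = (
    (40.0, 10, 73 / 165),
    (35.0, 7, 60 / 165),
    (28.0, 4, 32 / 165),
)

#: fibrosis grade 1/2/3 counts in the emulated cohort (any grade = positive)
GRADE_COUNTS: tuple[int, int, int] = (26, 12, 3)

#: logistic slopes of the planted outcome model (standardized features);
#: higher low-dose tail of PTV BED raises risk, heavy-tailed PTV RED lowers it
DEFAULT_EFFECTS: dict[str, float] = {
    "bed_gaussian_ptv_firstorder_p10": 1.5,
    "red_none_ptv_firstorder_kurtosis": -1.0,
}

META_COLUMNS = ("patient_id", "label", "is_synthetic")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a table: everything except metadata/covariates."""
    return [
        c
        for c in table.columns
        if c not in META_COLUMNS and not c.startswith(("cov_", "scheme_"))
    ]


@dataclass
class SyntheticCohortConfig:
    """Study conditions for a synthetic cohort."""

    n_patients: int = 165
    prevalence: float = 41 / 165
    grid_shape: tuple[int, int, int] = (32, 64, 64)  # (nz, ny, nx)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.5)  # (x, y, z) mm
    scheme_mix: tuple[tuple[float, int, float], ...] = DEFAULT_SCHEME_MIX
    effect_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    intercept: float | None = None  # None → auto-calibrated to prevalence
    hotspot_probability: float = 0.3
    noise_sd_hu: float = 20.0
    gland_fraction: float | None = None  # None → per-patient draw in [0.2, 0.6]
    texture_correlation_mm: float = 6.0
    penumbra_mm: float = 5.0
    skin_margin_mm: float = 5.0
    alpha_beta: float = 3.0
    target_spacing_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValueError("n_patients must be at least 10")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        w = np.array([s[2] for s in self.scheme_mix], dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("scheme weights must be non-negative and sum to 1")
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")


@dataclass
class SyntheticPatient:
    patient_id: str
    ct: VolumeGrid
    dose: VolumeGrid
    breast_mask: ROIMask
    ptv_mask: ROIMask
    scheme: FractionationScheme
    covariates: dict
    label: int | None = None
    latent_score: float | None = None


def _correlated_field(shape, spacing_xyz, corr_mm, rng) -> np.ndarray:
    """Unit-variance Gaussian field with a given spatial correlation length."""
    noise = rng.standard_normal(shape)
    sigma = tuple(corr_mm / spacing_xyz[2 - ax] for ax in range(3))
    f = ndimage.gaussian_filter(noise, sigma=sigma, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_phantom(config: SyntheticCohortConfig, index: int) -> SyntheticPatient:
    """Build one breast/dose phantom, deterministic given (seed, index).

    The breast is a half-ellipsoid of tissue surrounded by air; in-breast
    HU come from a two-component fat/gland mixture (≈ −100 / +40 HU) with
    per-patient gland fraction and 6 mm spatial correlation; the PTV is a
    sphere placed to respect a 5 mm skin margin; dose is a prescription
    plateau over the PTV with a sigmoidal penumbra and an optional Gaussian
    hot spot.
    """
    if index >= config.n_patients:
        raise ValueError(f"index {index} out of range for n_patients={config.n_patients}")
    rng = stage_rng(config.seed, "phantom", index)
    nz, ny, nx = config.grid_shape
    sx, sy, sz = config.voxel_spacing

    zc = (np.arange(nz) * sz)[:, None, None]
    yc = (np.arange(ny) * sy)[None, :, None]
    xc = (np.arange(nx) * sx)[None, None, :]

    # chest wall at y=0 face; half-ellipsoid bulging toward +y
    ax_x = nx * sx * (0.40 + 0.04 * rng.uniform(-1, 1))
    ax_y = ny * sy * (0.70 + 0.05 * rng.uniform(-1, 1))
    ax_z = nz * sz * (0.42 + 0.04 * rng.uniform(-1, 1))
    cx = nx * sx / 2.0
    cz = nz * sz / 2.0
    breast = ((xc - cx) / ax_x) ** 2 + (yc / ax_y) ** 2 + ((zc - cz) / ax_z) ** 2 <= 1.0
    breast = np.broadcast_to(breast, (nz, ny, nx)).copy()

    gland_fraction = (
        config.gland_fraction
        if config.gland_fraction is not None
        else float(rng.uniform(0.2, 0.6))
    )
    tex = _correlated_field((nz, ny, nx), config.voxel_spacing,
                            config.texture_correlation_mm, rng)
    if gland_fraction <= 0.0:
        gland = np.zeros_like(tex, dtype=bool)
    elif gland_fraction >= 1.0:
        gland = np.ones_like(tex, dtype=bool)
    else:
        thr = np.quantile(tex[breast], 1.0 - gland_fraction)
        gland = tex > thr
    hu = np.full((nz, ny, nx), -1000.0)
    hu[breast] = np.where(gland[breast], 40.0, -100.0)
    hu += rng.normal(0.0, config.noise_sd_hu, size=hu.shape)
    ct = VolumeGrid(hu, config.voxel_spacing)

    # PTV: sphere fitting inside the breast with the skin margin
    sampling = (sz, sy, sx)
    dist_in = ndimage.distance_transform_edt(breast, sampling=sampling)
    # target radius 10-16 mm, capped so the sphere plus skin margin fits
    r_cap = float(dist_in.max()) - config.skin_margin_mm
    if r_cap < 4.0:
        raise ValueError(
            f"PTV cannot fit inside the breast: a {config.skin_margin_mm:.0f} mm "
            f"skin margin leaves at most {max(r_cap, 0):.1f} mm of radius"
        )
    r_hi = min(16.0, r_cap)
    r_lo = min(10.0, 0.75 * r_hi)
    r_ptv = float(rng.uniform(r_lo, r_hi))
    candidates = np.argwhere(dist_in >= r_ptv + config.skin_margin_mm)
    pz, py, px = candidates[rng.integers(len(candidates))]
    d_ptv = np.sqrt(
        ((zc - pz * sz)) ** 2 + ((yc - py * sy)) ** 2 + ((xc - px * sx)) ** 2
    )
    ptv = np.broadcast_to(d_ptv <= r_ptv, (nz, ny, nx)) & breast

    # scheme assignment
    weights = np.array([s[2] for s in config.scheme_mix])
    k = rng.choice(len(config.scheme_mix), p=weights / weights.sum())
    total_dose, n_fx, _ = config.scheme_mix[k]
    scheme = FractionationScheme(total_dose, int(n_fx), config.alpha_beta)

    # dose: plateau over PTV, logistic penumbra outside
    signed = np.where(ptv, -ndimage.distance_transform_edt(ptv, sampling=sampling),
                      ndimage.distance_transform_edt(~ptv, sampling=sampling))
    dose = total_dose * expit(-4.0 * signed / config.penumbra_mm)
    if rng.uniform() < config.hotspot_probability:
        in_ptv = np.argwhere(ptv)
        hz, hy, hx = in_ptv[rng.integers(len(in_ptv))]
        amp = total_dose * rng.uniform(0.08, 0.15)
        sig = 8.0
        bump = amp * np.exp(
            -(((zc - hz * sz) ** 2 + (yc - hy * sy) ** 2 + (xc - hx * sx) ** 2)
              / (2.0 * sig**2))
        )
        dose = dose + np.broadcast_to(bump, dose.shape)
    dose = np.clip(dose, 0.0, None)

    covariates = {
        "cov_age": float(np.round(rng.normal(60.0, 8.0), 1)),
        "cov_comorbidity": int(rng.uniform() < 0.2),
        "cov_histology": str(rng.choice(["ductal", "lobular", "other"], p=[0.75, 0.15, 0.10])),
        "cov_laterality": str(rng.choice(["left", "right"])),
        "cov_quadrant": str(rng.choice(["UO", "UI", "LO", "LI", "central"])),
        "cov_chemo": int(rng.uniform() < 0.3),
        "cov_hormone": int(rng.uniform() < 0.7),
        "cov_followup_months": float(np.round(rng.normal(60.0, 12.0), 1)),
    }
    return SyntheticPatient(
        patient_id=f"P{index:04d}",
        ct=ct,
        dose=VolumeGrid(dose, config.voxel_spacing),
        breast_mask=ROIMask(breast, config.voxel_spacing, roi_name="breast"),
        ptv_mask=ROIMask(ptv & breast, config.voxel_spacing, roi_name="ptv"),
        scheme=scheme,
        covariates=covariates,
    )


def prepare_patient(
    patient: SyntheticPatient,
    curve: CalibrationCurve | None = None,
    target_spacing: float | None = None,
) -> tuple[VolumeGrid, VolumeGrid, ROIMask, ROIMask]:
    """CT/dose → (RED, BED, breast, PTV) on the isotropic analysis grid."""
    curve = curve or default_calibration_curve()
    sp = target_spacing or 3.0
    tgt = (sp, sp, sp)
    red = resample(hu_to_red(patient.ct, curve), tgt)
    bed = resample(dose_to_bed(patient.dose, patient.scheme), tgt)
    breast = resample_mask(patient.breast_mask, tgt)
    ptv = resample_mask(patient.ptv_mask, tgt)
    return red, bed, breast, ptv


def planted_features(
    patient: SyntheticPatient,
    names: list[str],
    config: SyntheticCohortConfig,
) -> dict[str, float]:
    """Compute only the named catalog features for one patient."""
    from .radiomics import firstorder_features, glcm_features, glrlm_features, shape_features

    red, bed, breast, ptv = prepare_patient(
        patient, target_spacing=config.target_spacing_mm
    )
    images = {"red": red, "bed": bed}
    rois = {"breast": breast, "ptv": ptv}
    out: dict[str, float] = {}
    for name in names:
        parts = name.split("_")
        if parts[0] == "shape":
            roi = parts[1]
            feat = "_".join(parts[2:])
            out[name] = shape_features(rois[roi], intensity=red)[feat]
            continue
        image, fkind, roi, family = parts[0], parts[1], parts[2], parts[3]
        feat = "_".join(parts[4:])
        vol = apply_filter(images[image], FilterSpec(fkind) if fkind != "none" else FilterSpec("none"))
        if family == "firstorder":
            out[name] = firstorder_features(vol, rois[roi])[feat]
        elif family == "glcm":
            out[name] = glcm_features(discretize(vol, rois[roi]))[feat]
        elif family == "glrlm":
            out[name] = glrlm_features(discretize(vol, rois[roi]))[feat]
        else:
            raise KeyError(name)
    return out


def _validate_effect_names(config: SyntheticCohortConfig) -> None:
    from .radiomics import default_catalog

    valid = set(default_catalog().columns)
    unknown = [n for n in config.effect_coefficients if n not in valid]
    if unknown:
        preview = ", ".join(sorted(valid))[:300]
        raise KeyError(
            f"unknown feature name(s) in effect_coefficients: {unknown}; "
            f"valid names start with: {preview}..."
        )


def _calibrate_intercept(latent: np.ndarray, prevalence: float) -> float:
    """Intercept b with mean(sigmoid(b + latent)) == prevalence."""

    def f(b):
        return float(expit(b + latent).mean() - prevalence)

    return float(brentq(f, -30.0, 30.0))


def assign_outcomes(
    patients: list[SyntheticPatient],
    config: SyntheticCohortConfig,
    features: pd.DataFrame | None = None,
) -> list[SyntheticPatient]:
    """Draw the binary fibrosis outcome for a whole cohort.

    The latent score is ``intercept + Σ coef · z(feature)`` with features
    standardized over the cohort; the intercept, unless fixed in the
    config, is calibrated so the expected prevalence matches the config.
    Labels are then independent Bernoulli draws.  Patients are modified in
    place and returned.
    """
    _validate_effect_names(config)
    coefs = config.effect_coefficients
    if coefs:
        if features is None:
            rows = [planted_features(p, list(coefs), config) for p in patients]
            features = pd.DataFrame(rows)
        z = (features - features.mean()) / features.std(ddof=0).replace(0.0, 1.0)
        latent = sum(c * z[name].to_numpy() for name, c in coefs.items())
        latent = np.asarray(latent, dtype=float)
    else:
        latent = np.zeros(len(patients))
    intercept = (
        config.intercept
        if config.intercept is not None
        else _calibrate_intercept(latent, config.prevalence)
    )
    probs = expit(intercept + latent)
    rng = stage_rng(config.seed, "outcome")
    labels = (rng.uniform(size=len(patients)) < probs).astype(int)
    for p, s, y in zip(patients, latent, labels):
        p.latent_score = float(intercept + s)
        p.label = int(y)
    return patients


def assign_outcome(
    patient: SyntheticPatient,
    config: SyntheticCohortConfig,
    standardization: dict[str, tuple[float, float]] | None = None,
) -> int:
    """Outcome draw for a single patient.

    With effect coefficients, cohort standardization statistics
    ``{name: (mean, sd)}`` must be supplied (the logistic slopes act on
    standardized features); without coefficients the label is a pure
    Bernoulli draw at the configured prevalence.
    """
    _validate_effect_names(config)
    coefs = config.effect_coefficients
    if coefs:
        if standardization is None:
            raise ValueError(
                "single-patient outcome with effect coefficients needs cohort "
                "standardization statistics; use assign_outcomes for a cohort"
            )
        feats = planted_features(patient, list(coefs), config)
        latent = sum(
            c * (feats[n] - standardization[n][0]) / (standardization[n][1] or 1.0)
            for n, c in coefs.items()
        )
    else:
        latent = 0.0
    intercept = (
        config.intercept
        if config.intercept is not None
        else float(np.log(config.prevalence / (1.0 - config.prevalence)))
    )
    idx = int(patient.patient_id.lstrip("P"))
    rng = stage_rng(config.seed, "outcome_single", idx)
    patient.latent_score = float(intercept + latent)
    patient.label = int(rng.uniform() < expit(patient.latent_score))
    return patient.label


def generate_cohort(config: SyntheticCohortConfig, out_dir: str | Path) -> pd.DataFrame:
    """Generate, label and write a full phantom cohort.

    Writes per-patient CT, dose and mask volumes plus ``cohort.csv``
    (covariates, scheme, label, file paths) and returns the manifest.
    Idempotent for a fixed config.
    """
    from .io import write_mask, write_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patients = [generate_phantom(config, i) for i in range(config.n_patients)]
    assign_outcomes(patients, config)

    records = []
    for p in patients:
        pdir = out_dir / p.patient_id
        pdir.mkdir(exist_ok=True)
        paths = {
            "ct_path": pdir / "ct.nii.gz",
            "dose_path": pdir / "dose.nii.gz",
            "breast_path": pdir / "breast.nii.gz",
            "ptv_path": pdir / "ptv.nii.gz",
        }
        write_volume(p.ct, paths["ct_path"])
        write_volume(p.dose, paths["dose_path"])
        write_mask(p.breast_mask, paths["breast_path"])
        write_mask(p.ptv_mask, paths["ptv_path"])
        rec = {
            "patient_id": p.patient_id,
            **{k: str(v.relative_to(out_dir)) for k, v in paths.items()},
            "scheme_total_dose": p.scheme.total_dose,
            "scheme_n_fractions": p.scheme.n_fractions,
            "label": p.label,
            "latent_score": p.latent_score,
            **p.covariates,
        }
        records.append(rec)
    manifest = pd.DataFrame(records)
    manifest.to_csv(out_dir / "cohort.csv", index=False)
    return manifest


def _feature_names(n_features: int) -> list[str]:
    """Radiomics-style column names, planted-effect names first."""
    from .radiomics import default_catalog

    priority = [
        "bed_gaussian_ptv_firstorder_p10",
        "red_none_ptv_firstorder_kurtosis",
        "bed_log_breast_glcm_cluster_shade",
        "bed_log_breast_glrlm_run_length_non_uniformity",
        "red_gaussian_ptv_firstorder_range",
        "red_gaussian_ptv_glcm_cluster_shade",
        "bed_log_ptv_glcm_inverse_variance",
    ]
    rest = [c for c in default_catalog().columns if c not in priority]
    names = (priority + rest)[:n_features]
    if len(names) < n_features:  # more columns than the catalog has
        names += [f"noise_feature_{k}" for k in range(n_features - len(names))]
    return names


def generate_feature_table(
    n_pos: int,
    n_neg: int,
    n_features: int = 30,
    shift: tuple[float, ...] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Class-conditional multivariate-normal feature table.

    Positive rows are shifted by ``shift`` on the first ``len(shift)``
    features; the remaining columns are pure standard-normal noise.
    Column names follow the radiomics naming scheme.
    """
    if n_features < len(shift):
        raise ValueError("n_features must be at least len(shift)")
    rng = stage_rng(seed, "feature_table")
    names = _feature_names(n_features)
    X_neg = rng.standard_normal((n_neg, n_features))
    X_pos = rng.standard_normal((n_pos, n_features))
    mu = np.zeros(n_features)
    mu[: len(shift)] = shift
    X_pos = X_pos + mu
    X = np.vstack([X_neg, X_pos])
    y = np.concatenate([np.zeros(n_neg, dtype=int), np.ones(n_pos, dtype=int)])
    order = rng.permutation(len(y))
    df = pd.DataFrame(X[order], columns=names)
    df.insert(0, "label", y[order])
    df.insert(0, "patient_id", [f"P{i:04d}" for i in range(len(y))])
    return df
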