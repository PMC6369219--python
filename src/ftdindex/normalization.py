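"""Head-size, age and sex correction of regional volumes.

Volumes are corrected in two stages, in this order:

1. **Head size** — proportional scaling to a common intracranial volume:
   ``v' = v * reference_tiv / tiv``, with ``reference_tiv`` the mean TIV of
   the reference group.  This removes the (to first order proportional)
   dependence of regional volume on cranial capacity.
2. **Age and sex** — per-region linear residualization on age (centred at
   the reference mean age) and a male indicator, with coefficients
   estimated by ordinary least squares within the reference group.  An
   optional third stage subtracts additive per-field-strength offsets.

The reference group defaults to the non-FTD diagnoses, matching the
population against which the index z-scores are calibrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas_io import DIAGNOSES, Cohort, IncompatibleModelError

NON_FTD = tuple(d for d in DIAGNOSES if d != "FTD")
DEFAULT_COVARIATES = ("headsize", "age", "sex")
VALID_COVARIATES = ("headsize", "age", "sex", "field_strength")

#: floor for corrected volumes so downstream log-ratios stay defined (ml)
VOLUME_EPS = 1e-3

_SEX_IND = {"female": 0.0, "male": 1.0}


@dataclass
class NormalizationModel:
    """Fitted per-region head-size/age/sex (optionally field-strength) correction."""

    regions: list[str]
    covariates: tuple[str, ...]
    reference_tiv: float
    reference_mean_age: float
    age_coef: dict[str, float]            # ml / year
    sex_coef: dict[str, float]            # ml (male minus female)
    fieldstrength_coefs: dict[str, dict[float, float]] = field(default_factory=dict)
    reference_group: tuple[str, ...] = NON_FTD
    fitted_on: int = 0

    def to_dict(self) -> dict:
        return {
            "model_type": "normalization",
            "regions": list(self.regions),
            "covariates": list(self.covariates),
            "reference_tiv": self.reference_tiv,
            "reference_mean_age": self.reference_mean_age,
            "age_coef": self.age_coef,
            "sex_coef": self.sex_coef,
            "fieldstrength_coefs": {
                r: {repr(fs): c for fs, c in m.items()}
                for r, m in self.fieldstrength_coefs.items()},
            "reference_group": list(self.reference_group),
            "fitted_on": self.fitted_on,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationModel":
        return cls(
            regions=list(d["regions"]),
            covariates=tuple(d["covariates"]),
            reference_tiv=float(d["reference_tiv"]),
            reference_mean_age=float(d["reference_mean_age"]),
            age_coef={k: float(v) for k, v in d["age_coef"].items()},
            sex_coef={k: float(v) for k, v in d["sex_coef"].items()},
            fieldstrength_coefs={
                r: {float(fs): float(c) for fs, c in m.items()}
                for r, m in d["fieldstrength_coefs"].items()},
            reference_group=tuple(d["reference_group"]),
            fitted_on=int(d["fitted_on"]),
        )

    def check_atlas(self, atlas) -> None:
        missing = [r for r in self.regions if r not in atlas]
        if missing:
            raise IncompatibleModelError(
                f"normalization model covers regions absent from atlas: {missing[:5]}")


def fit_normalization(cohort: Cohort,
                      reference_group=NON_FTD,
                      covariates=DEFAULT_COVARIATES) -> NormalizationModel:
    """Estimate the correction on the reference subjects of ``cohort``.

    ``covariates`` is a subset of ``{"headsize", "age", "sex",
    "field_strength"}``; omitted covariates get zero coefficients (their
    correction becomes a no-op).  A covariate with zero variance in the
    reference group is fixed at 0 with a warning.
    """
    unknown = set(covariates) - set(VALID_COVARIATES)
    if unknown:
        raise ValueError(f"unknown covariates: {sorted(unknown)}")
    ref = cohort.subset(cohort.mask(reference_group))
    n = len(ref)
    if n == 0:
        raise ValueError(f"reference group {reference_group} is empty")
    df = ref.data
    regions = cohort.atlas.names

    ref_tiv = float(df["tiv"].mean()) if "headsize" in covariates else float("nan")
    ref_age = float(df["age"].mean())

    # stage 1: proportional head-size scaling of the reference volumes
    v = df[regions].to_numpy(dtype=float)
    if "headsize" in covariates:
        v = v * (ref_tiv / df["tiv"].to_numpy(dtype=float))[:, None]

    # stage 2: shared design matrix, one OLS per region solved jointly
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    fs_levels: list[float] = []
    if "age" in covariates:
        age = df["age"].to_numpy(dtype=float) - ref_age
        if np.ptp(age) == 0:
            warnings.warn("age has zero variance in reference group; "
                          "age coefficient fixed at 0", stacklevel=2)
        else:
            cols.append(age)
            names.append("age")
    if "sex" in covariates:
        sex = df["sex"].map(_SEX_IND).to_numpy(dtype=float)
        if np.ptp(sex) == 0:
            warnings.warn("sex has zero variance in reference group; "
                          "sex coefficient fixed at 0", stacklevel=2)
        else:
            cols.append(sex)
            names.append("sex")
    if "field_strength" in covariates:
        fs = df["field_strength"].to_numpy(dtype=float)
        if np.isnan(fs).any():
            raise ValueError("field_strength correction requested but values missing")
        levels = sorted(set(fs))
        # offsets relative to the most frequent field strength
        base = max(levels, key=lambda l: (fs == l).sum())
        for lev in levels:
            if lev == base:
                continue
            cols.append((fs == lev).astype(float))
            names.append(f"fs_{lev}")
            fs_levels.append(lev)
        if not fs_levels:
            warnings.warn("field strength has a single level in reference group; "
                          "offsets fixed at 0", stacklevel=2)

    n_coef = len(names)
    if n * 1.0 < 10 * n_coef:
        raise ValueError(
            f"reference group too small: {n} subjects for {n_coef} coefficients "
            f"(need >= {10 * n_coef})")

    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)  # (n_coef, n_regions)
    coef = {name: beta[i] for i, name in enumerate(names)}

    zeros = np.zeros(len(regions))
    age_c = coef.get("age", zeros)
    sex_c = coef.get("sex", zeros)
    fs_coefs: dict[str, dict[float, float]] = {}
    if fs_levels:
        fs_coefs = {r: {lev: float(coef[f"fs_{lev}"][j]) for lev in fs_levels}
                    for j, r in enumerate(regions)}

    return NormalizationModel(
        regions=list(regions),
        covariates=tuple(covariates),
        reference_tiv=ref_tiv,
        reference_mean_age=ref_age,
        age_coef={r: float(age_c[j]) for j, r in enumerate(regions)},
        sex_coef={r: float(sex_c[j]) for j, r in enumerate(regions)},
        fieldstrength_coefs=fs_coefs,
        reference_group=tuple(reference_group),
        fitted_on=n,
    )


def apply_normalization(model: NormalizationModel, cohort: Cohort) -> Cohort:
    """Return a cohort whose volumes are corrected by ``model``.

    ``v_norm = v * reference_tiv/tiv - age_coef*(age - ref_mean_age)
    - sex_coef*male_indicator - field_strength_offset``, floored at a small
    positive epsilon so log-ratios downstream stay defined.
    """
    model.check_atlas(cohort.atlas)
    df = cohort.data
    regions = model.regions
    v = df[regions].to_numpy(dtype=float)

    if "headsize" in model.covariates:
        tiv = df["tiv"].to_numpy(dtype=float)
        if (tiv <= 0).any():
            who = df.loc[tiv <= 0, "subject_id"].tolist()
            raise ValueError(f"non-positive TIV for subjects: {who}")
        v = v * (model.reference_tiv / tiv)[:, None]

    age_c = np.array([model.age_coef[r] for r in regions])
    sex_c = np.array([model.sex_coef[r] for r in regions])
    age = df["age"].to_numpy(dtype=float) - model.reference_mean_age
    sex = df["sex"].map(_SEX_IND).to_numpy(dtype=float)
    v = v - np.outer(age, age_c) - np.outer(sex, sex_c)

    if model.fieldstrength_coefs:
        fs = df["field_strength"].to_numpy(dtype=float)
        off = np.zeros_like(v)
        for j, r in enumerate(regions):
            per = model.fieldstrength_coefs.get(r, {})
            for lev, c in per.items():
                off[fs == lev, j] = c
        v = v - off

    n_floored = int((v < VOLUME_EPS).sum())
    if n_floored:
        warnings.warn(f"{n_floored} corrected volumes floored at {VOLUME_EPS} ml",
                      stacklevel=2)
        v = np.maximum(v, VOLUME_EPS)

    out = pd.DataFrame(v, columns=regions, index=df.index)
    return cohort.with_volumes(out, note="normalized")
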