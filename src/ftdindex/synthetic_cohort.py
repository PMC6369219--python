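"""Synthetic memory-clinic cohort generator.

Emulates the structure the indices assume without any patient data: a
mixed diagnostic case mix (SCD/MCI/AD/VaD/DLB/Other/FTD with FTD
subtypes), group-specific regional atrophy patterns (frontotemporal in
FTD, left-lateralized in the aphasic variants, left temporal pole in
svPPA, temporoparietal+hippocampal in AD, and a subcortical-predominant
bvFTD subgroup), head-size/age/sex effects on volumes, and multiplicative
lognormal measurement noise.

Per subject the generator draws sex, age and TIV; sets each regional
volume to its template mean scaled proportionally by TIV and shrunk by a
linear age slope; applies the group's fractional reductions (overlapping
region sets compound multiplicatively); and finally multiplies lognormal
noise.  Generation is a pure function of (config, seed).

The default case mix follows a published two-center memory-clinic sample
of 1213 patients (341 AD, 66 DLB, 40 VaD, 104 other dementias, 229 MCI,
317 SCD, 116 FTD: 64 bvFTD / 30 svPPA / 8 nfvPPA / 10 rtvFTD / 4 +MND);
the validation preset mirrors an independent 200-patient single-center
sample (110 AD, 20 DLB, 28 VaD, 18 SCD, 24 FTD: 10/12/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas_io import Cohort, RegionAtlas, default_atlas

SUBTYPES = ("bvFTD", "svPPA", "nfvPPA", "rtvFTD", "FTD_MND")

#: ADC+PredictND-style case mix (n = 1213)
DEFAULT_GROUP_SIZES = {
    "AD": 341, "DLB": 66, "VaD": 40, "Other": 104, "MCI": 229, "SCD": 317,
    "bvFTD": 64, "svPPA": 30, "nfvPPA": 8, "rtvFTD": 10, "FTD_MND": 4,
}

#: DDRC-style external-validation case mix (n = 200)
VALIDATION_GROUP_SIZES = {
    "AD": 110, "DLB": 20, "VaD": 28, "SCD": 18,
    "bvFTD": 10, "svPPA": 12, "nfvPPA": 2,
}

#: fractional volume reductions per group, keyed by named region set
DEFAULT_EFFECTS = {
    "SCD": {},
    "MCI": {"temporoparietal": 0.05, "hippocampal": 0.08},
    "AD": {"temporoparietal": 0.15, "hippocampal": 0.15},
    "VaD": {"subcortical": 0.08},
    "DLB": {"all_tissue": 0.04},
    "Other": {"all_tissue": 0.05},
    "bvFTD": {"anterior": 0.15},
    "bvFTD_subcortical": {"subcortical": 0.20, "anterior": 0.05},
    "svPPA": {"left_temporal_pole": 0.30, "left_temporal": 0.15},
    "nfvPPA": {"left_frontal": 0.15},
    "rtvFTD": {"right_temporal": 0.20},
    "FTD_MND": {"anterior": 0.10},
}

#: per-group (age mean, age SD, female fraction)
DEFAULT_DEMOGRAPHICS = {
    "SCD": (62.0, 9.0, 0.55), "MCI": (67.0, 8.0, 0.38), "AD": (68.0, 8.0, 0.56),
    "VaD": (71.0, 8.0, 0.38), "DLB": (69.0, 8.0, 0.15), "Other": (73.0, 9.0, 0.51),
    "bvFTD": (63.0, 7.0, 0.44), "svPPA": (63.0, 6.0, 0.47),
    "nfvPPA": (70.0, 6.0, 0.38), "rtvFTD": (63.0, 7.0, 0.30),
    "FTD_MND": (62.0, 6.0, 0.50),
}

VALIDATION_DEMOGRAPHICS = {
    **DEFAULT_DEMOGRAPHICS,
    "SCD": (63.0, 7.0, 0.33), "AD": (72.0, 10.0, 0.62),
    "DLB": (72.0, 9.0, 0.35), "VaD": (72.0, 8.0, 0.39),
    "bvFTD": (65.0, 13.0, 0.30), "svPPA": (69.0, 7.0, 0.42),
    "nfvPPA": (72.0, 8.0, 0.50),
}


@dataclass
class SimulationConfig:
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    atrophy_effects: dict = field(default_factory=lambda: {
        g: dict(e) for g, e in DEFAULT_EFFECTS.items()})
    demographics: dict = field(default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS))
    #: share of bvFTD subjects drawn from the subcortical-predominant profile
    subcortical_bvftd_fraction: float = 0.5
    #: TIV (ml) mean/SD per sex
    tiv_model: dict = field(default_factory=lambda: {
        "female": (1420.0, 110.0), "male": (1560.0, 120.0)})
    #: SD of the lognormal measurement noise on log-volume
    noise_sd: float = 0.05
    #: relative volume loss per year of age beyond 65 (cortex / subcortex)
    age_slope_cortical: float = 0.003
    age_slope_subcortical: float = 0.0015
    field_strength_mix: dict = field(default_factory=lambda: {
        1.5: 0.60, 3.0: 0.35, 1.0: 0.05})
    #: optional multiplicative volume factor per field strength
    field_strength_factors: dict = field(default_factory=dict)
    subject_prefix: str = "S"
    seed: int = 0
    #: sub-stream index; presets meant to coexist (training vs validation)
    #: use different streams so the same seed never duplicates subjects
    seed_stream: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        for g, eff in self.atrophy_effects.items():
            for s, r in eff.items():
                if not 0.0 <= r < 1.0:
                    raise ValueError(f"reduction {g}/{s}={r} outside [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.subcortical_bvftd_fraction <= 1.0:
            raise ValueError("subcortical_bvftd_fraction must lie in [0, 1]")


def validation_config(seed: int = 0) -> SimulationConfig:
    """DDRC-style external-validation preset."""
    return SimulationConfig(group_sizes=dict(VALIDATION_GROUP_SIZES),
                            demographics=dict(VALIDATION_DEMOGRAPHICS),
                            subject_prefix="V", seed=seed, seed_stream=1)


# ---------------------------------------------------------------------------
# region sets and template volumes

def region_set(atlas: RegionAtlas, name: str) -> list[str]:
    """Resolve a named region set against the atlas."""
    tissue = [n for n in atlas.names if "ventricle" not in n]
    sets = {
        "anterior": lambda: atlas.anterior,
        "posterior": lambda: atlas.posterior,
        "left_anterior": lambda: atlas.anterior_hemi("left"),
        "right_anterior": lambda: atlas.anterior_hemi("right"),
        "left_frontal": lambda: atlas.select(hemisphere="left", lobe="frontal",
                                             cortical=True),
        "left_temporal": lambda: atlas.select(hemisphere="left", lobe="temporal",
                                              cortical=True),
        "right_temporal": lambda: atlas.select(hemisphere="right", lobe="temporal",
                                               cortical=True),
        "temporoparietal": lambda: atlas.select(lobes=("temporal", "parietal"),
                                                cortical=True),
        "hippocampal": lambda: atlas.find(r"hippocampus$"),
        "left_temporal_pole": lambda: [n for n in atlas.find("temporal_pole")
                                       if atlas.regions[atlas.names.index(n)]
                                       .hemisphere == "left"],
        "subcortical": lambda: [n for n in tissue
                                if not atlas.regions[atlas.names.index(n)].cortical],
        "all_tissue": lambda: tissue,
    }
    if name not in sets:
        raise ValueError(f"unknown region set {name!r}; known: {sorted(sets)}")
    return sets[name]()


_LOBE_BASE_ML = {"frontal": 9.0, "temporal": 8.0, "parietal": 9.0,
                 "occipital": 7.0, "subcortical_or_other": 5.0}
_TEMPLATE_SEED = 20190204  # fixed: template means are shipped constants


def template_means(atlas: RegionAtlas) -> pd.Series:
    """Plausible per-region template mean volumes (ml) at TIV 1500 ml.

    Fixed constants derived deterministically from the atlas (independent
    of any simulation seed); absolute levels are arbitrary and cancel in
    the ratio indices.
    """
    rng = np.random.default_rng(_TEMPLATE_SEED)
    mult = rng.uniform(0.6, 1.4, size=len(atlas))
    base = np.array([_LOBE_BASE_ML[r.lobe] for r in atlas.regions])
    return pd.Series(base * mult, index=atlas.names)


# ---------------------------------------------------------------------------
# generation

_REFERENCE_TIV = 1500.0
_REFERENCE_AGE = 65.0


def generate_cohort(config: SimulationConfig,
                    atlas: RegionAtlas | None = None) -> Cohort:
    """Draw a full synthetic cohort; bitwise-reproducible from config.seed."""
    config.validate()
    atlas = atlas if atlas is not None else default_atlas()
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, config.seed_stream)))
    tmpl = template_means(atlas).to_numpy()
    cortical = np.array([r.cortical for r in atlas.regions])
    slope = np.where(cortical, config.age_slope_cortical,
                     config.age_slope_subcortical)

    # validate effect region sets up front
    resolved: dict[str, list[tuple[np.ndarray, float]]] = {}
    for g, eff in config.atrophy_effects.items():
        resolved[g] = []
        for set_name, red in eff.items():
            members = region_set(atlas, set_name)
            mask = np.isin(atlas.names, members)
            resolved[g].append((mask, red))

    fs_levels = np.array(sorted(config.field_strength_mix))
    fs_probs = np.array([config.field_strength_mix[l] for l in fs_levels])
    fs_probs = fs_probs / fs_probs.sum()

    rows = []
    counter = 0
    for group in sorted(config.group_sizes):
        n = int(config.group_sizes[group])
        if n == 0:
            continue
        age_mean, age_sd, female_frac = config.demographics[group]
        is_subtype = group in SUBTYPES
        for i in range(n):
            counter += 1
            sid = f"{config.subject_prefix}{counter:04d}"
            sex = "female" if rng.random() < female_frac else "male"
            age = float(np.clip(rng.normal(age_mean, age_sd), 40.0, 95.0))
            tiv_mean, tiv_sd = config.tiv_model[sex]
            tiv = float(max(rng.normal(tiv_mean, tiv_sd), 900.0))
            fs = float(rng.choice(fs_levels, p=fs_probs))

            profile = group
            if group == "bvFTD" and rng.random() < config.subcortical_bvftd_fraction:
                profile = "bvFTD_subcortical"

            v = tmpl * (tiv / _REFERENCE_TIV)
            v = v * (1.0 - slope * (age - _REFERENCE_AGE))
            for mask, red in resolved.get(profile, []):
                v = np.where(mask, v * (1.0 - red), v)
            if config.field_strength_factors:
                v = v * float(config.field_strength_factors.get(fs, 1.0))
            if config.noise_sd > 0:
                v = v * np.exp(rng.normal(0.0, config.noise_sd, size=v.size))

            rows.append({
                "subject_id": sid,
                "diagnosis": "FTD" if is_subtype else group,
                "ftd_subtype": group if is_subtype else None,
                "age": round(age, 1), "sex": sex, "tiv": round(tiv, 1),
                "field_strength": fs,
                **{name: val for name, val in zip(atlas.names, np.round(v, 4))},
            })
    df = pd.DataFrame(rows)
    return Cohort(atlas, df, provenance={"generator": "ftdindex.synthetic_cohort",
                                         "seed": config.seed,
                                         "n": len(df)})


def make_validation_cohort(config: SimulationConfig | None = None,
                           seed: int = 0,
                           atlas: RegionAtlas | None = None) -> Cohort:
    """DDRC-style 200-subject external-validation cohort.

    Uses a seed stream disjoint from :func:`generate_cohort` at the same
    seed, so training and validation subjects never coincide.
    """
    cfg = config if config is not None else validation_config(seed)
    cfg = replace(cfg, seed=seed, seed_stream=max(cfg.seed_stream, 1))
    return generate_cohort(cfg, atlas)
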