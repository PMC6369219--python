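"""The three volumetric atrophy indices: API, ASI and TPL.

Each index is a z-score against the non-FTD population:

* **API** (anterior vs. posterior index): ``z(log V_A / V_P)`` where
  ``V_A`` is the weighted volume of the cortical frontal+temporal regions
  and ``V_P`` of the cortical parietal+occipital regions.  Low values mean
  frontotemporal-predominant atrophy, the structural hallmark of FTD.
* **ASI** (asymmetry index): ``z(log V_L / V_R)`` over the left vs. right
  frontotemporal regions; deviations flag the lateralized atrophy of the
  primary progressive aphasias.
* **TPL**: the (normalized) volume of the left temporal pole, z-scored the
  same way; low values are characteristic of svPPA.

Region weights are learned from the AD-vs-FTD contrast: for an anterior
region, ``w = (mean_AD - mean_FTD) / mean_nonFTD``; for a posterior
region the difference is reversed.  Negative weights are clamped to zero,
and regions on the exclusion list (by default the parahippocampal and
inferior temporal gyri, anatomical outliers from the anterior weight
pattern) are forced to zero.  Logarithms are natural; the base only
rescales the calibration constants and leaves the z-score unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .atlas_io import Cohort, IncompatibleModelError, RegionAtlas

INDEX_TYPES = ("API", "ASI", "TPL")
DEFAULT_CUTOFF = -1.65

#: name patterns of the regions excluded from the API weight map
DEFAULT_EXCLUSION_PATTERNS = ("parahippocampal", "inferior_temporal_gyrus")

POSITIVE_GROUP = ("FTD",)      # index is built to flag these
CONTRAST_GROUP = ("AD",)       # the weight-defining contrast
NON_FTD = ("SCD", "MCI", "AD", "VaD", "DLB", "Other")


class DegenerateReferenceError(ValueError):
    """Calibration impossible: the reference raw values have zero spread."""


@dataclass
class IndexModel:
    """One fitted biomarker: regions, weights, calibration and cutoff."""

    index_type: str                       # API | ASI | TPL
    numerator_regions: list[str]
    denominator_regions: list[str]
    weights: dict[str, float]
    excluded_regions: list[str]
    mu: float = math.nan
    sigma: float = math.nan
    cutoff: float = DEFAULT_CUTOFF
    direction: str = "lower_is_positive"
    two_sided: bool = False               # |z| rule, relevant for ASI

    def __post_init__(self) -> None:
        if self.index_type not in INDEX_TYPES:
            raise ValueError(f"unknown index type {self.index_type!r}")
        bad = {r: w for r, w in self.weights.items() if w < 0}
        if bad:
            raise ValueError(f"negative weights are not allowed: {bad}")
        for r in self.excluded_regions:
            if self.weights.get(r, 0.0) != 0.0:
                raise ValueError(f"excluded region {r!r} has nonzero weight")

    @property
    def calibrated(self) -> bool:
        return math.isfinite(self.mu) and math.isfinite(self.sigma)

    def to_dict(self) -> dict:
        return {
            "model_type": "index",
            "index_type": self.index_type,
            "numerator_regions": list(self.numerator_regions),
            "denominator_regions": list(self.denominator_regions),
            "weights": dict(self.weights),
            "excluded_regions": list(self.excluded_regions),
            "mu": self.mu,
            "sigma": self.sigma,
            "cutoff": self.cutoff,
            "direction": self.direction,
            "two_sided": self.two_sided,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IndexModel":
        return cls(
            index_type=d["index_type"],
            numerator_regions=list(d["numerator_regions"]),
            denominator_regions=list(d["denominator_regions"]),
            weights={k: float(v) for k, v in d["weights"].items()},
            excluded_regions=list(d["excluded_regions"]),
            mu=float(d["mu"]),
            sigma=float(d["sigma"]),
            cutoff=float(d["cutoff"]),
            direction=d["direction"],
            two_sided=bool(d.get("two_sided", False)),
        )

    def check_atlas(self, atlas: RegionAtlas) -> None:
        needed = set(self.numerator_regions) | set(self.denominator_regions)
        missing = [r for r in needed if r not in atlas]
        if missing:
            raise IncompatibleModelError(
                f"index model references regions absent from atlas: {missing[:5]}")


def default_exclusions(atlas: RegionAtlas,
                       patterns: Sequence[str] = DEFAULT_EXCLUSION_PATTERNS) -> list[str]:
    """Regions matching the exclusion name patterns (both hemispheres)."""
    out: list[str] = []
    for p in patterns:
        out.extend(atlas.find(p))
    return sorted(set(out))


def find_left_temporal_pole(atlas: RegionAtlas) -> str:
    """The left temporal-pole region of ``atlas`` (by name convention)."""
    cand = [n for n in atlas.find("temporal_pole")
            if next(r.hemisphere for r in atlas.regions if r.name == n) == "left"]
    if len(cand) != 1:
        raise ValueError(
            f"could not identify a unique left temporal pole region; candidates: {cand}")
    return cand[0]


# ---------------------------------------------------------------------------
# weight learning

def compute_region_weights(cohort: Cohort,
                           numerator_regions: Sequence[str],
                           denominator_regions: Sequence[str],
                           positive_group: Sequence[str] = POSITIVE_GROUP,
                           contrast_group: Sequence[str] = CONTRAST_GROUP,
                           reference_group: Sequence[str] = NON_FTD,
                           excluded_regions: Sequence[str] = ()) -> dict[str, float]:
    """Learn nonnegative region weights from the AD-vs-FTD contrast.

    Numerator (anterior-side) region: ``(mean_contrast - mean_positive) /
    mean_reference``; denominator (posterior-side) region: the difference
    reversed.  Negative results are clamped to 0; ``excluded_regions`` are
    forced to 0 regardless of the data.  Volumes must be normalized.
    """
    pos = cohort.subset(cohort.mask(positive_group))
    con = cohort.subset(cohort.mask(contrast_group))
    ref = cohort.subset(cohort.mask(reference_group))
    for name, grp in (("positive", pos), ("contrast", con), ("reference", ref)):
        if len(grp) < 2:
            raise ValueError(f"{name} group has {len(grp)} subjects; need >= 2")

    excluded = set(excluded_regions)
    weights: dict[str, float] = {}
    for side_regions, sign in ((numerator_regions, +1), (denominator_regions, -1)):
        for r in side_regions:
            if r in excluded:
                weights[r] = 0.0
                continue
            m_ref = float(ref.data[r].mean())
            if m_ref == 0:
                raise ValueError(f"reference mean volume is zero for region {r!r}")
            diff = float(con.data[r].mean()) - float(pos.data[r].mean())
            weights[r] = max(0.0, sign * diff / m_ref)
    return weights


def symmetrize_weights(weights: Mapping[str, float],
                       atlas: RegionAtlas) -> dict[str, float]:
    """Average each left/right homologue pair to a common weight.

    Used for ASI so that mirrored anatomy yields an exactly mirrored
    index; unpaired regions keep their own weight.  Averaging happens on
    the already-clamped weights, so nonnegativity is preserved.
    """
    pairs = atlas.mirror_pairs()
    out = dict(weights)
    for r, w in weights.items():
        other = pairs.get(r)
        if other is not None and other in weights:
            out[r] = 0.5 * (w + weights[other])
    return out


# ---------------------------------------------------------------------------
# raw values, calibration, classification

def compute_raw_index(volumes: Mapping[str, float], model: IndexModel) -> float:
    """Raw (uncalibrated) index for one subject's volume map.

    API/ASI: natural log of the weighted numerator over weighted
    denominator volume.  TPL: the (single, unit-weighted) region volume.
    """
    num = sum(model.weights.get(r, 0.0) * volumes[r] for r in model.numerator_regions)
    if not model.denominator_regions:        # TPL-style single-volume index
        if num <= 0:
            raise ValueError(f"non-positive {model.index_type} volume: {num}")
        return num
    den = sum(model.weights.get(r, 0.0) * volumes[r] for r in model.denominator_regions)
    if num <= 0:
        raise ValueError("non-positive weighted volume on the numerator side")
    if den <= 0:
        raise ValueError("non-positive weighted volume on the denominator side")
    return math.log(num / den)


def _raw_values(cohort: Cohort, model: IndexModel) -> np.ndarray:
    v = cohort.data
    num = np.zeros(len(v))
    for r in model.numerator_regions:
        num += model.weights.get(r, 0.0) * v[r].to_numpy(dtype=float)
    if not model.denominator_regions:
        if (num <= 0).any():
            raise ValueError("non-positive index volume for some subjects")
        return num
    den = np.zeros(len(v))
    for r in model.denominator_regions:
        den += model.weights.get(r, 0.0) * v[r].to_numpy(dtype=float)
    if (num <= 0).any():
        raise ValueError("non-positive weighted volume on the numerator side")
    if (den <= 0).any():
        raise ValueError("non-positive weighted volume on the denominator side")
    return np.log(num / den)


def calibrate_zscore(raw_values) -> tuple[float, float]:
    """Sample mean and SD (n-1) of the reference raw values."""
    x = np.asarray(list(raw_values), dtype=float)
    if x.size < 2:
        raise ValueError(f"need >= 2 reference values, got {x.size}")
    mu = float(x.mean())
    sigma = float(x.std(ddof=1))
    if sigma == 0:
        raise DegenerateReferenceError("reference raw values have zero spread")
    return mu, sigma


def classify(z, cutoff: float = DEFAULT_CUTOFF, two_sided: bool = False):
    """Positive iff ``z`` lies strictly beyond the cutoff.

    One-sided (default): ``z < cutoff``.  Two-sided (for ASI, where right-
    lateralized atrophy sits on the opposite tail): ``|z| > |cutoff|``.
    """
    z = np.asarray(z, dtype=float)
    out = np.abs(z) > abs(cutoff) if two_sided else z < cutoff
    return bool(out) if out.ndim == 0 else out


def score_cohort(model: IndexModel, cohort: Cohort) -> pd.DataFrame:
    """Per-subject raw value, z-score and classification for a cohort."""
    if not model.calibrated:
        raise ValueError("index model is not calibrated (mu/sigma missing)")
    model.check_atlas(cohort.atlas)
    raw = _raw_values(cohort, model)
    z = (raw - model.mu) / model.sigma
    return pd.DataFrame({
        "subject_id": cohort.data["subject_id"].to_numpy(),
        "raw_value": raw,
        "z": z,
        "predicted_positive": classify(z, model.cutoff, model.two_sided),
    })


# ---------------------------------------------------------------------------
# fitting

def fit_index(cohort: Cohort, index_type: str, *,
              positive_group: Sequence[str] = POSITIVE_GROUP,
              contrast_group: Sequence[str] = CONTRAST_GROUP,
              reference_group: Sequence[str] = NON_FTD,
              excluded_regions: Sequence[str] | None = None,
              cutoff: float = DEFAULT_CUTOFF,
              asi_weight_mode: str = "anterior_contrast",
              two_sided: bool | None = None) -> IndexModel:
    """Learn weights and calibration for one index on a normalized cohort.

    API weighs anterior against posterior cortex; ASI weighs left against
    right frontotemporal cortex, by default reusing the anterior-contrast
    weights symmetrized across homologue pairs (``asi_weight_mode=
    "independent"`` re-estimates per hemisphere without symmetrizing, at
    the cost of exact mirror antisymmetry); TPL is the identity-weighted
    left temporal pole.  Calibration (mu, sigma) always comes from the
    reference (non-FTD) subjects.
    """
    atlas = cohort.atlas
    if index_type == "API":
        numerator = atlas.anterior
        denominator = atlas.posterior
        excl = (default_exclusions(atlas) if excluded_regions is None
                else list(excluded_regions))
        weights = compute_region_weights(
            cohort, numerator, denominator, positive_group, contrast_group,
            reference_group, excluded_regions=excl)
    elif index_type == "ASI":
        numerator = atlas.anterior_hemi("left")
        denominator = atlas.anterior_hemi("right")
        excl = [] if excluded_regions is None else list(excluded_regions)
        # both hemispheres carry *anterior-side* weights: atrophy lowers them
        weights = compute_region_weights(
            cohort, numerator + denominator, [], positive_group, contrast_group,
            reference_group, excluded_regions=excl)
        if asi_weight_mode == "anterior_contrast":
            weights = symmetrize_weights(weights, atlas)
        elif asi_weight_mode != "independent":
            raise ValueError(f"unknown asi_weight_mode {asi_weight_mode!r}")
    elif index_type == "TPL":
        numerator = [find_left_temporal_pole(atlas)]
        denominator = []
        excl = []
        weights = {numerator[0]: 1.0}
    else:
        raise ValueError(f"unknown index type {index_type!r}")

    model = IndexModel(index_type, list(numerator), list(denominator),
                       weights, excl, cutoff=cutoff,
                       two_sided=bool(two_sided) if two_sided is not None
                       else (index_type == "ASI"))
    if all(w == 0 for w in model.weights.values()):
        raise ValueError(f"all {index_type} weights are zero; cannot form the index")
    ref = cohort.subset(cohort.mask(reference_group))
    model.mu, model.sigma = calibrate_zscore(_raw_values(ref, model))
    return model


# ---------------------------------------------------------------------------
# single-region screening

def screen_single_regions(cohort: Cohort,
                          positive_group: Sequence[str],
                          negative_group: Sequence[str]) -> pd.DataFrame:
    """Rank every atlas region by its AUC as a standalone atrophy marker.

    The score is the negated (normalized) volume, so a smaller volume in
    the positive group maps to a larger AUC.  Ties in AUC are broken
    alphabetically by region name.
    """
    pos_mask = cohort.mask(positive_group)
    neg_mask = cohort.mask(negative_group)
    if not pos_mask.any() or not neg_mask.any():
        raise ValueError("both screening groups must be non-empty")
    sel = pos_mask | neg_mask
    y = pos_mask[sel].astype(int)
    rows = []
    for r in cohort.atlas.names:
        v = cohort.data.loc[sel, r].to_numpy(dtype=float)
        rows.append((r, float(roc_auc_score(y, -v))))
    tab = pd.DataFrame(rows, columns=["region", "auc"])
    return (tab.sort_values(["auc", "region"], ascending=[False, True])
               .reset_index(drop=True))
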