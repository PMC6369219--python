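"""Region taxonomy and tabular I/O for atlases, cohorts and fitted models.

The atlas is the single source of truth for the anterior/posterior and
left/right partitions that the atrophy indices are built on: *anterior*
means cortical frontal or temporal, *posterior* means cortical parietal
or occipital.  Midline and non-cortical regions belong to neither
partition.  All operations are atlas-agnostic so volume tables from any
segmentation tool can be used, provided the region names line up.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

SCHEMA_VERSION = 1

DIAGNOSES = ("SCD", "MCI", "AD", "VaD", "DLB", "Other", "FTD")
FTD_SUBTYPES = ("bvFTD", "svPPA", "nfvPPA", "rtvFTD", "FTD_MND")
HEMISPHERES = ("left", "right", "midline")
LOBES = ("frontal", "temporal", "parietal", "occipital", "subcortical_or_other")
SEXES = ("female", "male")
FIELD_STRENGTHS = (1.0, 1.5, 3.0)

#: demographic / metadata columns of a cohort table, in canonical order
META_COLUMNS = ("subject_id", "diagnosis", "ftd_subtype", "age", "sex", "tiv", "field_strength")


class AtlasValidationError(ValueError):
    """Malformed atlas definition (duplicate names, unknown tokens...)."""


class CohortValidationError(ValueError):
    """Cohort table violates the atlas contract or record invariants."""


class IncompatibleModelError(ValueError):
    """A serialized model cannot be applied to the given atlas/cohort."""


@dataclass(frozen=True)
class RegionDef:
    name: str
    hemisphere: str  # left | right | midline
    lobe: str        # frontal | temporal | parietal | occipital | subcortical_or_other
    cortical: bool


@dataclass(frozen=True)
class RegionAtlas:
    """An ordered collection of region definitions with derived partitions."""

    regions: tuple[RegionDef, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.regions:
            if not r.name:
                raise AtlasValidationError("empty region name")
            if r.name in seen:
                raise AtlasValidationError(f"duplicate region name: {r.name!r}")
            seen.add(r.name)
            if r.hemisphere not in HEMISPHERES:
                raise AtlasValidationError(
                    f"region {r.name!r}: unknown hemisphere {r.hemisphere!r}")
            if r.lobe not in LOBES:
                raise AtlasValidationError(f"region {r.name!r}: unknown lobe {r.lobe!r}")

    # -- basic accessors -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def __len__(self) -> int:
        return len(self.regions)

    def __contains__(self, name: str) -> bool:
        return any(r.name == name for r in self.regions)

    def select(self, *, hemisphere: str | None = None, lobe: str | None = None,
               lobes: Iterable[str] | None = None,
               cortical: bool | None = None) -> list[str]:
        lobeset = set(lobes) if lobes is not None else None
        out = []
        for r in self.regions:
            if hemisphere is not None and r.hemisphere != hemisphere:
                continue
            if lobe is not None and r.lobe != lobe:
                continue
            if lobeset is not None and r.lobe not in lobeset:
                continue
            if cortical is not None and r.cortical != cortical:
                continue
            out.append(r.name)
        return out

    # -- derived partitions ----------------------------------------------
    @property
    def anterior(self) -> list[str]:
        """Cortical frontal+temporal regions (the FTD-vulnerable territory)."""
        return self.select(lobes=("frontal", "temporal"), cortical=True)

    @property
    def posterior(self) -> list[str]:
        """Cortical parietal+occipital regions (relatively spared in FTD)."""
        return self.select(lobes=("parietal", "occipital"), cortical=True)

    def anterior_hemi(self, hemisphere: str) -> list[str]:
        return self.select(lobes=("frontal", "temporal"), cortical=True,
                           hemisphere=hemisphere)

    @property
    def cortical_names(self) -> list[str]:
        return self.select(cortical=True)

    def mirror_pairs(self) -> dict[str, str]:
        """Map each lateralized region to its contralateral homologue.

        Pairing is by name identity after stripping a hemisphere marker
        (``l_``/``r_``, ``left_``/``right_`` prefixes or ``_l``/``_r``,
        ``_left``/``_right`` suffixes, case-insensitive).  Regions without
        a recognizable homologue are omitted.
        """
        def stem(name: str, hemi: str) -> str | None:
            tokens = ("l", "left") if hemi == "left" else ("r", "right")
            low = name.lower()
            for t in tokens:
                if low.startswith(t + "_"):
                    return name[len(t) + 1:]
                if low.endswith("_" + t):
                    return name[: -(len(t) + 1)]
            return None

        by_stem: dict[tuple[str, str], str] = {}
        for r in self.regions:
            if r.hemisphere in ("left", "right"):
                s = stem(r.name, r.hemisphere)
                if s is not None:
                    by_stem[(s, r.hemisphere)] = r.name
        pairs: dict[str, str] = {}
        for (s, hemi), name in by_stem.items():
            other = by_stem.get((s, "right" if hemi == "left" else "left"))
            if other is not None:
                pairs[name] = other
        return pairs

    def find(self, pattern: str) -> list[str]:
        """Region names matching a substring-or-regex ``pattern``."""
        rx = re.compile(pattern)
        return [n for n in self.names if rx.search(n)]


def default_atlas() -> RegionAtlas:
    """The bundled 133-region atlas (102 cortical, 31 non-cortical)."""
    path = importlib.resources.files("ftdindex.data") / "default_atlas.csv"
    with importlib.resources.as_file(path) as p:
        return read_atlas(p)


# ---------------------------------------------------------------------------
# atlas I/O

_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_atlas(path) -> RegionAtlas:
    """Read an atlas from CSV/TSV with columns name,hemisphere,lobe,cortical."""
    with open(path, newline="") as fh:
        first = fh.readline()
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        required = {"name", "hemisphere", "lobe", "cortical"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise AtlasValidationError(
                f"atlas file must have columns {sorted(required)}; "
                f"got {reader.fieldnames}")
        regions = []
        for i, row in enumerate(reader, start=2):
            cort = _BOOL.get(str(row["cortical"]).strip().lower())
            if cort is None:
                raise AtlasValidationError(
                    f"row {i}: cortical flag {row['cortical']!r} is not boolean")
            hemi = row["hemisphere"].strip()
            lobe = row["lobe"].strip()
            if hemi not in HEMISPHERES:
                raise AtlasValidationError(f"row {i}: unknown hemisphere {hemi!r}")
            if lobe not in LOBES:
                raise AtlasValidationError(f"row {i}: unknown lobe {lobe!r}")
            regions.append(RegionDef(row["name"].strip(), hemi, lobe, cort))
    return RegionAtlas(tuple(regions))


def write_atlas(atlas: RegionAtlas, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "hemisphere", "lobe", "cortical"])
        for r in atlas.regions:
            w.writerow([r.name, r.hemisphere, r.lobe, "true" if r.cortical else "false"])


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class Cohort:
    """Subjects x (demographics + regional volumes in ml).

    ``data`` holds one row per subject with the ``META_COLUMNS`` followed by
    one column per atlas region.  Row order is meaningful and preserved by
    all I/O.
    """

    atlas: RegionAtlas
    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        for col in META_COLUMNS:
            if col not in df.columns:
                raise CohortValidationError(f"missing column {col!r}")
        missing = [n for n in self.atlas.names if n not in df.columns]
        if missing:
            raise CohortValidationError(
                f"cohort table missing region columns: {missing}")
        if df["subject_id"].duplicated().any():
            dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise CohortValidationError(f"duplicate subject ids: {dups}")
        bad_dx = set(df["diagnosis"]) - set(DIAGNOSES)
        if bad_dx:
            raise CohortValidationError(f"unknown diagnosis labels: {sorted(bad_dx)}")
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise CohortValidationError(f"unknown sex labels: {sorted(bad_sex)}")
        if (df["tiv"] <= 0).any():
            who = df.loc[df["tiv"] <= 0, "subject_id"].tolist()
            raise CohortValidationError(f"non-positive TIV for subjects: {who}")
        if (df["age"] <= 0).any():
            who = df.loc[df["age"] <= 0, "subject_id"].tolist()
            raise CohortValidationError(f"non-positive age for subjects: {who}")
        vol = df[self.atlas.names]
        if vol.isna().any().any():
            cells = [(df.loc[idx, "subject_id"], col)
                     for idx, col in vol.isna().stack().loc[lambda s: s].index]
            raise CohortValidationError(f"missing volumes at (subject, region): {cells[:10]}")
        # subtype iff FTD
        is_ftd = df["diagnosis"] == "FTD"
        has_sub = df["ftd_subtype"].notna() & (df["ftd_subtype"] != "")
        if (has_sub & ~is_ftd).any():
            who = df.loc[has_sub & ~is_ftd, "subject_id"].tolist()
            raise CohortValidationError(f"ftd_subtype set for non-FTD subjects: {who}")
        if (is_ftd & ~has_sub).any():
            who = df.loc[is_ftd & ~has_sub, "subject_id"].tolist()
            warnings.warn(f"FTD subjects without subtype (recorded as absent): {who}",
                          stacklevel=2)
        bad_sub = set(df.loc[has_sub, "ftd_subtype"]) - set(FTD_SUBTYPES)
        if bad_sub:
            raise CohortValidationError(f"unknown FTD subtypes: {sorted(bad_sub)}")

    # -- accessors --------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def volumes(self) -> pd.DataFrame:
        """Region-volume block, indexed by subject_id (row order preserved)."""
        v = self.data[self.atlas.names].copy()
        v.index = pd.Index(self.data["subject_id"], name="subject_id")
        return v

    def labels(self) -> pd.Series:
        """Per-subject label: FTD subtype where present, else diagnosis."""
        lab = self.data["diagnosis"].copy()
        has_sub = self.data["ftd_subtype"].notna() & (self.data["ftd_subtype"] != "")
        lab[has_sub] = self.data.loc[has_sub, "ftd_subtype"]
        lab.index = pd.Index(self.data["subject_id"], name="subject_id")
        return lab

    def mask(self, groups: Sequence[str]) -> pd.Series:
        """Boolean row mask for subjects whose diagnosis OR subtype is in ``groups``."""
        groups = set(groups)
        m = self.data["diagnosis"].isin(groups) | self.data["ftd_subtype"].isin(groups)
        return m.to_numpy()

    def subset(self, mask) -> "Cohort":
        return Cohort(self.atlas, self.data.loc[mask].reset_index(drop=True),
                      dict(self.provenance))

    def with_volumes(self, volumes: pd.DataFrame, note: str | None = None) -> "Cohort":
        """Copy of the cohort with the region block replaced (same subjects)."""
        df = self.data.copy()
        df[self.atlas.names] = volumes[self.atlas.names].to_numpy()
        prov = dict(self.provenance)
        if note:
            prov["note"] = note
        return Cohort(self.atlas, df, prov)


def read_cohort(volumes_path, atlas: RegionAtlas) -> Cohort:
    """Read a cohort volume table (CSV/TSV) validated against ``atlas``."""
    with open(volumes_path, newline="") as fh:
        delim = _sniff_delimiter(fh.readline())
    df = pd.read_csv(volumes_path, sep=delim, dtype={"subject_id": str})
    for col in META_COLUMNS:
        if col not in df.columns:
            raise CohortValidationError(f"cohort file missing column {col!r}")
    missing = [n for n in atlas.names if n not in df.columns]
    if missing:
        raise CohortValidationError(f"cohort file missing region columns: {missing}")
    for name in atlas.names:
        coerced = pd.to_numeric(df[name], errors="coerce")
        bad = coerced.isna() & df[name].notna()
        if bad.any():
            idx = bad.idxmax()
            raise CohortValidationError(
                f"non-numeric volume at subject {df.loc[idx, 'subject_id']!r}, "
                f"region {name!r}: {df.loc[idx, name]!r}")
        df[name] = coerced
    if "ftd_subtype" in df.columns:
        df["ftd_subtype"] = df["ftd_subtype"].replace({"": None})
    if "field_strength" in df.columns:
        df["field_strength"] = pd.to_numeric(df["field_strength"], errors="coerce")
    return Cohort(atlas, df)


def write_cohort(cohort: Cohort, path) -> None:
    cols = list(META_COLUMNS) + cohort.atlas.names
    cohort.data[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model serialization (JSON-style, self-describing)

def write_model(model, path) -> None:
    """Serialize a fitted NormalizationModel or IndexModel losslessly."""
    payload = model.to_dict()
    payload["schema_version"] = SCHEMA_VERSION
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_model(path):
    """Load a model written by :func:`write_model` (type is self-described)."""
    # local imports avoid a cycle: the model classes live with their logic
    from .normalization import NormalizationModel
    from .indices import IndexModel

    with open(path) as fh:
        payload = json.load(fh)
    version = payload.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise IncompatibleModelError(
            f"unsupported model schema version {version!r} (expected {SCHEMA_VERSION})")
    kind = payload.get("model_type")
    if kind == "normalization":
        return NormalizationModel.from_dict(payload)
    if kind == "index":
        return IndexModel.from_dict(payload)
    raise IncompatibleModelError(f"unknown model_type {kind!r}")
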