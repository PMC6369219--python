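"""Atrophy-subtype analysis of the bvFTD group.

bvFTD is anatomically heterogeneous: roughly half of the cases lack the
pronounced cortical frontotemporal pattern that the API is built to
detect and instead show predominantly subcortical atrophy.  This module
clusters bvFTD subjects on z-standardized regional gray-matter volumes
(Ward hierarchical agglomeration by default, cut at k=4), characterizes
each cluster against reference groups with FDR-corrected region-wise
Welch contrasts, and cross-tabulates cluster membership against the API
cutoff to show which anatomical subtype escapes the index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from statsmodels.stats.multitest import multipletests

from .atlas_io import Cohort, RegionAtlas

LINKAGES = ("ward", "complete", "average")

#: default 18-ROI panel spanning frontal, temporal, insular and
#: subcortical territory of the bundled atlas
DEFAULT_ROI_SET = (
    "l_superior_frontal_gyrus", "r_superior_frontal_gyrus",
    "l_middle_frontal_gyrus", "r_middle_frontal_gyrus",
    "l_anterior_cingulate_gyrus", "r_anterior_cingulate_gyrus",
    "l_temporal_pole", "r_temporal_pole",
    "l_superior_temporal_gyrus", "r_superior_temporal_gyrus",
    "l_anterior_insula", "r_anterior_insula",
    "l_thalamus", "r_thalamus",
    "l_caudate_nucleus", "r_caudate_nucleus",
    "l_putamen", "r_putamen",
)


@dataclass
class ClusterResult:
    roi_set: list[str]
    linkage_tree: np.ndarray                 # scipy linkage matrix
    assignments: pd.Series                   # subject_id -> cluster in 1..k
    merge_heights: list[float]               # last merge heights, for choosing k
    contrasts: pd.DataFrame | None = None
    api_crosstab: pd.DataFrame | None = None

    @property
    def k(self) -> int:
        return int(self.assignments.max())


def default_roi_set(atlas: RegionAtlas) -> list[str]:
    rois = [r for r in DEFAULT_ROI_SET if r in atlas]
    if len(rois) < len(DEFAULT_ROI_SET):
        missing = sorted(set(DEFAULT_ROI_SET) - set(rois))
        raise ValueError(f"atlas lacks default ROI regions: {missing}; "
                         "pass roi_set explicitly")
    return rois


def _standardize(volumes: pd.DataFrame,
                 reference: pd.DataFrame | None) -> pd.DataFrame:
    """Per-region z against a reference group (or internally if None)."""
    base = reference if reference is not None else volumes
    mu = base.mean(axis=0)
    sd = base.std(axis=0, ddof=1).replace(0.0, 1.0)
    return (volumes - mu) / sd


def cluster_subjects(cohort: Cohort,
                     roi_set: Sequence[str] | None = None,
                     k: int = 4,
                     linkage: str = "ward",
                     reference: Cohort | None = None) -> ClusterResult:
    """Agglomerative clustering of the cohort on standardized ROI volumes.

    ROI volumes are z-standardized per region against ``reference`` (e.g.
    an SCD group) or internally when no reference is given, then merged
    with the requested linkage (Ward/Euclidean by default) and the tree
    cut at ``k``.  Cluster labels are renumbered by decreasing mean
    atrophy: cluster 1 has the lowest (most atrophic) mean ROI z-score.
    The result is deterministic and invariant to subject order.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    rois = list(roi_set) if roi_set is not None else default_roi_set(cohort.atlas)
    missing = [r for r in rois if r not in cohort.atlas]
    if missing:
        raise ValueError(f"roi_set regions absent from atlas: {missing}")
    n = len(cohort)
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside 1..{n}")

    vols = cohort.volumes[rois]
    ref_vols = reference.volumes[rois] if reference is not None else None
    z = _standardize(vols, ref_vols)

    # sort rows by subject_id so the merge order, and hence the partition,
    # cannot depend on the row order of the input table
    z = z.sort_index()
    tree = scipy_linkage(z.to_numpy(), method=linkage, metric="euclidean")
    raw = fcluster(tree, t=k, criterion="maxclust")

    mean_z = pd.Series(z.to_numpy().mean(axis=1), index=z.index)
    order = (mean_z.groupby(raw).mean().sort_values().index.tolist())
    relabel = {old: new for new, old in enumerate(order, start=1)}
    labels = pd.Series([relabel[c] for c in raw], index=z.index, name="cluster")
    labels = labels.loc[cohort.volumes.index]     # restore cohort row order

    heights = tree[:, 2][-min(10, len(tree)):].tolist()
    return ClusterResult(rois, tree, labels, heights)


def contrast_cluster_vs_reference(cluster_cohort: Cohort,
                                  reference_cohort: Cohort,
                                  regions: Sequence[str] | None = None,
                                  fdr_q: float = 0.05) -> pd.DataFrame:
    """Region-wise Welch contrasts of a cluster against a reference group.

    Returns one row per region with the effect direction ("atrophic" when
    the cluster mean is below the reference mean), the Welch p-value, the
    Benjamini-Hochberg q-value across the region set, and a significance
    flag at ``q < fdr_q``.
    """
    if len(cluster_cohort) < 2 or len(reference_cohort) < 2:
        raise ValueError("both groups need >= 2 subjects")
    regions = list(regions) if regions is not None else cluster_cohort.atlas.names
    a = cluster_cohort.data[regions].to_numpy(dtype=float)
    b = reference_cohort.data[regions].to_numpy(dtype=float)
    with warnings.catch_warnings():
        # degenerate (zero-variance) regions are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    zero_var = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    note = np.where(zero_var, "zero variance in both groups", "")
    p = np.where(np.isnan(p), 1.0, p)
    _, q, *_ = multipletests(p, method="fdr_bh")
    direction = np.where(a.mean(axis=0) < b.mean(axis=0), "atrophic", "preserved")
    return pd.DataFrame({
        "region": regions, "direction": direction,
        "p": p, "q": q, "significant": q < fdr_q, "note": note,
    })


def crosstab_api(assignments: pd.Series, api_scores: pd.Series,
                 cutoff: float = -1.65) -> pd.DataFrame:
    """Per-cluster counts of subjects below vs at-or-above the API cutoff.

    ``share_of_above`` is each cluster's share of *all* at-or-above-cutoff
    subjects — the quantity showing where the API-negative cases live.
    """
    missing = [s for s in assignments.index if s not in api_scores.index]
    if missing:
        raise ValueError(f"missing API scores for subjects: {missing[:5]}")
    z = api_scores.loc[assignments.index]
    below = z < cutoff
    tab = pd.DataFrame({"cluster": assignments.to_numpy(), "below": below.to_numpy()})
    out = (tab.groupby("cluster")["below"]
           .agg(n_below="sum", n_total="count").reset_index())
    out["n_at_or_above"] = out["n_total"] - out["n_below"]
    total_above = int(out["n_at_or_above"].sum())
    out["share_of_above"] = (out["n_at_or_above"] / total_above
                             if total_above else 0.0)
    return out[["cluster", "n_below", "n_at_or_above", "n_total", "share_of_above"]]


def analyze_subtypes(cohort: Cohort, *,
                     group: str = "bvFTD",
                     reference_groups: Sequence[str] = ("SCD", "AD"),
                     api_scores: pd.Series | None = None,
                     roi_set: Sequence[str] | None = None,
                     k: int = 4, linkage: str = "ward",
                     standardize_against: str | None = "SCD",
                     fdr_q: float = 0.05,
                     cutoff: float = -1.65) -> ClusterResult:
    """End-to-end subtype analysis on a normalized cohort.

    Clusters the ``group`` subjects, contrasts every cluster against each
    reference group with FDR correction, and (when API z-scores are
    supplied) cross-tabulates clusters against the API cutoff.
    """
    grp = cohort.subset(cohort.mask((group,)))
    ref_std = (cohort.subset(cohort.mask((standardize_against,)))
               if standardize_against else None)
    result = cluster_subjects(grp, roi_set, k, linkage, reference=ref_std)

    frames = []
    for ref_name in reference_groups:
        ref = cohort.subset(cohort.mask((ref_name,)))
        for c in sorted(result.assignments.unique()):
            ids = result.assignments[result.assignments == c].index
            sub = grp.subset(grp.data["subject_id"].isin(ids).to_numpy())
            tab = contrast_cluster_vs_reference(sub, ref, result.roi_set, fdr_q)
            tab.insert(0, "reference", ref_name)
            tab.insert(0, "cluster", c)
            frames.append(tab)
    result.contrasts = pd.concat(frames, ignore_index=True)

    if api_scores is not None:
        result.api_crosstab = crosstab_api(result.assignments, api_scores, cutoff)
    return result
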