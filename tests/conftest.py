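import numpy as np
import pandas as pd
import pytest

import ftdindex as fi


@pytest.fixture(scope="session")
def atlas():
    return fi.default_atlas()


def make_tiny_atlas():
    """A minimal atlas exercising every partition (10 regions)."""
    rows = [
        ("l_frontal_a", "left", "frontal", True),
        ("r_frontal_a", "right", "frontal", True),
        ("l_temporal_pole", "left", "temporal", True),
        ("r_temporal_pole", "right", "temporal", True),
        ("l_parietal_a", "left", "parietal", True),
        ("r_parietal_a", "right", "parietal", True),
        ("l_occipital_a", "left", "occipital", True),
        ("r_occipital_a", "right", "occipital", True),
        ("l_hippocampus", "left", "subcortical_or_other", False),
        ("brainstem", "midline", "subcortical_or_other", False),
    ]
    return fi.RegionAtlas(tuple(fi.RegionDef(*r) for r in rows))


@pytest.fixture(scope="session")
def tiny_atlas():
    return make_tiny_atlas()


def make_cohort(atlas, n=12, seed=0, diagnoses=None, base=10.0, noise=0.5,
                volume_overrides=None):
    """Hand-rolled small cohort with N(base, noise) volumes."""
    rng = np.random.default_rng(seed)
    diagnoses = diagnoses if diagnoses is not None else \
        [["SCD", "AD", "FTD"][i % 3] for i in range(n)]
    rows = []
    for i, dx in enumerate(diagnoses):
        rows.append({
            "subject_id": f"T{i:03d}",
            "diagnosis": dx,
            "ftd_subtype": "bvFTD" if dx == "FTD" else None,
            "age": float(55 + (i % 20)),
            "sex": "female" if i % 2 else "male",
            "tiv": 1500.0,
            "field_strength": 1.5,
            **{name: float(base + noise * rng.standard_normal())
               for name in atlas.names},
        })
    df = pd.DataFrame(rows)
    if volume_overrides:
        for (sid, region), value in volume_overrides.items():
            df.loc[df["subject_id"] == sid, region] = value
    return fi.Cohort(atlas, df)


@pytest.fixture(scope="session")
def default_cohort():
    """Synthetic cohort with the default (ADC+PredictND-style) case mix."""
    return fi.generate_cohort(fi.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def normalized_cohort(default_cohort):
    model = fi.fit_normalization(default_cohort)
    return fi.apply_normalization(model, default_cohort)


def auc_pairwise(pos_scores, neg_scores):
    """Brute-force AUC oracle for lower-is-positive scores.

    Mean over all (pos, neg) pairs of 1 if the positive scores lower,
    0.5 on ties, else 0.
    """
    total = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p < n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos_scores) * len(neg_scores))
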