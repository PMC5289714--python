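"""Shared fixtures: small synthetic cohorts and derived feature matrices.

Simulation sizes here are deliberately compact (seconds of signal, not the
full 5-minute protocol) so the suite exercises every stage end-to-end while
staying fast; statistical assertions use seeded Monte Carlo.
"""

import numpy as np
import pandas as pd
import pytest

from eegresp import (CohortSpec, FeatureMatrix, fit_reference, generate_cohort,
                     standardize)
from eegresp.pipeline import build_feature_matrix
from eegresp.preprocessing import PreprocessConfig, preprocess_recording


@pytest.fixture(scope="session")
def small_cohort():
    """12 patients + 4 controls, 8 s per condition."""
    spec = CohortSpec(n_patients=12, n_controls=4, duration_per_condition=8.0,
                      seed=42)
    recs, meta = generate_cohort(spec)
    return spec, recs, meta


@pytest.fixture(scope="session")
def cohort_features():
    """Standardized wavelet feature matrix of a full-size (n=34) cohort."""
    spec = CohortSpec(n_patients=34, n_controls=4, duration_per_condition=10.0,
                      seed=7)
    recs, _ = generate_cohort(spec)
    cfg = PreprocessConfig(epoch_length=8.0)
    clean = [preprocess_recording(r, cfg) for r in recs]
    patients = build_feature_matrix([r for r in clean if r.group != "control"])
    controls = build_feature_matrix([r for r in clean if r.group == "control"])
    return standardize(patients, fit_reference(controls))


def gaussian_feature_matrix(rng, n_subjects=34, n_features=30, shift=0.0,
                            shifted_cols=(), n_pos=None):
    """Plain Gaussian FeatureMatrix with EC/EO duplicated instances."""
    n_pos = n_subjects // 2 if n_pos is None else n_pos
    base = rng.standard_normal((n_subjects, n_features))
    groups = np.array(["R"] * n_pos + ["NR"] * (n_subjects - n_pos))
    for c in shifted_cols:
        base[groups == "R", c] += shift
    values = np.vstack([base, base + 0.05 * rng.standard_normal(base.shape)])
    inst = pd.DataFrame(dict(
        subject_id=[f"S{i:02d}" for i in range(n_subjects)] * 2,
        condition=["EC"] * n_subjects + ["EO"] * n_subjects,
        group=np.concatenate([groups, groups]),
        sex=(["F", "M"] * n_subjects)[:n_subjects] * 2,
    ))
    meta = pd.DataFrame(dict(channel=["C3"] * n_features,
                             band=["delta"] * n_features,
                             method=["synthetic"] * n_features,
                             index=range(n_features)))
    return FeatureMatrix(values, meta, inst)
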