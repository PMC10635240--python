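"""Shared fixtures-by-hand for classifier and acceptance tests."""

import numpy as np

from chromascan import FeatureMatrix


def make_feature_cohort(n_per_class, effect, nuclei_per_patient=5, n_features=12, seed=0):
    """Per-nucleus features with a patient-level class shift in a correlated
    block of four features (as texture features co-vary in real images)."""
    rng = np.random.default_rng(seed)
    rows, ids, labels = [], [], {}
    for cls in (0, 1):
        for i in range(n_per_class):
            pid = f"c{cls}-{i}"
            labels[pid] = cls
            center = rng.normal(cls * effect, 1.0)
            for j in range(nuclei_per_patient):
                vec = rng.normal(0, 1, n_features)
                vec[:4] += center + rng.normal(0, 0.3)
                rows.append(vec)
                ids.append((pid, j))
    return FeatureMatrix(np.array(rows), ids, [f"f{k}" for k in range(n_features)]), labels
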