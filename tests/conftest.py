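import numpy as np
import pandas as pd
import pytest

from muscleomics import OmicsMatrix


def make_matrix(values: np.ndarray, sex: str = "M", n_replicates: int = 3,
                feature_prefix: str = "F") -> OmicsMatrix:
    """Wrap a (features x 18) array as an OmicsMatrix with full metadata."""
    n_features, n_samples = values.shape
    sample_ids, genos, times, reps = [], [], [], []
    for g in ("WT", "KI"):
        for t in ("SED", "T10", "EXH"):
            for r in range(n_replicates):
                sample_ids.append(f"{sex}_{g}_{t}_r{r + 1}")
                genos.append(g)
                times.append(t)
                reps.append(r + 1)
    assert len(sample_ids) == n_samples
    meta = pd.DataFrame(
        {"sex": sex, "genotype": genos, "timepoint": times, "replicate": reps},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    features = pd.Index([f"{feature_prefix}{i:04d}" for i in range(n_features)],
                        name="feature_id")
    return OmicsMatrix(pd.DataFrame(values, index=features, columns=sample_ids), meta)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(rng):
    """Random complete 50-feature matrix over the full 2x3x3 design."""
    return make_matrix(rng.normal(20.0, 1.0, size=(50, 18)))
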