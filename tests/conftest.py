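import numpy as np
import pytest

from facematch import CohortSpec, Facebase, GeneratorConfig, ImageRecord


def make_facebase(spec, embeddings=None):
    """Build a Facebase from (image_id, individual_id, cohort[, stage]) tuples."""
    records = []
    for row in spec:
        image_id, individual_id, cohort = row[:3]
        stage = row[3] if len(row) > 3 else 1
        records.append(ImageRecord(image_id, individual_id, cohort, stage))
    if embeddings is not None:
        embeddings = np.asarray(embeddings, dtype=float)
    return Facebase(records, embeddings)


@pytest.fixture
def tiny_fb():
    """3 images, 2 cohorts: geometry forces the ranking [B1, C1] for test A1."""
    return make_facebase(
        [("A1", "a", "W"), ("B1", "b", "W"), ("C1", "c", "CONTROL")],
        embeddings=[[1.0, 0.0], [0.995, 0.0999], [0.0, 1.0]],
    )


def random_generator_config(rng, max_images=100):
    """A small random synthetic config for oracle-equivalence checks."""
    n_cohorts = int(rng.integers(1, 4))
    budget = int(rng.integers(10, max_images))
    cohorts = []
    for i in range(n_cohorts):
        n = int(rng.integers(2, max(3, budget // (2 * n_cohorts))))
        cohorts.append(
            CohortSpec(
                f"S{i}",
                n_images=n,
                multi_image_fraction=float(rng.uniform(0, 0.4)),
            )
        )
    n_controls = max(0, budget - sum(c.n_images for c in cohorts))
    return GeneratorConfig(
        cohorts=tuple(cohorts),
        n_controls=n_controls,
        d=int(rng.integers(2, 9)),
        sigma_b=float(rng.uniform(0, 2)),
        sigma_w=float(rng.uniform(0.1, 1)),
        sigma_e=float(rng.uniform(0.1, 1)),
        seed=int(rng.integers(0, 2**31)),
    )
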