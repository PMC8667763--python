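import numpy as np
import pandas as pd
import pytest

import mhladr_endotypes as m

#: Published day-1 / day-6 anchor means (AB/C) per endotype.
ANCHORS = {
    "Non-improvers": (3265.0, 3865.0),
    "Decliners": (31774.0, 10785.0),
    "Improvers": (6331.0, 9787.0),
    "High expressors": (9681.0, 28604.0),
}


@pytest.fixture(scope="session")
def aggregated_run():
    """Full pipeline run on the default synthetic aggregated cohort.

    Shared by the clustering-recovery, proportion, and assignment-quality
    tests so the 100-restart clustering only runs once.
    """
    cfg = m.default_config("aggregated", seed=42)
    traj, labels = m.simulate_trajectories(cfg)
    clean = m.clean_trajectories(traj)
    cohort = m.TrajectoryCohort.from_long(clean.data)
    partition = m.kmeans_longitudinal(cohort, k=4, n_restarts=100, seed=43)
    centers_abc = clean.transform.inverse(partition.centers)
    partition.names = m.name_endotypes(centers_abc)
    return {
        "config": cfg,
        "trajectories": traj,
        "labels": labels,
        "clean": clean,
        "cohort": cohort,
        "partition": partition,
        "centers_abc": centers_abc,
    }


@pytest.fixture()
def blob_cohort():
    """Complete-data cohort with two well-separated trajectory blobs."""
    rng = np.random.default_rng(5)
    a = rng.normal([0.0, 0.0, 0.0], 0.3, size=(40, 3))
    b = rng.normal([5.0, 5.0, 5.0], 0.3, size=(40, 3))
    matrix = np.vstack([a, b])
    n = matrix.shape[0]
    return m.TrajectoryCohort(
        patients=np.array([f"P{i}" for i in range(n)]),
        grid=np.array([1.5, 3.5, 6.0]),
        matrix=matrix,
        days=np.tile([1.5, 3.5, 6.0], (n, 1)),
        cohort=np.array(["all"] * n, dtype=object),
    ), np.array([0] * 40 + [1] * 40)
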