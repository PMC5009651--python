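import numpy as np
import pytest

from harman import (
    ExperimentDesign,
    ExpressionMatrix,
    SimulationConfig,
    validate_study,
)


@pytest.fixture
def toy_design():
    """Two batches x two treatments, one replicate of each per batch."""
    samples = ["a1", "a2", "b1", "b2"]
    return ExperimentDesign(
        samples,
        batch_of={"a1": "X", "a2": "Y", "b1": "X", "b2": "Y"},
        treatment_of={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
    )


@pytest.fixture
def four_batch_design():
    """Scores (-3,-1,+1,+3) style setup: two batches of two samples."""
    samples = ["s1", "s2", "s3", "s4"]
    return ExperimentDesign(
        samples,
        batch_of={"s1": "1", "s2": "1", "s3": "2", "s4": "2"},
        treatment_of={"s1": "T", "s2": "T", "s3": "T", "s4": "T"},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160901)


def random_matrix(rng, p=30, n=8, prefix=""):
    vals = rng.normal(size=(p, n))
    return ExpressionMatrix(
        vals, [f"{prefix}g{i}" for i in range(p)], [f"{prefix}s{j}" for j in range(n)]
    )


@pytest.fixture
def small_matrix(rng):
    return random_matrix(rng)


def random_design(rng, n_treat=3, max_rep=6, n_batch=None):
    """Random small design: treatments with random replicate counts split
    randomly over batches (each batch non-empty)."""
    reps = {f"T{t}": int(rng.integers(2, max_rep + 1)) for t in range(n_treat)}
    n_batch = n_batch or int(rng.integers(2, 4))
    n_batch = min(n_batch, sum(reps.values()))
    while True:
        samples, batch_of, treatment_of = [], {}, {}
        i = 0
        for t, n in reps.items():
            for _ in range(n):
                sid = f"s{i}"
                i += 1
                samples.append(sid)
                treatment_of[sid] = t
                batch_of[sid] = f"B{int(rng.integers(n_batch))}"
        if len(set(batch_of.values())) == n_batch:
            return ExperimentDesign(samples, batch_of, treatment_of)


@pytest.fixture
def null_study(rng):
    """Dataset-1-shaped synthetic study with no injected batch effect."""
    cfg = SimulationConfig(p=300, batch_sd=0.0, seed=11)
    from harman import generate_study

    matrix, design, _ = generate_study(cfg)
    return validate_study(matrix, design)


@pytest.fixture
def batchy_study():
    """Dataset-1-shaped study with a strong batch effect (3x the noise)."""
    cfg = SimulationConfig(p=300, batch_sd=0.3, noise_sd=0.1, seed=5)
    from harman import generate_study

    matrix, design, truth = generate_study(cfg)
    return validate_study(matrix, design), truth
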