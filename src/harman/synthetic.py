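"""Synthetic studies with known batch, treatment and noise structure.

The generator emulates the structure of a post-normalisation log-scale
expression study: for sample i (treatment alpha, batch j) and feature g,

    value = baseline_g + T_{alpha,g} + B_{j,g} * 1[g affected] + eps,

with treatment effects T ~ N(0, treatment_sd^2), batch offsets
B ~ N(0, batch_sd^2) constant across all samples of a batch (the
additive, batch-shared character of batch noise on the log scale), and
replicate noise eps ~ N(0, noise_sd^2) i.i.d. per cell.  A fraction of
features can be left unaffected by batch, and an optional low-rank
factor model correlates batch offsets across features, mimicking the
spatially structured "watermark" character of real batch distortion.

Every random component draws from its own named substream of a single
seed, so e.g. noise can be varied while batch offsets stay fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import ExperimentDesign, ExpressionMatrix
from .errors import ValidationError

_SUBSTREAMS = ("baseline", "treatment", "batch", "noise", "affected")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic study.

    ``treatments`` maps treatment label to its total replicate count
    n_alpha; ``batches`` maps batch label to a {treatment: k_alpha}
    composition.  Compositions must partition the replicates exactly.
    Scales are standard deviations on the log-intensity scale.
    """

    p: int = 2000
    treatments: dict[str, int] = field(
        default_factory=lambda: {f"T{a}": 4 for a in range(1, 8)}
    )
    batches: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            f"B{j}": {f"T{a}": 1 for a in range(1, 8)} for j in range(1, 5)
        }
    )
    batch_sd: float = 0.3
    treatment_sd: float = 0.2
    noise_sd: float = 0.1
    affected_fraction: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    batch_rank: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValidationError("p must be positive")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.batch_sd < 0 or self.treatment_sd < 0:
            raise ValidationError("effect scales must be non-negative")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValidationError("affected_fraction must lie in [0, 1]")
        if len(self.batches) < 2:
            raise ValidationError("need at least two batches")
        totals: dict[str, int] = {t: 0 for t in self.treatments}
        for b, comp in self.batches.items():
            for t, k in comp.items():
                if t not in self.treatments:
                    raise ValidationError(f"batch {b!r} uses unknown treatment {t!r}")
                if k < 1:
                    raise ValidationError(f"batch {b!r} has non-positive count for {t!r}")
                totals[t] += k
        if totals != dict(self.treatments):
            raise ValidationError(
                f"batch compositions {totals} do not partition the replicate "
                f"counts {dict(self.treatments)}"
            )

    @property
    def n_samples(self) -> int:
        return sum(self.treatments.values())


def dataset1_shaped(seed: int = 0, **overrides) -> SimulationConfig:
    """Balanced 7-treatment x 4-replicate study in 4 batches of 7 (one
    replicate of every treatment per batch)."""
    return SimulationConfig(seed=seed, **overrides)


@dataclass(frozen=True)
class GroundTruth:
    """The effects that went into a synthetic matrix, for recovery checks."""

    batch_offsets: np.ndarray  # b x p, zero for unaffected features
    treatment_effects: np.ndarray  # tau x p
    baseline: np.ndarray  # p
    batch_labels: list[str]
    treatment_labels: list[str]
    affected: np.ndarray  # boolean, p


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def generate_study(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExperimentDesign, GroundTruth]:
    """Draw one synthetic study; a pure function of the config (same
    config, same outputs, bit for bit)."""
    rngs = _substreams(config.seed)
    p = config.p
    t_labels = list(config.treatments)
    b_labels = list(config.batches)

    baseline = rngs["baseline"].normal(config.baseline_mean, config.baseline_sd, size=p)
    treatment_effects = rngs["treatment"].normal(
        0.0, config.treatment_sd, size=(len(t_labels), p)
    )

    affected = np.zeros(p, dtype=bool)
    n_aff = int(round(config.affected_fraction * p))
    affected[rngs["affected"].choice(p, size=n_aff, replace=False)] = True

    if config.batch_rank is not None:
        # low-rank structure: offsets share `rank` feature patterns across batches
        loadings = rngs["batch"].normal(0.0, 1.0, size=(config.batch_rank, p))
        loadings /= np.sqrt(config.batch_rank)
        factors = rngs["batch"].normal(
            0.0, config.batch_sd, size=(len(b_labels), config.batch_rank)
        )
        batch_offsets = factors @ loadings
    else:
        batch_offsets = rngs["batch"].normal(
            0.0, config.batch_sd, size=(len(b_labels), p)
        )
    batch_offsets = batch_offsets * affected[None, :]

    # assemble samples batch by batch, replicate indices per treatment
    sample_ids: list[str] = []
    batch_of: dict[str, str] = {}
    treatment_of: dict[str, str] = {}
    rows: list[np.ndarray] = []
    rep_counter = {t: 0 for t in t_labels}
    for bi, b in enumerate(b_labels):
        for t, k in config.batches[b].items():
            ti = t_labels.index(t)
            for _ in range(k):
                rep_counter[t] += 1
                sid = f"{t}_r{rep_counter[t]}"
                sample_ids.append(sid)
                batch_of[sid] = b
                treatment_of[sid] = t
                rows.append(baseline + treatment_effects[ti] + batch_offsets[bi])
    noise = rngs["noise"].normal(0.0, config.noise_sd, size=(len(rows), p))
    values = np.vstack(rows) + noise  # N x p

    matrix = ExpressionMatrix(
        values.T, [f"g{i + 1}" for i in range(p)], sample_ids
    )
    design = ExperimentDesign(sample_ids, batch_of, treatment_of)
    truth = GroundTruth(
        batch_offsets=batch_offsets,
        treatment_effects=treatment_effects,
        baseline=baseline,
        batch_labels=b_labels,
        treatment_labels=t_labels,
        affected=affected,
    )
    return matrix, design, truth


def inject_batch_effect(
    matrix: ExpressionMatrix, design: ExperimentDesign, offsets: np.ndarray
) -> ExpressionMatrix:
    """Add a constant per-(batch, feature) offset to every sample of each
    batch; within-batch sample differences are untouched."""
    offsets = np.asarray(offsets, dtype=float)
    b_labels = design.batches
    if offsets.shape != (len(b_labels), matrix.n_features):
        raise ValidationError(
            f"offsets shape {offsets.shape} does not match "
            f"({len(b_labels)} batches, {matrix.n_features} features)"
        )
    if design.sample_ids != matrix.sample_ids:
        raise ValidationError("design must be aligned to the matrix")
    batch_idx = np.array([b_labels.index(design.batch_of[s]) for s in matrix.sample_ids])
    return matrix.with_values(matrix.values + offsets[batch_idx].T)
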