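"""Core study containers: expression matrix, experiment design, validated study.

An expression matrix holds log-scale intensities for p features (rows) by
N samples (columns).  The design assigns each sample to exactly one
processing batch and one treatment group; batch labels drive the null
model of batch means, treatment labels drive the candidate-batch
combinatorics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MismatchError, ValidationError


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    dupes = [i for i in ids if i in seen or seen.add(i)]
    if dupes:
        raise ValidationError(f"duplicate {what}: {sorted(set(dupes))}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Feature-by-sample matrix of finite, log-scale values.

    Parameters
    ----------
    values : ndarray, shape (p, N)
        Log-scale intensities; must be finite.
    feature_ids : list of str
        p unique row labels (probesets, CpG sites, genes...).
    sample_ids : list of str
        N unique column labels.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "feature_ids", list(map(str, self.feature_ids)))
        object.__setattr__(self, "sample_ids", list(map(str, self.sample_ids)))
        if vals.ndim != 2:
            raise ValidationError("matrix values must be two-dimensional")
        p, n = vals.shape
        if p < 1:
            raise ValidationError("matrix must have at least one feature")
        if n < 2:
            raise ValidationError("matrix must have at least two samples")
        if len(self.feature_ids) != p or len(self.sample_ids) != n:
            raise ValidationError(
                f"label counts ({len(self.feature_ids)}, {len(self.sample_ids)}) "
                f"do not match matrix shape {vals.shape}"
            )
        _check_unique(self.feature_ids, "feature IDs")
        _check_unique(self.sample_ids, "sample IDs")
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite value at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same labels, new values (used to assemble corrected matrices)."""
        return ExpressionMatrix(values, self.feature_ids, self.sample_ids)

    def equals(self, other: "ExpressionMatrix", atol: float = 0.0) -> bool:
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values, other.values, rtol=0.0, atol=atol)
        )


@dataclass(frozen=True)
class ExperimentDesign:
    """Per-sample batch and treatment assignment.

    Labels are opaque strings; at least two non-empty batches are required
    because a single batch admits no between-batch comparison.
    """

    sample_ids: list[str]
    batch_of: dict[str, str]
    treatment_of: dict[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", list(map(str, self.sample_ids)))
        _check_unique(self.sample_ids, "sample IDs")
        missing_b = [s for s in self.sample_ids if s not in self.batch_of]
        missing_t = [s for s in self.sample_ids if s not in self.treatment_of]
        if missing_b or missing_t:
            raise ValidationError(
                f"samples lacking batch {missing_b} or treatment {missing_t}"
            )
        if len(self.batches) < 2:
            raise ValidationError("design must contain at least two batches")

    @property
    def batches(self) -> list[str]:
        """Batch labels in first-appearance order."""
        out: list[str] = []
        for s in self.sample_ids:
            b = self.batch_of[s]
            if b not in out:
                out.append(b)
        return out

    @property
    def treatments(self) -> list[str]:
        """Treatment labels in first-appearance order."""
        out: list[str] = []
        for s in self.sample_ids:
            t = self.treatment_of[s]
            if t not in out:
                out.append(t)
        return out

    def samples_in_batch(self, batch: str) -> list[str]:
        return [s for s in self.sample_ids if self.batch_of[s] == batch]

    def replicates_of(self, treatment: str) -> int:
        """n_alpha: total replicates of a treatment across the whole study."""
        return sum(1 for s in self.sample_ids if self.treatment_of[s] == treatment)

    def batch_composition(self, batch: str) -> dict[str, int]:
        """k_alpha per treatment for one batch (treatments absent are omitted)."""
        counts: dict[str, int] = {}
        for s in self.samples_in_batch(batch):
            t = self.treatment_of[s]
            counts[t] = counts.get(t, 0) + 1
        return counts

    def reordered(self, sample_ids: list[str]) -> "ExperimentDesign":
        if set(sample_ids) != set(self.sample_ids):
            raise MismatchError("cannot reorder to a different sample set")
        return ExperimentDesign(list(sample_ids), dict(self.batch_of), dict(self.treatment_of))


@dataclass(frozen=True)
class ValidatedStudy:
    """A matrix/design pair whose samples agree in identity and order."""

    matrix: ExpressionMatrix
    design: ExperimentDesign = field(repr=False)

    def __post_init__(self) -> None:
        if self.design.sample_ids != self.matrix.sample_ids:
            raise MismatchError(
                "design sample order does not match matrix columns; "
                "use validate_study() to align them"
            )


def validate_study(matrix: ExpressionMatrix, design: ExperimentDesign) -> ValidatedStudy:
    """Align a design to a matrix's column order and bundle them.

    Raises
    ------
    MismatchError
        If either input mentions samples the other lacks; the offending
        IDs are listed in the message.
    """
    m_ids, d_ids = set(matrix.sample_ids), set(design.sample_ids)
    if m_ids != d_ids:
        only_m = sorted(m_ids - d_ids)
        only_d = sorted(d_ids - m_ids)
        raise MismatchError(
            f"sample sets differ: only in matrix {only_m}, only in design {only_d}"
        )
    return ValidatedStudy(matrix, design.reordered(matrix.sample_ids))
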