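"""Null distribution of per-batch mean scores under the no-batch-effect assumption.

If batch membership carries no signal, a batch containing k_alpha of the
n_alpha replicates of each treatment alpha is just one of
prod_alpha C(n_alpha, k_alpha) equally likely candidate batches that
could have been assembled from the observed scores.  The means of all
candidate batches form a finite population whose spread quantifies how
far a real batch mean may wander from zero by sampling alone.  By the
central limit theorem — applied once when features are summed into PC
scores, and again when scores are averaged into a batch mean — that
population is well approximated by a normal with mean zero, so only its
standard deviation is needed.

Three routes to the standard deviation are provided:

``exact_enumeration``
    Build every candidate mean and take the population standard
    deviation.  Used when the candidate count is modest.
``analytic``
    Closed-form finite-population variance of a stratified
    without-replacement sample mean:
    (1/m^2) * sum_alpha k_alpha * sigma2_alpha * (n_alpha - k_alpha)/(n_alpha - 1),
    with sigma2_alpha the population variance of treatment alpha's
    scores.  Equal to the enumeration exactly, at any candidate count.
``monte_carlo``
    Sample candidate batches at random; retained as an independent
    cross-check of the other two.

From a batch mean BM and the null standard deviation, the tail
probability z = Phi(-|BM| / std) is at most 0.5 (attained at BM = 0).
The b per-batch probabilities combine into a normalized likelihood

    L = (2^(b-1) / b) * sum_i prod_{j != i} z_j,

which is 1 when every batch mean is zero and shrinks toward 0 as batch
means disperse; 1 - L is reported as the confidence that batch noise is
present.  The leave-one-out structure reflects the constraint that
centred batch means are linearly dependent (the last is fixed by the
others), and the constant makes L comparable across designs with
different numbers of batches.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Literal

import numpy as np
from scipy.stats import norm

from .datamodel import ExperimentDesign
from .errors import ValidationError

#: largest candidate population that is enumerated exhaustively
ENUMERATION_CAP = 100_000

#: floor applied to each z before forming products, so L never collapses
#: to an exact floating-point zero for extreme offsets
Z_FLOOR = 1e-300

#: reported confidences are capped just below 1
CONFIDENCE_CAP = 1.0 - 1e-15

NullMethod = Literal["exact_enumeration", "analytic", "monte_carlo"]


@dataclass(frozen=True)
class BatchComposition:
    """Treatment make-up of one batch: k_alpha replicates per treatment."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValidationError("batch composition is empty")
        for t, k in self.counts.items():
            if k < 1:
                raise ValidationError(f"treatment {t!r} has non-positive count {k}")

    @property
    def size(self) -> int:
        """m: total samples in the batch."""
        return sum(self.counts.values())

    @classmethod
    def of_batch(cls, design: ExperimentDesign, batch: str) -> "BatchComposition":
        return cls(design.batch_composition(batch))


@dataclass(frozen=True)
class BatchMeanNull:
    """Normal null for one batch composition on one component's scores.

    ``std`` is the null standard deviation of the batch mean; the mean is
    zero by construction.  ``degenerate`` marks compositions whose
    candidate means are all identical (no spread, so no probability can
    be assigned and the component is left uncorrected).
    """

    std: float
    method: NullMethod
    n_candidates: int | None = None
    mean: float = 0.0

    @property
    def degenerate(self) -> bool:
        return self.std <= 0.0


@dataclass(frozen=True)
class LikelihoodResult:
    """Normalized likelihood of an observed set of batch means under the null."""

    z_values: np.ndarray
    L: float
    confidence: float


def _treatment_scores(
    pc_scores: np.ndarray, design: ExperimentDesign
) -> dict[str, np.ndarray]:
    scores = np.asarray(pc_scores, dtype=float)
    if scores.shape != (len(design.sample_ids),):
        raise ValidationError(
            f"scores length {scores.shape} does not match design "
            f"({len(design.sample_ids)} samples)"
        )
    out: dict[str, np.ndarray] = {}
    for t in design.treatments:
        idx = [i for i, s in enumerate(design.sample_ids) if design.treatment_of[s] == t]
        out[t] = scores[idx]
    return out


def count_candidate_batches(design: ExperimentDesign, comp: BatchComposition) -> int:
    """Number of distinct candidate batches: prod_alpha C(n_alpha, k_alpha)."""
    total = 1
    for t, k in comp.counts.items():
        n = design.replicates_of(t)
        if k > n:
            raise ValidationError(
                f"batch requests {k} replicates of treatment {t!r} but the study has {n}"
            )
        total *= comb(n, k)
    return total


def enumerate_candidate_means(
    pc_scores: np.ndarray, design: ExperimentDesign, comp: BatchComposition
) -> np.ndarray:
    """Means of every candidate batch that the composition permits.

    The candidate population is the cartesian product, over treatments,
    of all k_alpha-subsets of that treatment's scores; it is built by
    convolving per-treatment subset sums, so the cost is the number of
    candidates rather than candidates x batch size.
    """
    n_cand = count_candidate_batches(design, comp)
    if n_cand > ENUMERATION_CAP:
        raise ValidationError(
            f"{n_cand} candidate batches exceed the enumeration cap "
            f"({ENUMERATION_CAP}); use the analytic or monte_carlo method"
        )
    by_treatment = _treatment_scores(pc_scores, design)
    totals = np.zeros(1)
    for t, k in comp.counts.items():
        vals = by_treatment[t]
        subset_sums = np.array([sum(c) for c in combinations(vals, k)])
        totals = np.add.outer(totals, subset_sums).ravel()
    return totals / comp.size


def null_std(
    pc_scores: np.ndarray,
    design: ExperimentDesign,
    comp: BatchComposition,
    method: Literal["auto", "exact_enumeration", "analytic", "monte_carlo"] = "auto",
    n_reps: int = 100_000,
    rng: np.random.Generator | None = None,
) -> BatchMeanNull:
    """Null standard deviation of the batch mean for one composition.

    ``auto`` enumerates exhaustively when the candidate count is within
    the cap and otherwise falls back to the (exactly equivalent) analytic
    form.  ``monte_carlo`` requires ``rng``.
    """
    n_cand = count_candidate_batches(design, comp)
    if method == "auto":
        method = "exact_enumeration" if n_cand <= ENUMERATION_CAP else "analytic"

    if method == "exact_enumeration":
        means = enumerate_candidate_means(pc_scores, design, comp)
        return BatchMeanNull(std=float(np.std(means)), method=method, n_candidates=n_cand)

    if method == "analytic":
        by_treatment = _treatment_scores(pc_scores, design)
        m = comp.size
        var = 0.0
        for t, k in comp.counts.items():
            vals = by_treatment[t]
            n = vals.size
            if k > n:
                raise ValidationError(
                    f"batch requests {k} replicates of treatment {t!r} but the study has {n}"
                )
            if n == 1:
                continue  # a single replicate contributes no sampling variance
            sigma2 = float(np.var(vals))  # population variance, denominator n
            var += k * sigma2 * (n - k) / (n - 1)
        return BatchMeanNull(std=float(np.sqrt(var)) / m, method=method, n_candidates=n_cand)

    if method == "monte_carlo":
        if rng is None:
            raise ValidationError("monte_carlo method requires an rng")
        by_treatment = _treatment_scores(pc_scores, design)
        total = np.zeros(n_reps)
        for t, k in comp.counts.items():
            vals = by_treatment[t]
            if k > vals.size:
                raise ValidationError(
                    f"batch requests {k} replicates of treatment {t!r} "
                    f"but the study has {vals.size}"
                )
            # k distinct draws per replicate via partial argsort of uniforms
            u = rng.random((n_reps, vals.size))
            idx = np.argpartition(u, k - 1, axis=1)[:, :k]
            total += vals[idx].sum(axis=1)
        means = total / comp.size
        return BatchMeanNull(std=float(np.std(means, ddof=1)), method=method, n_candidates=None)

    raise ValidationError(f"unknown null method {method!r}")


def batch_probability(batch_mean: float, null: BatchMeanNull) -> float:
    """Tail probability z = Phi(-|BM| / std); 0.5 at BM = 0, symmetric in sign."""
    if null.degenerate:
        raise ValidationError("null distribution is degenerate (zero spread)")
    z = float(norm.cdf(-abs(batch_mean) / null.std))
    return max(z, Z_FLOOR)


def likelihood(z_values: np.ndarray) -> LikelihoodResult:
    """Combine per-batch probabilities into the normalized likelihood L.

    L = (2^(b-1)/b) * sum over batches of the product of the other
    batches' z values; equals 1 when every z is at its maximum of 0.5.
    Strictly increasing in each z, so shrinking batch means can only
    raise L (lower the confidence of a batch effect).
    """
    z = np.asarray(z_values, dtype=float)
    b = z.size
    if b < 2:
        raise ValidationError("likelihood needs at least two batches")
    if np.any(z <= 0.0) or np.any(z > 0.5):
        raise ValidationError(f"z values must lie in (0, 0.5], got {z}")
    z = np.maximum(z, Z_FLOOR)
    # leave-one-out products via prefix/suffix partial products (no division)
    prefix = np.concatenate(([1.0], np.cumprod(z[:-1])))
    suffix = np.concatenate((np.cumprod(z[::-1])[-2::-1], [1.0]))
    loo = prefix * suffix
    L = float(2.0 ** (b - 1) / b * loo.sum())
    L = min(max(L, Z_FLOOR), 1.0)  # products may underflow even after the z floor
    confidence = min(1.0 - L, CONFIDENCE_CAP)
    return LikelihoodResult(z_values=z, L=L, confidence=confidence)
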