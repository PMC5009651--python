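"""Metrics for scoring a correction: guided-PCA detection, variance partition,
preserved variance.

The guided-PCA (gPCA) statistic asks how much of the data's leading
variance is aligned with batch membership: the batch-indicator matrix Y
summarises the feature-centred data X into per-batch sums Y'X, whose
first right singular vector defines a "guided" axis; delta is the
variance of the samples projected on that axis divided by the variance
along the first unguided principal axis.  Delta near 1 means the
dominant direction of variation separates batches.  Significance comes
from permuting batch labels over samples.

The variance partition is an ANOVA-style decomposition of each feature's
centred sum of squares into a batch-mean component, a treatment-mean
component computed after batch means are removed, and a residual,
averaged over features.  Removing batch means first deliberately
attributes all batch-attributable variance to batch; on balanced designs
the order is immaterial.

Preserved variance is the fraction of the raw matrix's total
feature-centred variance that survives correction — the
signal-preservation axis of a noise-rejection/signal-preservation
trade-off plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ExperimentDesign, ExpressionMatrix
from .errors import DegenerateInputError, ValidationError


@dataclass(frozen=True)
class GPCAResult:
    delta: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class VariancePartition:
    """Per-feature-averaged variance components, in squared matrix units.

    ``confounded`` flags designs where every treatment lies wholly inside
    one batch, making the batch/treatment attribution ambiguous.
    """

    batch_var: float
    treatment_var: float
    residual_var: float
    confounded: bool = False

    @property
    def total(self) -> float:
        return self.batch_var + self.treatment_var + self.residual_var


def _centred_samples_by_features(matrix: ExpressionMatrix) -> np.ndarray:
    x = matrix.values.T.astype(float)  # N x p
    return x - x.mean(axis=0)


def _group_indicator(labels: list[str]) -> np.ndarray:
    uniq = list(dict.fromkeys(labels))
    y = np.zeros((len(labels), len(uniq)))
    for i, lab in enumerate(labels):
        y[i, uniq.index(lab)] = 1.0
    return y


def gpca_delta(matrix: ExpressionMatrix, batch_of: dict[str, str]) -> float:
    """Guided-PCA batch statistic: var along first guided axis over var
    along first unguided axis; lies in (0, 1]."""
    labels = [batch_of[s] for s in matrix.sample_ids]
    if len(set(labels)) < 2:
        raise ValidationError("gPCA requires at least two batches")
    x = _centred_samples_by_features(matrix)
    sv = np.linalg.svd(x, compute_uv=False)
    if sv[0] <= 0 or not np.isfinite(sv[0]):
        raise DegenerateInputError("matrix has no variance across samples")
    y = _group_indicator(labels)
    return _delta_given_unguided(x, y, float(sv[0] ** 2))


def _delta_given_unguided(x: np.ndarray, y: np.ndarray, var_unguided: float) -> float:
    _, _, vt = np.linalg.svd(y.T @ x, full_matrices=False)
    proj = x @ vt[0]
    return float(proj @ proj / var_unguided)


def gpca_pvalue(
    matrix: ExpressionMatrix,
    batch_of: dict[str, str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> GPCAResult:
    """Permutation p-value for the gPCA statistic.

    Batch labels are permuted over samples; the add-one estimator
    p = (1 + #{delta_perm >= delta_obs}) / (n_permutations + 1) keeps the
    p-value away from an exact zero.
    """
    if n_permutations < 100:
        raise ValidationError("use at least 100 permutations")
    labels = [batch_of[s] for s in matrix.sample_ids]
    if len(set(labels)) < 2:
        raise ValidationError("gPCA requires at least two batches")
    x = _centred_samples_by_features(matrix)
    sv = np.linalg.svd(x, compute_uv=False)
    if sv[0] <= 0 or not np.isfinite(sv[0]):
        raise DegenerateInputError("matrix has no variance across samples")
    var_unguided = float(sv[0] ** 2)
    y = _group_indicator(labels)
    observed = _delta_given_unguided(x, y, var_unguided)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y.shape[0])
        if _delta_given_unguided(x, y[perm], var_unguided) >= observed:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return GPCAResult(delta=observed, p_value=p, n_permutations=n_permutations, seed=seed)


def variance_partition(
    matrix: ExpressionMatrix, design: ExperimentDesign
) -> VariancePartition:
    """Batch / treatment / residual variance components, averaged over features.

    Per feature, the batch component is the sum of squares of batch means
    about the grand mean; treatment means are then recomputed on the
    batch-mean-removed data; whatever remains is residual.  Each
    component is divided by N - 1 and averaged over features.
    """
    if design.sample_ids != matrix.sample_ids:
        raise ValidationError("design must be aligned to the matrix (validate_study)")
    x = _centred_samples_by_features(matrix)  # N x p
    n = x.shape[0]
    yb = _group_indicator([design.batch_of[s] for s in design.sample_ids])
    yt = _group_indicator([design.treatment_of[s] for s in design.sample_ids])

    # batch wholly determines treatment -> attribution ambiguous
    cross = yb.T @ yt  # batches x treatments, sample counts
    confounded = bool(np.all((cross > 0).sum(axis=0) == 1))

    counts_b = yb.sum(axis=0)[:, None]
    batch_fit = yb @ (yb.T @ x / counts_b)  # per-feature batch means, broadcast
    ss_batch = np.sum(batch_fit**2, axis=0)

    debatched = x - batch_fit
    counts_t = yt.sum(axis=0)[:, None]
    treat_fit = yt @ (yt.T @ debatched / counts_t)
    ss_treat = np.sum(treat_fit**2, axis=0)

    resid = debatched - treat_fit
    ss_resid = np.sum(resid**2, axis=0)

    scale = 1.0 / (n - 1)
    return VariancePartition(
        batch_var=float(ss_batch.mean() * scale),
        treatment_var=float(ss_treat.mean() * scale),
        residual_var=float(ss_resid.mean() * scale),
        confounded=confounded,
    )


def preserved_variance(raw: ExpressionMatrix, corrected: ExpressionMatrix) -> float:
    """Fraction of raw total feature-centred variance left in the corrected
    matrix, clipped to [0, 1]."""
    if raw.values.shape != corrected.values.shape:
        raise ValidationError(
            f"shape mismatch: raw {raw.values.shape} vs corrected {corrected.values.shape}"
        )
    if raw.feature_ids != corrected.feature_ids or raw.sample_ids != corrected.sample_ids:
        raise ValidationError("raw and corrected matrices carry different labels")
    var_raw = float(np.sum(np.var(raw.values, axis=1)))
    if var_raw <= 0:
        raise DegenerateInputError("raw matrix has no variance")
    var_cor = float(np.sum(np.var(corrected.values, axis=1)))
    return float(np.clip(var_cor / var_raw, 0.0, 1.0))
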