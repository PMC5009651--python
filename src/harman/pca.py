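"""Mean-centred principal component decomposition and its exact inverse.

The decomposition treats samples as observations and features as
variables: the feature-by-sample matrix is transposed to N x p, feature
means are subtracted, and the centred matrix is factored by SVD.  With N
samples there are at most N - 1 components; components whose singular
value is below 1e-10 of the largest are dropped, so rank-deficient data
yields fewer.  Scores are U * S (one column per component, zero column
sums), loadings are the right singular vectors (orthonormal columns).

Only centring is applied — no variance scaling.  Batch offsets are
additive on the log scale, and rescaling features would distort that
additive structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ExpressionMatrix
from .errors import DegenerateInputError, ValidationError

#: relative singular-value cutoff below which a component is considered null
RANK_TOL = 1e-10


@dataclass(frozen=True)
class PCDecomposition:
    """Result of a mean-centred PCA of an expression matrix.

    Attributes
    ----------
    coeff : ndarray, shape (p, m)
        Orthonormal loadings, one column per component.
    scores : ndarray, shape (N, m)
        Sample scores; each column sums to zero.
    feature_means : ndarray, shape (p,)
        Per-feature means removed before the decomposition and restored
        on reconstruction.
    var_fraction : ndarray, shape (m,)
        Fraction of total centred variance carried by each component;
        non-increasing, sums to one when m equals the matrix rank.
    feature_ids, sample_ids : list of str
        Carried through so corrected matrices keep their labels.
    """

    coeff: np.ndarray
    scores: np.ndarray
    feature_means: np.ndarray
    var_fraction: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def decompose(matrix: ExpressionMatrix) -> PCDecomposition:
    """Principal component decomposition of a feature-by-sample matrix.

    Raises
    ------
    DegenerateInputError
        If the matrix is constant across samples (rank zero after
        centring) so no component exists.
    """
    data = matrix.values.T.astype(float)  # N x p
    feature_means = data.mean(axis=0)
    centred = data - feature_means
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] <= 0 or not np.isfinite(s[0]):
        raise DegenerateInputError("matrix is constant across samples; nothing to decompose")
    keep = s > RANK_TOL * s[0]
    u, s, vt = u[:, keep], s[keep], vt[keep]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = u * s
    var_fraction = s**2 / np.sum(s**2)
    return PCDecomposition(
        coeff=vt.T.copy(),
        scores=scores,
        feature_means=feature_means,
        var_fraction=var_fraction,
        feature_ids=matrix.feature_ids,
        sample_ids=matrix.sample_ids,
    )


def reconstruct(decomp: PCDecomposition, scores: np.ndarray | None = None) -> ExpressionMatrix:
    """Invert the decomposition: scores x loadings' + feature means.

    With the original scores this reproduces the input matrix exactly (to
    floating point); with modified scores it maps corrected components
    back to the original feature space.  The result is unique because the
    loadings are fixed.
    """
    if scores is None:
        scores = decomp.scores
    scores = np.asarray(scores, dtype=float)
    if scores.shape != decomp.scores.shape:
        raise ValidationError(
            f"scores shape {scores.shape} does not match decomposition "
            f"{decomp.scores.shape}"
        )
    data = scores @ decomp.coeff.T + decomp.feature_means  # N x p
    return ExpressionMatrix(data.T, decomp.feature_ids, decomp.sample_ids)


def variance_explained(decomp: PCDecomposition) -> np.ndarray:
    """Per-component fractions of total centred variance (non-increasing)."""
    return decomp.var_fraction.copy()
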