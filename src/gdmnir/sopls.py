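"""Two-block sequential and orthogonalized PLS-LDA (SO-PLS-LDA).

The multi-block generalization of PLS-LDA proceeds in three steps:

1. fit a PLS model between the binary-coded response and the first block,
   y_hat = T1 q1 = X1 b1;
2. orthogonalize the second block with respect to the block-1 scores,
   X2_orth = X2 - T1 (T1' T1)^-1 T1' X2, so block 2 can only contribute
   information not already captured by block 1;
3. fit a PLS model between the first-stage residuals e1 = y - y_hat and
   X2_orth, giving e1_hat = X2_orth b2_orth.

The combined prediction is y_hat_SO = X1 b1 + X2_orth b2_orth, classified
by LDA on y_hat_SO. For new samples, block-1 scores are predicted from X1
and the training projection is reused to orthogonalize X2. With A2 = 0 the
model reduces exactly to single-block PLS-LDA on X1; block order matters
and both orders are screened in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plslda import (
    LDAThreshold,
    PLSModel,
    classify_scores,
    lda_threshold,
    pls1_fit,
    pls1_predict,
)

__all__ = ["SOPLSModel", "orthogonalize_block", "sopls_fit", "sopls_predict", "sopls_classify"]


def orthogonalize_block(X2: np.ndarray, T1: np.ndarray) -> np.ndarray:
    """Residual of X2 after projection onto the span of the score matrix T1.

    Uses the pseudo-inverse when T1 is rank deficient, so the result is
    always the orthogonal-projection residual with T1' X2_orth = 0.
    """
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    T1 = np.atleast_2d(np.asarray(T1, dtype=float))
    if T1.shape[0] != X2.shape[0]:
        raise ValueError(f"row mismatch: T1 has {T1.shape[0]}, X2 has {X2.shape[0]}")
    if T1.size == 0:
        return X2.copy()
    return X2 - T1 @ np.linalg.lstsq(T1, X2, rcond=None)[0]


@dataclass(frozen=True)
class SOPLSModel:
    """Fitted two-block SO-PLS-LDA model."""

    block1: PLSModel | None  # None when A1 = 0 (block 1 unused)
    block2: PLSModel | None  # None when A2 = 0
    proj: np.ndarray | None  # (A1, p2): training map T1 -> X2 projection
    x2_mean: np.ndarray
    y_mean: float
    threshold: LDAThreshold
    A1: int
    A2: int

    @property
    def T1(self) -> np.ndarray:
        if self.block1 is None:
            return np.empty((0, 0))
        return self.block1.T


def _so_scores(m: "SOPLSModel", X1_new: np.ndarray, X2_new: np.ndarray) -> np.ndarray:
    X1_new = np.atleast_2d(np.asarray(X1_new, dtype=float))
    X2_new = np.atleast_2d(np.asarray(X2_new, dtype=float))
    n = X2_new.shape[0]
    if m.block1 is not None:
        y1 = pls1_predict(m.block1, X1_new)
        T1_new = (X1_new - m.block1.x_mean) @ m.block1.R
    else:
        y1 = np.full(n, m.y_mean)
        T1_new = np.empty((n, 0))
    if m.block2 is not None:
        X2c = X2_new - m.x2_mean
        X2o = X2c - T1_new @ m.proj if m.proj is not None and m.proj.size else X2c
        # block-2 model was trained on zero-mean residuals, so its own
        # y_mean term is (numerically) zero
        y2 = pls1_predict(m.block2, X2o)
    else:
        y2 = 0.0
    return y1 + y2


def sopls_fit(
    X1: np.ndarray,
    X2: np.ndarray,
    y: np.ndarray,
    A1: int,
    A2: int,
    priors: str = "equal",
) -> SOPLSModel:
    """Fit the three-step SO-PLS-LDA model with A1/A2 latent variables.

    A1 = 0 is accepted as the degenerate block-1-free model (no scores to
    orthogonalize against, so X2_orth is simply centered X2); A2 = 0 drops
    block 2 and reduces to single-block PLS-LDA on X1.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X1.shape[0] != X2.shape[0] or X1.shape[0] != y.size:
        raise ValueError("X1, X2 and y must have matching row counts")
    if A1 < 0 or A2 < 0 or A1 + A2 < 1:
        raise ValueError("need A1 >= 0, A2 >= 0 and at least one component")

    x2_mean = X2.mean(axis=0)
    X2c = X2 - x2_mean

    if A1 >= 1:
        m1 = pls1_fit(X1, y, A1)
        y1 = pls1_predict(m1, X1)
        T1 = m1.T
        proj = np.linalg.lstsq(T1, X2c, rcond=None)[0]
        X2o = X2c - T1 @ proj
    else:
        m1, proj, X2o = None, None, X2c
        y1 = np.full(y.size, y.mean())

    e1 = y - y1
    if A2 >= 1:
        m2 = pls1_fit(X2o, e1, A2)
        y2 = pls1_predict(m2, X2o)
    else:
        m2, y2 = None, 0.0

    y_so = y1 + y2
    thr = lda_threshold(y_so, y, priors=priors)
    return SOPLSModel(m1, m2, proj, x2_mean, float(y.mean()), thr, A1, A2)


def sopls_predict(m: SOPLSModel, X1_new: np.ndarray, X2_new: np.ndarray) -> np.ndarray:
    """Combined predicted responses y_hat_SO = X1 b1 + X2_orth b2_orth."""
    return _so_scores(m, X1_new, X2_new)


def sopls_classify(m: SOPLSModel, X1_new: np.ndarray, X2_new: np.ndarray) -> np.ndarray:
    """0/1 labels from the LDA threshold on y_hat_SO; ties -> NGT."""
    return classify_scores(sopls_predict(m, X1_new, X2_new), m.threshold)
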