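"""Single-block PLS-LDA: PLS1 regression on a binary-coded response with an
LDA-derived decision threshold on the predicted responses.

The class membership (1 = GDM, 0 = NGT) is regressed on the predictor matrix
by PLS1, which compresses X into scores T = XR of maximal covariance with y;
the response is regressed on the scores, y_hat = Tq, so that in terms of the
original variables y_hat = XRq = Xb with b = Rq. Because y_hat is
real-valued, a threshold is placed on it by one-dimensional two-class LDA
with pooled within-class variance; samples on the case side of the threshold
are predicted GDM.

Components are extracted by NIPALS with X-deflation. Fitting with `A`
components also exposes the nested coefficient path b_1..b_A, so the
predictions of every smaller model are available from a single fit — the
double-cross-validation inner loop relies on this.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PLSModel",
    "LDAThreshold",
    "pls1_fit",
    "pls1_predict",
    "lda_threshold",
    "plslda_classify",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class PLSModel:
    """Fitted PLS1 model with nested component path.

    `W`, `P`, `q`, `R`, `T` follow the usual PLS conventions (weights,
    x-loadings, y-loadings, transformed weights with T = X_centered R,
    training scores). `coef_path[:, a-1]` holds the regression coefficients
    of the a-component sub-model; `b = coef_path[:, A-1]`.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    R: np.ndarray
    T: np.ndarray
    coef_path: np.ndarray

    @property
    def b(self) -> np.ndarray:
        """Regression coefficients of the full A-component model."""
        return self.coef_path[:, self.n_components - 1]

    def fitted_path(self) -> np.ndarray:
        """Training predictions for every sub-model, shape (n, A)."""
        return np.cumsum(self.T * self.q, axis=1) + self.y_mean


@dataclass(frozen=True)
class LDAThreshold:
    """One-dimensional two-class LDA decision rule on predicted responses."""

    threshold: float
    orientation: str  # "gdm_above" | "gdm_below"
    m0: float
    m1: float
    pooled_var: float
    pi0: float
    pi1: float


def pls1_fit(X: np.ndarray, y: np.ndarray, A: int) -> PLSModel:
    """Fit a PLS1 model with `A` latent variables by NIPALS.

    X is centered internally (training means stored); y is the binary-coded
    response. If `A` exceeds the effective rank, extraction stops early with
    a warning and the model keeps the components found.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"y length {y.size} != rows {n}")
    if A < 1:
        raise ValueError("A must be >= 1")
    # A constant response (e.g. zero residuals in a sequential second stage)
    # yields the degenerate all-zero-coefficient model; classification-level
    # code raises on single-class targets when placing the LDA threshold.
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    A_cap = min(A, max(1, min(n - 1, p)))
    W = np.zeros((p, A_cap))
    P = np.zeros((p, A_cap))
    T = np.zeros((n, A_cap))
    q = np.zeros(A_cap)

    Xd = Xc.copy()
    tiny = 1e-12 * max(1.0, float(np.abs(Xc).max(initial=0.0)))
    a_eff = 0
    for a in range(A_cap):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw <= tiny:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= tiny**2:
            break
        P[:, a] = Xd.T @ t / tt
        q[a] = float(yc @ t) / tt
        W[:, a] = w
        T[:, a] = t
        Xd -= np.outer(t, P[:, a])
        a_eff = a + 1

    if a_eff == 0:
        # no extractable covariance: all-zero coefficients
        W, P, T, q = (np.zeros((p, 1)), np.zeros((p, 1)), np.zeros((n, 1)), np.zeros(1))
        R = np.zeros((p, 1))
        coef_path = np.zeros((p, 1))
        return PLSModel(1, x_mean, y_mean, W, P, q, R, T, coef_path)

    if a_eff < A:
        warnings.warn(
            f"rank limit: extracted {a_eff} of {A} requested components", stacklevel=2
        )
    W, P, T, q = W[:, :a_eff], P[:, :a_eff], T[:, :a_eff], q[:a_eff]
    # T = Xc R with R = W (P'W)^-1 (P'W is unit upper triangular for NIPALS)
    R = np.linalg.solve((P.T @ W).T, W.T).T
    coef_path = np.cumsum(R * q, axis=1)
    return PLSModel(a_eff, x_mean, y_mean, W, P, q, R, T, coef_path)


def pls1_predict(m: PLSModel, X_new: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Predicted responses y_hat = (X_new - x_mean) b + y_mean."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != m.x_mean.size:
        raise ValueError(f"column mismatch: {X_new.shape[1]} vs trained {m.x_mean.size}")
    A = m.n_components if n_components is None else n_components
    if not 1 <= A <= m.n_components:
        raise ValueError(f"n_components must be in 1..{m.n_components}")
    return (X_new - m.x_mean) @ m.coef_path[:, A - 1] + m.y_mean


def lda_threshold(
    y_hat: np.ndarray, y: np.ndarray, priors: str = "equal"
) -> LDAThreshold:
    """Two-class LDA on the 1-D predicted responses.

    With pooled within-class variance s2 and class means m0 < or > m1,
    the boundary is (m0+m1)/2 + s2*ln(pi0/pi1)/(m1-m0); equal priors reduce
    it to the midpoint. Orientation records which side is the case side.
    """
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y).ravel()
    g0, g1 = y_hat[y == 0], y_hat[y == 1]
    if g0.size == 0 or g1.size == 0:
        raise ValueError("both classes must be present to place a threshold")
    m0, m1 = float(g0.mean()), float(g1.mean())
    if m0 == m1:
        raise ValueError("degenerate separation: class means coincide")
    n0, n1 = g0.size, g1.size
    ss = (g0 - m0) @ (g0 - m0) + (g1 - m1) @ (g1 - m1)
    dof = n0 + n1 - 2
    s2 = float(ss / dof) if dof > 0 else 0.0
    if priors == "equal":
        pi0 = pi1 = 0.5
    elif priors == "proportional":
        pi0, pi1 = n0 / (n0 + n1), n1 / (n0 + n1)
    else:
        raise ValueError("priors must be 'equal' or 'proportional'")
    log_ratio = np.log(pi0 / pi1)
    if log_ratio != 0.0 and s2 == 0.0:
        raise ValueError("zero pooled variance with unequal priors")
    thr = (m0 + m1) / 2 + s2 * log_ratio / (m1 - m0)
    orientation = "gdm_above" if m1 > m0 else "gdm_below"
    return LDAThreshold(float(thr), orientation, m0, m1, s2, pi0, pi1)


def plslda_classify(
    m: PLSModel, t: LDAThreshold, X_new: np.ndarray, n_components: int | None = None
) -> np.ndarray:
    """Predict 0/1 labels; exact ties at the threshold go to class 0 (NGT)."""
    y_hat = pls1_predict(m, X_new, n_components)
    return classify_scores(y_hat, t)


def classify_scores(y_hat: np.ndarray, t: LDAThreshold) -> np.ndarray:
    """Apply an LDA threshold to predicted responses; ties -> class 0."""
    y_hat = np.asarray(y_hat, dtype=float)
    if t.orientation == "gdm_above":
        return (y_hat > t.threshold).astype(int)
    return (y_hat < t.threshold).astype(int)


def save_model(path: str | Path, m: PLSModel, t: LDAThreshold | None = None) -> None:
    """Write a fitted model (and optional threshold) as structured text.

    The format is JSON with full float precision, so a reloaded model
    reproduces predictions bit-for-bit; no binary formats are involved.
    """
    payload = {
        "format": "gdmnir-plslda",
        "version": 1,
        "model": {
            "n_components": m.n_components,
            "y_mean": m.y_mean,
            **{
                k: getattr(m, k).tolist()
                for k in ("x_mean", "W", "P", "q", "R", "T", "coef_path")
            },
        },
        "threshold": asdict(t) if t is not None else None,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[PLSModel, LDAThreshold | None]:
    """Reload a model written by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "gdmnir-plslda":
        raise ValueError(f"{path} is not a PLS-LDA model file")
    d = payload["model"]
    m = PLSModel(
        n_components=int(d["n_components"]),
        x_mean=np.asarray(d["x_mean"], float),
        y_mean=float(d["y_mean"]),
        W=np.asarray(d["W"], float),
        P=np.asarray(d["P"], float),
        q=np.asarray(d["q"], float),
        R=np.asarray(d["R"], float),
        T=np.asarray(d["T"], float),
        coef_path=np.asarray(d["coef_path"], float),
    )
    t = LDAThreshold(**payload["threshold"]) if payload["threshold"] else None
    return m, t
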