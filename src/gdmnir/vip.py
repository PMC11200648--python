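"""Variable importance in projection (VIP) and spectral interval reporting.

For a single-response PLS model with A components, weights w_a (unit norm,
per deflated matrix), scores t_a and y-loadings q_a, the importance of
variable j is

    VIP_j = sqrt( p * sum_a SS_a * w_ja^2 / sum_a SS_a ),   SS_a = q_a^2 t_a' t_a,

the standard single-response formulation. The normalization makes the mean
squared VIP equal 1, so variables with average VIP above 1 are flagged as
relevant. Selected variables are reported as contiguous wavenumber
intervals; runs separated by at most `gap` unselected points are merged, so
an interval is "mainly" rather than exclusively composed of relevant points.
"""

from __future__ import annotations

import numpy as np

from .plslda import PLSModel

__all__ = ["vip_scores", "select_relevant", "merge_intervals"]


def vip_scores(m: PLSModel, n_components: int | None = None) -> np.ndarray:
    """Per-variable VIP vector of a fitted PLS model (mean square = 1)."""
    A = m.n_components if n_components is None else n_components
    if not 1 <= A <= m.n_components:
        raise ValueError(f"n_components must be in 1..{m.n_components}")
    W = m.W[:, :A]
    ss = m.q[:A] ** 2 * np.einsum("ij,ij->j", m.T[:, :A], m.T[:, :A])
    total = ss.sum()
    p = W.shape[0]
    if total <= 0:
        # degenerate fit with no explained covariance: uniform importance
        return np.ones(p)
    return np.sqrt(p * (W**2 @ ss) / total)


def select_relevant(avg_vip: np.ndarray, threshold: float = 1.0) -> np.ndarray:
    """Boolean relevance mask, strictly-greater comparison."""
    return np.asarray(avg_vip, dtype=float) > threshold


def merge_intervals(
    mask: np.ndarray, wavenumbers: np.ndarray, gap: int = 3
) -> list[tuple[float, float]]:
    """Contiguous (high, low) cm^-1 intervals of selected variables.

    Runs of selected points separated by at most `gap` unselected points
    are merged into one interval. The axis is descending, so each interval
    is reported as (high, low).
    """
    mask = np.asarray(mask, dtype=bool).ravel()
    wavenumbers = np.asarray(wavenumbers, dtype=float).ravel()
    if mask.size != wavenumbers.size:
        raise ValueError("mask and wavenumber axis lengths differ")
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    runs: list[list[int]] = [[idx[0], idx[0]]]
    for i in idx[1:]:
        if i - runs[-1][1] - 1 <= gap:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    return [(float(wavenumbers[a]), float(wavenumbers[b])) for a, b in runs]
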