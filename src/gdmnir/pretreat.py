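"""Composable spectral pretreatments and the screening grid.

Row-wise operators (Savitzky-Golay smoothing/derivatives, SNV scatter
correction, iterative weighted-least-squares baseline removal, 2-norm
normalization) are stateless: each spectrum is transformed independently,
so they can be applied before any train/test split without leakage.
Column scalers (mean centering, autoscaling) learn statistics and must be
fitted on training rows only; :class:`FittedScaler` carries those statistics.

A :class:`PretreatmentSpec` is an ordered step list with a compact string
form mirroring chemometrics shorthand: ``"SM(W=23)+N+MC"``,
``"1D(W=15)+MC"``, ``"WLS+N+MC"``, ``"SNV+MC"``, ``"AS"`` (autoscale).
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "PretreatmentSpec",
    "FittedScaler",
    "GridConfig",
    "savitzky_golay",
    "snv",
    "wls_baseline",
    "norm2",
    "fit_column_scaler",
    "apply_column_scaler",
    "build_grid",
    "apply_pipeline",
    "apply_row_steps",
]

_FILTER_OPS = {"smooth", "deriv1", "deriv2"}
_SCALER_OPS = {"mean_center", "autoscale"}
_ROW_OPS = _FILTER_OPS | {"snv", "wls_baseline", "norm2"}

_TOKEN = {
    "smooth": "SM",
    "deriv1": "1D",
    "deriv2": "2D",
    "snv": "SNV",
    "wls_baseline": "WLS",
    "norm2": "N",
    "mean_center": "MC",
    "autoscale": "AS",
}
_OP_FROM_TOKEN = {v: k for k, v in _TOKEN.items()}


@dataclass(frozen=True)
class PretreatmentSpec:
    """Ordered list of (operator, parameters) pretreatment steps."""

    steps: tuple[tuple[str, tuple[tuple[str, float], ...]], ...]

    def __post_init__(self) -> None:
        ops = [op for op, _ in self.steps]
        unknown = set(ops) - _ROW_OPS - _SCALER_OPS
        if unknown:
            raise ValueError(f"unknown operators {sorted(unknown)}")
        if len(set(ops) & _FILTER_OPS) > 1 or sum(op in _FILTER_OPS for op in ops) > 1:
            raise ValueError("at most one of smooth/deriv1/deriv2 allowed")
        scalers = [op for op in ops if op in _SCALER_OPS]
        if len(scalers) > 1:
            raise ValueError("mean_center and autoscale are mutually exclusive")
        if scalers and ops[-1] not in _SCALER_OPS:
            raise ValueError("the column scaler must be the last step")
        for op, params in self.steps:
            p = dict(params)
            if op in _FILTER_OPS and "width" in p:
                w = int(p["width"])
                if w < 3 or w % 2 == 0:
                    raise ValueError(f"{op}: window width must be odd and >= 3, got {w}")

    @classmethod
    def make(cls, *steps: str | tuple[str, dict]) -> "PretreatmentSpec":
        """Build a spec from step names or (name, params) pairs."""
        norm = []
        for s in steps:
            if isinstance(s, str):
                norm.append((s, ()))
            else:
                op, params = s
                norm.append((op, tuple(sorted((k, float(v)) for k, v in params.items()))))
        return cls(tuple(norm))

    def params(self, i: int) -> dict:
        return dict(self.steps[i][1])

    # -- string DSL ------------------------------------------------------
    def __str__(self) -> str:
        parts = []
        for op, params in self.steps:
            tok = _TOKEN[op]
            p = dict(params)
            if op in _FILTER_OPS:
                tok += f"(W={int(p.get('width', 0))})" if "width" in p else ""
            parts.append(tok)
        return "+".join(parts) if parts else "raw"

    @classmethod
    def parse(cls, text: str) -> "PretreatmentSpec":
        """Parse the shorthand form, e.g. ``"1D(W=15)+MC"``."""
        if text.strip() in ("", "raw"):
            return cls(())
        steps: list[tuple[str, dict]] = []
        for tok in text.split("+"):
            tok = tok.strip()
            m = re.fullmatch(r"([A-Z0-9]+)(?:\(W=(\d+)\))?", tok)
            if not m or m.group(1) not in _OP_FROM_TOKEN:
                raise ValueError(f"cannot parse pretreatment token {tok!r}")
            op = _OP_FROM_TOKEN[m.group(1)]
            params = {"width": int(m.group(2))} if m.group(2) else {}
            steps.append((op, params))
        return cls.make(*steps)


@dataclass(frozen=True)
class FittedScaler:
    """Column statistics learned on a training partition."""

    mode: str  # "mean_center" | "autoscale"
    means: np.ndarray
    scales: np.ndarray = field(default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# Row-wise operators


def savitzky_golay(
    X: np.ndarray, width: int, polyorder: int = 2, deriv: int = 0
) -> np.ndarray:
    """Savitzky-Golay smoothing (`deriv=0`) or derivative per spectrum.

    Local least-squares polynomial of order `polyorder` over a sliding
    window of `width` points; derivatives are in per-point units (the
    wavenumber step cancels after centering in all downstream models).
    Edges use polynomial extrapolation within the first/last window.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if width % 2 == 0 or width < 3:
        raise ValueError(f"window width must be odd and >= 3, got {width}")
    if width > X.shape[1]:
        raise ValueError(f"window width {width} exceeds variable count {X.shape[1]}")
    if width < polyorder + 1:
        raise ValueError("window width must be >= polyorder + 1")
    return savgol_filter(X, width, polyorder, deriv=deriv, delta=1.0, axis=1, mode="interp")


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: center/scale each spectrum to mean 0, SD 1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    degenerate = np.flatnonzero(sd.ravel() == 0)
    if degenerate.size:
        raise ValueError(f"constant spectra (zero SD) at rows {degenerate.tolist()}")
    return (X - mu) / sd


def wls_baseline(
    X: np.ndarray,
    order: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
    eps: float = 0.01,
) -> np.ndarray:
    """Subtract an iteratively re-weighted polynomial baseline per spectrum.

    Points above the current baseline (candidate peaks) get weight `eps`,
    points on/below it weight 1, and the order-`order` polynomial is refit
    until the weight vector changes by less than `tol` (max-norm) or
    `max_iter` is reached. Returns spectrum minus converged baseline.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    if order >= p:
        raise ValueError(f"order {order} must be < variable count {p}")
    # scaled abscissa for conditioning
    t = np.linspace(-1.0, 1.0, p)
    V = np.vander(t, order + 1, increasing=True)
    out = np.empty_like(X)
    for i in range(n):
        y = X[i]
        w = np.ones(p)
        baseline = np.zeros(p)
        for _ in range(max_iter):
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(V * sw[:, None], y * sw, rcond=None)
            baseline = V @ coef
            w_new = np.where(y > baseline, eps, 1.0)
            if np.max(np.abs(w_new - w)) < tol:
                break
            w = w_new
        out[i] = y - baseline
    return out


def norm2(X: np.ndarray) -> np.ndarray:
    """Scale each spectrum to unit Euclidean norm."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    zero = np.flatnonzero(norms.ravel() == 0)
    if zero.size:
        raise ValueError(f"zero-norm spectra at rows {zero.tolist()}")
    return X / norms


# ---------------------------------------------------------------------------
# Column scalers (train/test aware)


def fit_column_scaler(X_train: np.ndarray, mode: str) -> FittedScaler:
    """Learn column means (and SDs for autoscaling) from training rows.

    Constant training columns under autoscaling receive scale 1 with a
    warning: binary covariates can legitimately be constant inside small
    cross-validation folds.
    """
    if mode not in _SCALER_OPS:
        raise ValueError(f"mode must be one of {sorted(_SCALER_OPS)}")
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    means = X_train.mean(axis=0)
    scales = None
    if mode == "autoscale":
        scales = X_train.std(axis=0, ddof=1)
        const = scales == 0
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant column(s) under autoscale; scale set to 1",
                stacklevel=2,
            )
            scales = np.where(const, 1.0, scales)
    return FittedScaler(mode, means, scales)


def apply_column_scaler(f: FittedScaler, X: np.ndarray) -> np.ndarray:
    """Apply learned centering/scaling to any matrix with matching columns."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != f.means.size:
        raise ValueError(f"column mismatch: {X.shape[1]} vs fitted {f.means.size}")
    out = X - f.means
    if f.mode == "autoscale":
        out = out / f.scales
    return out


# ---------------------------------------------------------------------------
# Pipeline application


_ROW_FUNCS = {
    "smooth": lambda X, p: savitzky_golay(
        X, int(p["width"]), int(p.get("polyorder", 2)), deriv=0
    ),
    "deriv1": lambda X, p: savitzky_golay(
        X, int(p["width"]), int(p.get("polyorder", 2)), deriv=1
    ),
    "deriv2": lambda X, p: savitzky_golay(
        X, int(p["width"]), int(p.get("polyorder", 2)), deriv=2
    ),
    "snv": lambda X, p: snv(X),
    "wls_baseline": lambda X, p: wls_baseline(
        X,
        order=int(p.get("order", 2)),
        max_iter=int(p.get("max_iter", 100)),
        tol=float(p.get("tol", 1e-6)),
    ),
    "norm2": lambda X, p: norm2(X),
}


def apply_row_steps(X: np.ndarray, spec: PretreatmentSpec) -> np.ndarray:
    """Apply only the stateless row-wise steps of a spec, in order."""
    out = np.atleast_2d(np.asarray(X, dtype=float))
    for i, (op, params) in enumerate(spec.steps):
        if op in _SCALER_OPS:
            continue
        try:
            out = _ROW_FUNCS[op](out, dict(params))
        except ValueError as exc:
            raise ValueError(f"step {i} ({op}): {exc}") from exc
    return out


def apply_pipeline(
    X: np.ndarray, spec: PretreatmentSpec, fitted: FittedScaler | None = None
) -> tuple[np.ndarray, FittedScaler | None]:
    """Run a full pretreatment spec on a matrix.

    Row-wise operators are applied statelessly in listed order. If the spec
    ends in a column scaler, it is fitted on `X` when `fitted` is None
    (training call) or re-applied with the stored statistics (test call).
    Returns the transformed matrix and the (possibly newly fitted) scaler.
    """
    out = apply_row_steps(X, spec)
    scaler_ops = [op for op, _ in spec.steps if op in _SCALER_OPS]
    if not scaler_ops:
        return out, None
    if fitted is None:
        fitted = fit_column_scaler(out, scaler_ops[0])
    elif fitted.mode != scaler_ops[0]:
        raise ValueError(f"fitted scaler mode {fitted.mode!r} != spec {scaler_ops[0]!r}")
    return apply_column_scaler(fitted, out), fitted


# ---------------------------------------------------------------------------
# Screening grid


@dataclass(frozen=True)
class GridConfig:
    """Options enumerated into the pretreatment screening grid.

    The default grid is {none | SM(W) | 1D(W) | 2D(W), W in widths}
    x {none | SNV | WLS} x {none | N}, each spec terminated by MC:
    (1 + 3*4) * 3 * 2 = 78 combinations.
    """

    widths: tuple[int, ...] = (3, 7, 15, 23)
    filters: tuple[str, ...] = ("smooth", "deriv1", "deriv2")
    include_no_filter: bool = True
    scatter_options: tuple[str, ...] = ("none", "snv", "wls_baseline")
    norm_options: tuple[str, ...] = ("none", "norm2")
    scaler: str = "mean_center"


#: Reduced grid for quick screening: 4 x 3 x 1 = 12 specs at width 15.
REDUCED_GRID = GridConfig(widths=(15,), norm_options=("none",))


def build_grid(config: GridConfig = GridConfig()) -> list[PretreatmentSpec]:
    """Deterministically enumerate the pretreatment grid in canonical order."""
    if not (config.filters or config.include_no_filter):
        raise ValueError("no filter options configured")
    if not config.scatter_options or not config.norm_options:
        raise ValueError("scatter/norm option lists must be nonempty")
    filter_opts: list[tuple] = [()] if config.include_no_filter else []
    for f in config.filters:
        if f not in _FILTER_OPS:
            raise ValueError(f"unknown filter {f!r}")
        for w in config.widths:
            filter_opts.append(((f, {"width": w}),))
    scatter_opts = [() if s == "none" else ((s, {}),) for s in config.scatter_options]
    norm_opts = [() if n == "none" else ((n, {}),) for n in config.norm_options]

    specs, seen = [], set()
    for fo, so, no in itertools.product(filter_opts, scatter_opts, norm_opts):
        steps = fo + so + no + ((config.scaler, {}),)
        spec = PretreatmentSpec.make(*steps)
        key = str(spec)
        if key not in seen:
            seen.add(key)
            specs.append(spec)
    return specs
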