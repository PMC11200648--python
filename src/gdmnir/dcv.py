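"""Repeated double cross-validation (DCV) for two-class models.

DCV nests two cross-validation loops: the inner loop (default 10 segments)
selects the model complexity — the number of latent variables — by balanced
accuracy (NER), and the outer loop (default 20 segments) estimates
predictive performance on samples never seen during selection or fitting.
The whole procedure is repeated (default 50 times) with re-randomized
splits; every figure of merit is reported as mean +/- SD over repetitions.

Model families plug in through :class:`ModelBuilder`: a builder fits, on a
training partition only, a *path* of candidate models (e.g. PLS-LDA with
1..A_max components from a single NIPALS run) and returns decision scores,
labels and per-candidate LDA thresholds. Anything learned — centering
means, autoscaling SDs, thresholds, the selected component count — is
derived strictly inside the current training split.

Partitions are plain random with near-equal segment sizes and are re-drawn
(bounded retries) until every training complement contains both classes;
with 8 cases and 20 outer segments per-segment stratification is not
possible, so none is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .metrics import auroc, confusion_from_labels, sp_se_ner
from .plslda import PLSModel, classify_scores, pls1_fit
from .pretreat import FittedScaler, apply_column_scaler, fit_column_scaler
from .sopls import SOPLSModel, sopls_fit, sopls_predict
from .vip import vip_scores

__all__ = [
    "DCVConfig",
    "DCVResult",
    "ModelBuilder",
    "FittedPath",
    "PLSLDABuilder",
    "SOPLSLDABuilder",
    "FixedRuleBuilder",
    "make_partition",
    "inner_select",
    "dcv_run",
]

Blocks = "np.ndarray | tuple[np.ndarray, ...]"


def _rows(X, idx):
    if isinstance(X, tuple):
        return tuple(b[idx] for b in X)
    return X[idx]


def _n_rows(X) -> int:
    return (X[0] if isinstance(X, tuple) else X).shape[0]


@dataclass(frozen=True)
class DCVConfig:
    """Parameters of the repeated double cross-validation procedure."""

    inner_segments: int = 10
    outer_segments: int = 20
    repetitions: int = 50
    seed: int = 0
    A_max: int = 10
    priors: str = "equal"

    def __post_init__(self) -> None:
        if self.inner_segments < 2 or self.outer_segments < 2:
            raise ValueError("segment counts must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class DCVResult:
    """Per-repetition figures of merit and outer-loop predictions."""

    sp: np.ndarray
    se: np.ndarray
    ner: np.ndarray
    auroc: np.ndarray
    predictions: np.ndarray  # (reps, n) pooled outer predicted responses
    pred_labels: np.ndarray  # (reps, n) pooled outer predicted labels
    labels: np.ndarray  # (n,) true labels
    selected: list  # [rep][fold] -> chosen candidate
    vip_mean: np.ndarray | None = None
    vip_models: int = 0

    def summary(self) -> dict[str, float]:
        """Mean +/- sample SD over repetitions for each metric."""
        out = {}
        for name in ("sp", "se", "ner", "auroc"):
            v = getattr(self, name)
            out[f"{name}_mean"] = float(np.mean(v))
            # a constant metric vector has SD exactly 0 (deterministic rules)
            if v.size <= 1 or np.ptp(v) == 0.0:
                out[f"{name}_sd"] = 0.0
            else:
                out[f"{name}_sd"] = float(np.std(v, ddof=1))
        return out

    def roc_inputs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-repetition (scores, labels) pairs for ROC averaging."""
        return [(self.predictions[r], self.labels) for r in range(self.predictions.shape[0])]


# ---------------------------------------------------------------------------
# Partitioning


def make_partition(
    n: int, k: int, labels: np.ndarray, rng: np.random.Generator, max_retries: int = 100
) -> np.ndarray:
    """Random segment assignment 0..k-1 with sizes differing by <= 1.

    Re-drawn until no segment swallows an entire class (so every training
    complement contains both classes); raises after `max_retries` draws if
    the constraint cannot be met (e.g. leave-one-out with a singleton class).
    """
    labels = np.asarray(labels).ravel()
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} segments")
    base, rem = divmod(n, k)
    sizes = np.full(k, base)
    sizes[:rem] += 1
    seg_of_slot = np.repeat(np.arange(k), sizes)
    for _ in range(max_retries):
        perm = rng.permutation(n)
        assign = np.empty(n, dtype=int)
        assign[perm] = seg_of_slot
        ok = True
        for cls in (0, 1):
            members = assign[labels == cls]
            # a class entirely inside one segment leaves that segment's
            # training complement without the class
            if members.size and np.unique(members).size == 1 and k > 1:
                ok = False
                break
        if ok:
            return assign
    raise ValueError(
        f"could not partition {n} samples into {k} segments with both classes "
        "in every training complement"
    )


# ---------------------------------------------------------------------------
# Model builders


class FittedPath(Protocol):
    """A family of candidate models fitted on one training partition."""

    def decision(self, X_new) -> np.ndarray:
        """Predicted responses, shape (n_new, n_candidates)."""

    def predict_labels(self, X_new) -> np.ndarray:
        """0/1 labels, shape (n_new, n_candidates)."""

    def vip(self, cand_idx: int) -> np.ndarray | None:
        """Per-variable VIP of candidate `cand_idx`, if defined."""


class ModelBuilder(Protocol):
    """Factory of candidate-model paths; `candidates` is ordered so that
    ties in inner NER resolve to the earlier (simpler) candidate."""

    candidates: Sequence

    def fit_path(self, X, y) -> FittedPath: ...


def _vectorized_lda(F: np.ndarray, y: np.ndarray, priors: str):
    """Per-column 1-D LDA thresholds for a fitted-value path matrix F (n, C).

    Returns (thr, sign, valid): decision is GDM iff sign*(score - thr) > 0;
    columns with coincident class means are invalid (always predict NGT).
    Numerically identical to `lda_threshold` column by column.
    """
    pos = y == 1
    n1 = int(pos.sum())
    n0 = y.size - n1
    m1 = F[pos].mean(axis=0)
    m0 = F[~pos].mean(axis=0)
    valid = m1 != m0
    sign = np.where(m1 > m0, 1.0, -1.0)
    if priors == "equal":
        thr = (m0 + m1) / 2
    elif priors == "proportional":
        ss = ((F[pos] - m1) ** 2).sum(axis=0) + ((F[~pos] - m0) ** 2).sum(axis=0)
        dof = n0 + n1 - 2
        s2 = ss / dof if dof > 0 else np.zeros_like(ss)
        log_ratio = np.log(n0 / n1)
        with np.errstate(divide="ignore", invalid="ignore"):
            thr = (m0 + m1) / 2 + s2 * log_ratio / (m1 - m0)
        valid = valid & ~((s2 == 0) & (log_ratio != 0))
    else:
        raise ValueError("priors must be 'equal' or 'proportional'")
    return np.where(valid, thr, 0.0), sign, valid


class _PLSLDAPath:
    def __init__(self, model: PLSModel, y: np.ndarray, priors: str, n_cand: int):
        self.model = model
        self.n_cand = n_cand
        self.priors = priors
        self.thr, self.sign, self.valid = _vectorized_lda(
            self._pad(model.fitted_path()), y, priors
        )

    def _pad(self, raw: np.ndarray) -> np.ndarray:
        if raw.shape[1] < self.n_cand:  # rank-limited: reuse the deepest model
            pad = np.repeat(raw[:, -1:], self.n_cand - raw.shape[1], axis=1)
            raw = np.hstack([raw, pad])
        return raw

    def _scores_all(self, X_new) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        return self._pad(
            (X_new - self.model.x_mean) @ self.model.coef_path + self.model.y_mean
        )

    def decision(self, X_new) -> np.ndarray:
        return self._scores_all(X_new)

    def predict_labels(self, X_new) -> np.ndarray:
        scores = self._scores_all(X_new)
        return ((self.sign * (scores - self.thr) > 0) & self.valid).astype(int)

    def vip(self, cand_idx: int) -> np.ndarray | None:
        A = min(cand_idx + 1, self.model.n_components)
        return vip_scores(self.model, A)


class PLSLDABuilder:
    """PLS-LDA path over 1..A_max latent variables from a single NIPALS fit.

    Mean centering is inherent to the PLS fit; pass `scaler="autoscale"`
    to additionally autoscale columns on the training partition (used for
    clinical covariate blocks).
    """

    def __init__(self, A_max: int = 10, priors: str = "equal", scaler: str | None = None):
        self.A_max = A_max
        self.priors = priors
        self.scaler = scaler
        self.candidates = list(range(1, A_max + 1))

    def fit_path(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y).ravel()
        fitted_scaler = None
        if self.scaler == "autoscale":
            fitted_scaler = fit_column_scaler(X, "autoscale")
            X = apply_column_scaler(fitted_scaler, X)
        A_cap = min(self.A_max, max(1, min(X.shape[0] - 1, X.shape[1])))
        model = pls1_fit(X, y, A_cap)
        path = _PLSLDAPath(model, y, self.priors, self.A_max)
        if fitted_scaler is not None:
            return _ScaledPath(path, fitted_scaler)
        return path


class _ScaledPath:
    """Wrap a path so new data passes through a training-fitted scaler."""

    def __init__(self, inner, scaler: FittedScaler):
        self.inner = inner
        self.scaler = scaler

    def decision(self, X_new):
        return self.inner.decision(apply_column_scaler(self.scaler, X_new))

    def predict_labels(self, X_new):
        return self.inner.predict_labels(apply_column_scaler(self.scaler, X_new))

    def vip(self, cand_idx):
        return self.inner.vip(cand_idx)


class _SOPLSPath:
    def __init__(self, models: list[SOPLSModel | None], candidates):
        self.models = models
        self.candidates = candidates

    def decision(self, X_new) -> np.ndarray:
        X1, X2 = X_new
        cols = []
        for m in self.models:
            if m is None:
                cols.append(np.zeros(np.atleast_2d(X1).shape[0]))
            else:
                cols.append(sopls_predict(m, X1, X2))
        return np.column_stack(cols)

    def predict_labels(self, X_new) -> np.ndarray:
        X1, X2 = X_new
        cols = []
        for m in self.models:
            if m is None:
                cols.append(np.zeros(np.atleast_2d(X1).shape[0], dtype=int))
            else:
                scores = sopls_predict(m, X1, X2)
                cols.append(classify_scores(scores, m.threshold))
        return np.column_stack(cols)

    def vip(self, cand_idx: int) -> np.ndarray | None:
        # per-block VIP of the block-1 sub-model (spectral block) when present
        m = self.models[cand_idx]
        if m is None or m.block1 is None:
            return None
        return vip_scores(m.block1)


class SOPLSLDABuilder:
    """SO-PLS-LDA path over an (A1, A2) grid.

    Candidates are ordered by total complexity (A1 + A2, then A1) so inner
    ties resolve to the most parsimonious model. `scalers` gives the
    per-block column treatment (None = centering only, via the PLS fit;
    "autoscale" for covariate blocks).
    """

    def __init__(
        self,
        A1_max: int = 5,
        A2_max: int = 5,
        priors: str = "equal",
        scalers: tuple[str | None, str | None] = (None, None),
        include_A1_zero: bool = False,
    ):
        self.A1_max = A1_max
        self.A2_max = A2_max
        self.priors = priors
        self.scalers = scalers
        a1_lo = 0 if include_A1_zero else 1
        grid = [
            (a1, a2)
            for a1 in range(a1_lo, A1_max + 1)
            for a2 in range(0, A2_max + 1)
            if a1 + a2 >= 1
        ]
        self.candidates = sorted(grid, key=lambda c: (c[0] + c[1], c[0]))

    def fit_path(self, X, y):
        X1, X2 = X
        fitted_scalers = []
        blocks = []
        for block, mode in zip((X1, X2), self.scalers):
            block = np.atleast_2d(np.asarray(block, dtype=float))
            if mode == "autoscale":
                fs = fit_column_scaler(block, "autoscale")
                block = apply_column_scaler(fs, block)
                fitted_scalers.append(fs)
            else:
                fitted_scalers.append(None)
            blocks.append(block)
        models: list[SOPLSModel | None] = []
        for a1, a2 in self.candidates:
            try:
                models.append(sopls_fit(blocks[0], blocks[1], y, a1, a2, priors=self.priors))
            except ValueError:
                models.append(None)
        path = _SOPLSPath(models, self.candidates)
        if any(fs is not None for fs in fitted_scalers):
            return _BlockScaledPath(path, fitted_scalers)
        return path


class _BlockScaledPath:
    def __init__(self, inner, scalers):
        self.inner = inner
        self.scalers = scalers

    def _transform(self, X_new):
        out = []
        for block, fs in zip(X_new, self.scalers):
            out.append(apply_column_scaler(fs, block) if fs is not None else block)
        return tuple(out)

    def decision(self, X_new):
        return self.inner.decision(self._transform(X_new))

    def predict_labels(self, X_new):
        return self.inner.predict_labels(self._transform(X_new))

    def vip(self, cand_idx):
        return self.inner.vip(cand_idx)


class _FixedRulePath:
    def __init__(self, threshold: float):
        self.threshold = threshold

    def decision(self, X_new) -> np.ndarray:
        return np.atleast_2d(np.asarray(X_new, dtype=float))[:, [0]].copy()

    def predict_labels(self, X_new) -> np.ndarray:
        return (self.decision(X_new) > self.threshold).astype(int)

    def vip(self, cand_idx):
        return None


class FixedRuleBuilder:
    """Deterministic single-variable rule: predict GDM iff column 0 > cut.

    Has no tunable hyperparameters and learns nothing from the data, so its
    DCV metrics are identical across repetitions (SD exactly zero).
    """

    def __init__(self, cut: float = 0.5):
        self.cut = cut
        self.candidates = [None]

    def fit_path(self, X, y):
        return _FixedRulePath(self.cut)


# ---------------------------------------------------------------------------
# Inner selection and the DCV engine


def _pooled_ner_per_candidate(labels_pred: np.ndarray, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).ravel()
    pos, neg = y == 1, y == 0
    n1, n0 = pos.sum(), neg.sum()
    se = (labels_pred[pos] == 1).sum(axis=0) / n1
    sp = (labels_pred[neg] == 0).sum(axis=0) / n0
    return (sp + se) / 2


def inner_select(
    X,
    y,
    builder: ModelBuilder,
    inner_segments: int,
    rng: np.random.Generator,
) -> tuple[int, np.ndarray]:
    """Pick the candidate with the best pooled inner-CV NER.

    Returns ``(best_index, ner_per_candidate)``; ties go to the first
    (simplest) candidate in the builder's ordering.
    """
    y = np.asarray(y).ravel()
    n = y.size
    k = min(inner_segments, n)
    part = make_partition(n, k, y, rng)
    n_cand = len(builder.candidates)
    pooled = np.zeros((n, n_cand), dtype=int)
    for seg in range(k):
        te = part == seg
        tr = ~te
        path = builder.fit_path(_rows(X, tr), y[tr])
        pooled[te] = path.predict_labels(_rows(X, te))
    ner = _pooled_ner_per_candidate(pooled, y)
    return int(np.argmax(ner)), ner


def dcv_run(
    X,
    y,
    builder: ModelBuilder,
    cfg: DCVConfig,
    collect_vip: bool = False,
) -> DCVResult:
    """Run repeated double cross-validation.

    `X` is a matrix or a tuple of block matrices (for SO-PLS builders);
    rows must already be through any stateless row-wise pretreatment.
    Column statistics, thresholds and component counts are (re)fitted
    inside each outer-training set. The master seed spawns one child
    stream per repetition, so repetitions are independently reproducible.
    """
    y = np.asarray(y).ravel().astype(int)
    n = _n_rows(X)
    if n != y.size:
        raise ValueError("X rows and y length differ")
    reps = cfg.repetitions
    sp = np.empty(reps)
    se = np.empty(reps)
    ner = np.empty(reps)
    auc = np.empty(reps)
    predictions = np.empty((reps, n))
    pred_labels = np.empty((reps, n), dtype=int)
    selected: list[list] = []
    vip_sum = None
    vip_n = 0

    children = np.random.SeedSequence(cfg.seed).spawn(reps)
    for r in range(reps):
        rng = np.random.default_rng(children[r])
        k_outer = min(cfg.outer_segments, n)
        outer = make_partition(n, k_outer, y, rng)
        chosen: list = []
        for seg in range(k_outer):
            te = outer == seg
            tr = ~te
            try:
                best_idx, _ = inner_select(
                    _rows(X, tr), y[tr], builder, cfg.inner_segments, rng
                )
                path = builder.fit_path(_rows(X, tr), y[tr])
                predictions[r, te] = path.decision(_rows(X, te))[:, best_idx]
                pred_labels[r, te] = path.predict_labels(_rows(X, te))[:, best_idx]
            except Exception as exc:
                raise RuntimeError(f"DCV failure at repetition {r}, fold {seg}: {exc}") from exc
            chosen.append(builder.candidates[best_idx])
            if collect_vip:
                v = path.vip(best_idx)
                if v is not None:
                    vip_sum = v if vip_sum is None else vip_sum + v
                    vip_n += 1
        selected.append(chosen)
        sp[r], se[r], ner[r] = sp_se_ner(confusion_from_labels(y, pred_labels[r]))
        auc[r] = auroc(predictions[r], y)

    vip_mean = vip_sum / vip_n if vip_sum is not None and vip_n else None
    return DCVResult(sp, se, ner, auc, predictions, pred_labels, y, selected, vip_mean, vip_n)
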