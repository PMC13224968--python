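"""Discrimination and calibration metrics for censored predictions.

Implements Harrell's concordance index, the Graf inverse-probability-of-
censoring-weighted (IPCW) Brier score and its time-integrated version, and
the k-fold cross-validation harness comparing the linear and network AFT
models.

Conventions
-----------
* C-index scores: larger score = longer predicted survival.  Pairs (i, j)
  with ``t_i < t_j`` and ``event_i = 1`` are comparable; score ties count
  0.5; time-tied pairs are not comparable.
* IPCW uses the Kaplan-Meier estimate of the censoring survival G, with
  left limits G(t-) at event times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ffn import FFNConfig, FFNWeibullAFT
from .linear import LinearWeibullAFT

__all__ = [
    "concordance_index",
    "km_censoring_survival",
    "CensoringSurvival",
    "brier_score",
    "integrated_brier_score",
    "default_time_grid",
    "cross_validate",
    "CVResult",
    "FeatureStandardizer",
]


def concordance_index(time, event, scores) -> float:
    """Harrell's C: concordant fraction over comparable pairs.

    ``scores`` rank subjects with larger = later predicted event (e.g. the
    predicted log scale).  Raises if no pair is comparable.
    """
    t = np.asarray(time, dtype=float).ravel()
    d = np.asarray(event).astype(int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if not (t.shape == d.shape == s.shape):
        raise ValueError("time, event and scores must have equal length")
    # comparable: t_i < t_j and the earlier subject had the event
    lt = t[:, None] < t[None, :]
    comp = lt & (d[:, None] == 1)
    n_comp = int(comp.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs (all times tied or no events)")
    si, sj = np.broadcast_arrays(s[:, None], s[None, :])
    concordant = (si < sj) & comp
    tied = (si == sj) & comp
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


class CensoringSurvival:
    """Kaplan-Meier estimate G(t) of the censoring survival function.

    Censorings play the role of events; subjects whose outcome event occurs
    at the same time are still counted at risk (events-before-censorings
    tie convention).  Callable; ``left=True`` gives the left limit G(t-).
    """

    def __init__(self, times, censor_counts, at_risk):
        self.times = np.asarray(times, dtype=float)
        with np.errstate(invalid="ignore"):
            factors = 1.0 - np.asarray(censor_counts) / np.asarray(at_risk)
        self.surv = np.cumprod(factors)

    def __call__(self, t, left: bool = False):
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:  # no censoring anywhere: G == 1
            out = np.ones_like(t, dtype=float)
            return float(out) if out.ndim == 0 else out
        if left:
            idx = np.searchsorted(self.times, t, side="left") - 1
        else:
            idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.surv[np.clip(idx, 0, None)], 1.0)
        return float(out) if out.ndim == 0 else out


def km_censoring_survival(time, event) -> CensoringSurvival:
    """Reverse Kaplan-Meier: G(0)=1, steps down at censoring times."""
    t = np.asarray(time, dtype=float).ravel()
    d = np.asarray(event).astype(int).ravel()
    if t.size == 0:
        raise ValueError("empty cohort")
    uniq = np.unique(t)
    cens = np.array([np.sum((t == u) & (d == 0)) for u in uniq])
    at_risk = np.array([np.sum(t >= u) for u in uniq])
    keep = cens > 0
    return CensoringSurvival(uniq[keep], cens[keep], at_risk[keep])


def brier_score(t_star, time, event, surv_prob, censoring=None) -> float:
    """Graf IPCW Brier score at horizon ``t_star``.

    Subjects with an event by ``t_star`` contribute ``S_hat^2 / G(t_i-)``;
    subjects still under observation past ``t_star`` contribute
    ``(1 - S_hat)^2 / G(t_star)``; subjects censored before ``t_star``
    contribute 0.  Mean over all subjects.
    """
    t = np.asarray(time, dtype=float).ravel()
    d = np.asarray(event).astype(int).ravel()
    s_hat = np.asarray(surv_prob, dtype=float).ravel()
    if np.any((s_hat < 0) | (s_hat > 1)):
        raise ValueError("predicted survival probabilities must lie in [0, 1]")
    if s_hat.shape != t.shape:
        raise ValueError("one prediction per subject required")
    G = censoring if censoring is not None else km_censoring_survival(t, d)
    dead = (t <= t_star) & (d == 1)
    alive = t > t_star
    contrib = np.zeros_like(s_hat)
    if dead.any():
        g_dead = G(t[dead], left=True)
        if np.any(g_dead <= 0):
            raise ValueError(
                "censoring survival G(t-)=0 at an event before t_star; "
                "choose a smaller evaluation horizon"
            )
        contrib[dead] = s_hat[dead] ** 2 / g_dead
    if alive.any():
        g_star = G(t_star)
        if g_star <= 0:
            raise ValueError(
                "censoring survival G(t_star)=0; choose a smaller horizon"
            )
        contrib[alive] = (1.0 - s_hat[alive]) ** 2 / g_star
    return float(contrib.mean())


def default_time_grid(time, n_points: int = 100, lo: float = 0.05, hi: float = 0.95):
    """Evaluation grid: `n_points` equispaced between time quantiles."""
    t = np.asarray(time, dtype=float)
    a, b = np.quantile(t, [lo, hi])
    if b <= a:
        b = a + max(a, 1.0) * 1e-6
    return np.linspace(a, b, n_points)


def integrated_brier_score(time, event, surv_matrix, time_grid, censoring=None) -> float:
    """Trapezoidal integral of BS(t) over the grid, divided by the span."""
    grid = np.asarray(time_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty time grid")
    S = np.asarray(surv_matrix, dtype=float)
    if S.ndim != 2 or S.shape[1] != grid.size:
        raise ValueError("surv_matrix must be (n_subjects, n_grid)")
    if censoring is None:
        censoring = km_censoring_survival(time, event)
    bs = np.array(
        [brier_score(tj, time, event, S[:, j], censoring) for j, tj in enumerate(grid)]
    )
    if grid.size == 1:
        return float(bs[0])
    return float(np.trapezoid(bs, grid) / (grid[-1] - grid[0]))


# ----------------------------------------------------------------------
class FeatureStandardizer:
    """Standardize continuous columns on the training fold only.

    Columns whose training values are all in {0, 1} are treated as binary
    indicators and passed through untouched; other columns are centered and
    scaled to unit training-fold variance.
    """

    def __init__(self):
        self.mean_ = None
        self.scale_ = None
        self.continuous_ = None

    def fit(self, X):
        X = np.asarray(X, dtype=float)
        is_binary = np.array(
            [np.all(np.isin(X[:, j], (0.0, 1.0))) for j in range(X.shape[1])]
        )
        self.continuous_ = ~is_binary
        self.mean_ = np.where(self.continuous_, X.mean(axis=0), 0.0)
        sd = X.std(axis=0, ddof=0)
        self.scale_ = np.where(self.continuous_ & (sd > 0), sd, 1.0)
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X):
        return self.fit(X).transform(X)


@dataclass
class CVResult:
    """Per-fold cross-validation metrics plus their mean/std summary."""

    frame: pd.DataFrame  # columns: fold, split, model, c_index, ibs
    model_kind: str
    k: int
    seed: int | None = None

    def summary(self) -> pd.DataFrame:
        """Wide layout: one row per fold plus Mean and Std rows."""
        wide = self.frame.pivot_table(
            index="fold", columns="split", values=["c_index", "ibs"]
        )
        wide.columns = [f"{split}_{metric}" for metric, split in wide.columns]
        wide = wide[[c for c in
                     ("train_c_index", "test_c_index", "train_ibs", "test_ibs")
                     if c in wide.columns]]
        mean = wide.mean(axis=0).rename("Mean")
        std = wide.std(axis=0, ddof=1).rename("Std")
        return pd.concat([wide, mean.to_frame().T, std.to_frame().T])

    def mean_test_c_index(self) -> float:
        sel = self.frame[(self.frame.split == "test")]
        return float(sel.c_index.mean())

    def mean_test_ibs(self) -> float:
        sel = self.frame[(self.frame.split == "test")]
        return float(sel.ibs.mean())

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)


def _fit_eval_fold(cohort, train_idx, test_idx, model_kind, ffn_config, ridge,
                   standardize, seed, grid_points):
    X = cohort.features.to_numpy(dtype=float)
    t, d = cohort.time, cohort.event
    if d[train_idx].sum() == 0 or d[test_idx].sum() == 0:
        raise ValueError("fold with no events; cannot evaluate")
    Xtr, Xte = X[train_idx], X[test_idx]
    if standardize:
        std = FeatureStandardizer().fit(Xtr)
        Xtr, Xte = std.transform(Xtr), std.transform(Xte)
    names = cohort.feature_names
    if model_kind == "linear":
        res = LinearWeibullAFT(t[train_idx], d[train_idx], Xtr,
                               feature_names=names).fit(
            ridge=ridge, compute_bse=False
        )
    elif model_kind == "ffn":
        model = FFNWeibullAFT(t[train_idx], d[train_idx], Xtr, feature_names=names)
        res = model.fit(ffn_config or FFNConfig(), seed=seed)
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")

    rows = []
    for split, idx, Xs in (("train", train_idx, Xtr), ("test", test_idx, Xte)):
        eta = res.predict_log_scale(Xs)
        ci = concordance_index(t[idx], d[idx], eta)
        grid = default_time_grid(t[idx], grid_points)
        S = res.predict_survival(grid, Xs)
        ibs = integrated_brier_score(t[idx], d[idx], S, grid)
        rows.append({"split": split, "c_index": ci, "ibs": ibs})
    return rows, res


def cross_validate(
    cohort,
    model_kind: str,
    folds,
    ffn_config: FFNConfig | None = None,
    ridge: float = 0.0,
    standardize: bool = True,
    seed: int = 0,
    grid_points: int = 100,
) -> CVResult:
    """k-fold cross-validation of an AFT model on a cohort.

    Each fold serves as the test set once; the model is retrained from a
    fresh initialization on the remaining folds.  C-index scores are the
    predicted log scale (larger = later predicted onset); IBS is computed
    from the fitted Weibull survival curves on a per-split time grid.
    """
    records = []
    for fold in range(folds.k):
        train_idx, test_idx = folds.train_test_indices(fold)
        rows, _ = _fit_eval_fold(
            cohort, train_idx, test_idx, model_kind, ffn_config, ridge,
            standardize, seed + fold, grid_points,
        )
        for r in rows:
            records.append({"fold": fold, "model": model_kind, **r})
    frame = pd.DataFrame.from_records(
        records, columns=["fold", "split", "model", "c_index", "ibs"]
    )
    return CVResult(frame=frame, model_kind=model_kind, k=folds.k, seed=seed)
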