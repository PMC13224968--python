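"""Shapley-value attribution of the model's log-scale output.

Both estimators target the *interventional* Shapley value: the value of a
coalition S is the model output with the explained subject's features on S
and background-row features elsewhere, averaged over the background set,

    v(S) = mean_b f(x_S, b_{-S}).

`shapley_exact` enumerates all 2^p coalitions (feasible up to p ~ 15);
`shapley_sampled` is the unbiased permutation-sampling estimator with a
Monte-Carlo standard error per value.  Attributions are in units of the
explained output — here log lam, where larger means later predicted onset,
so a positive value pushes toward lower risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

__all__ = [
    "AttributionResult",
    "shapley_exact",
    "shapley_sampled",
    "explain",
    "mean_abs_importance",
    "beeswarm_table",
    "dependence_table",
]

EXACT_FEATURE_CAP = 15


@dataclass
class AttributionResult:
    """Per-subject, per-feature Shapley values for one explained model.

    Invariant (additivity): for every subject i,
    ``base_value + phi[i].sum() == f(x_i)`` up to numerical / Monte-Carlo
    tolerance.
    """

    phi: np.ndarray              # (n_subjects, n_features)
    base_value: float
    feature_names: list
    values: np.ndarray           # f(x_i), the explained outputs
    mc_stderr: np.ndarray | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def additivity_gap(self) -> np.ndarray:
        """|base + sum(phi) - f(x)| per subject."""
        return np.abs(self.base_value + self.phi.sum(axis=1) - self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, columns=self.feature_names)


def _as_background(background, p):
    B = np.asarray(background, dtype=float)
    if B.ndim == 1:
        B = B[None, :]
    if B.shape[0] == 0:
        raise ValueError("background set is empty")
    if B.shape[1] != p:
        raise ValueError("background width does not match instance")
    return B


def shapley_exact(model_fn, instance, background):
    """Exact interventional Shapley values by coalition enumeration.

    Returns ``(phi, base_value)``.  Cost is O(2^p * n_background) model
    evaluations; refuses p above the cap and points to the sampler.
    """
    x = np.asarray(instance, dtype=float).ravel()
    p = x.size
    if p > EXACT_FEATURE_CAP:
        raise ValueError(
            f"{p} features exceeds the exact-enumeration cap "
            f"({EXACT_FEATURE_CAP}); use shapley_sampled"
        )
    B = _as_background(background, p)
    n_bg = B.shape[0]
    n_masks = 1 << p
    # v(S) for every coalition, vectorized over the background
    v = np.empty(n_masks)
    masks = np.arange(n_masks)
    bits = ((masks[:, None] >> np.arange(p)[None, :]) & 1).astype(bool)
    for m in range(n_masks):
        comp = np.where(bits[m][None, :], x[None, :], B)
        v[m] = float(np.mean(model_fn(comp)))
    size = bits.sum(axis=1)
    w = np.array([factorial(s) * factorial(p - 1 - s) / factorial(p)
                  for s in range(p)])
    phi = np.zeros(p)
    for j in range(p):
        without = masks[~bits[:, j]]
        with_j = without | (1 << j)
        phi[j] = float(np.sum(w[size[without]] * (v[with_j] - v[without])))
    return phi, float(v[0])


def shapley_sampled(model_fn, instance, background, n_permutations: int = 200,
                    seed: int = 0, chunk: int = 16):
    """Permutation-sampling Shapley estimator with Monte-Carlo stderr.

    For each sampled feature ordering the marginal contribution of every
    feature is collected; the estimate is the mean over orderings and the
    reported stderr is the per-feature standard deviation across orderings
    divided by sqrt(n_permutations).  Returns ``(phi, base, stderr)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = np.asarray(instance, dtype=float).ravel()
    p = x.size
    B = _as_background(background, p)
    n_bg = B.shape[0]
    rng = np.random.default_rng(seed)
    base = float(np.mean(model_fn(B)))
    contribs = np.empty((n_permutations, p))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perms = np.stack([rng.permutation(p) for _ in range(m)])  # (m, p)
        # prefix membership masks: (m, p+1, p); level l includes perm[:l]
        member = np.zeros((m, p + 1, p), dtype=bool)
        rows = np.repeat(np.arange(m), p)
        lvls = np.tile(np.arange(1, p + 1), m)
        member[rows, lvls, perms.ravel()] = True
        member = np.cumsum(member, axis=1).astype(bool)
        comp = np.where(member[:, :, None, :], x[None, None, None, :],
                        B[None, None, :, :])  # (m, p+1, n_bg, p)
        vals = np.asarray(model_fn(comp.reshape(-1, p)), dtype=float)
        v = vals.reshape(m, p + 1, n_bg).mean(axis=2)  # (m, p+1)
        marg = np.diff(v, axis=1)                      # (m, p)
        out = np.empty((m, p))
        np.put_along_axis(out, perms, marg, axis=1)
        contribs[done : done + m] = out
        done += m
    phi = contribs.mean(axis=0)
    if n_permutations > 1:
        stderr = contribs.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    else:
        stderr = np.full(p, np.nan)
    return phi, base, stderr


def explain(model_fn, X, background, feature_names=None, method: str = "auto",
            n_permutations: int = 200, seed: int = 0) -> AttributionResult:
    """Attribute every row of X; returns an :class:`AttributionResult`.

    ``method``: "exact", "sampled", or "auto" (exact when the feature count
    is within the enumeration cap).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    if method == "auto":
        method = "exact" if p <= EXACT_FEATURE_CAP else "sampled"
    phi = np.empty((n, p))
    stderr = None
    base = None
    if method == "exact":
        for i in range(n):
            phi[i], base = shapley_exact(model_fn, X[i], background)
    elif method == "sampled":
        stderr = np.empty((n, p))
        for i in range(n):
            phi[i], base, stderr[i] = shapley_sampled(
                model_fn, X[i], background, n_permutations, seed=seed + i
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    values = np.asarray(model_fn(X), dtype=float).ravel()
    return AttributionResult(
        phi=phi, base_value=base, feature_names=list(feature_names),
        values=values, mc_stderr=stderr,
        n_permutations=n_permutations if method == "sampled" else None,
        seed=seed if method == "sampled" else None,
    )


def mean_abs_importance(attribution: AttributionResult) -> pd.DataFrame:
    """Rank features by mean |Shapley value| (descending; name tiebreak)."""
    if attribution.phi.size == 0:
        raise ValueError("empty attribution")
    means = np.abs(attribution.phi).mean(axis=0)
    tab = pd.DataFrame(
        {"feature": attribution.feature_names, "mean_abs_shap": means}
    ).sort_values(
        ["mean_abs_shap", "feature"], ascending=[False, True]
    ).reset_index(drop=True)
    tab.insert(0, "rank", np.arange(1, len(tab) + 1))
    return tab


def beeswarm_table(attribution: AttributionResult, features,
                   top_k: int = 20) -> pd.DataFrame:
    """Long-format (subject, feature, feature_value, shap_value) table.

    One row per subject x feature for the `top_k` features by mean |phi| —
    the data behind a beeswarm plot.
    """
    if isinstance(features, pd.DataFrame):
        Xdf = features[list(attribution.feature_names)]
    else:
        Xdf = pd.DataFrame(np.asarray(features, dtype=float),
                           columns=attribution.feature_names)
    if Xdf.shape[0] != attribution.phi.shape[0]:
        raise ValueError("feature matrix and attribution shapes disagree")
    ranking = mean_abs_importance(attribution)
    top = ranking.feature.head(top_k).tolist()
    col_of = {f: j for j, f in enumerate(attribution.feature_names)}
    rows = []
    for f in top:
        j = col_of[f]
        for i in range(Xdf.shape[0]):
            rows.append(
                (Xdf.index[i], f, float(Xdf.iloc[i, j]),
                 float(attribution.phi[i, j]))
            )
    return pd.DataFrame(rows, columns=["subject", "feature", "feature_value",
                                       "shap_value"])


def dependence_table(attribution: AttributionResult, features, feature: str,
                     interaction_feature: str) -> pd.DataFrame:
    """Per-subject rows for a dependence plot of phi_j vs x_j.

    Columns: feature_value, shap_value, interaction_value (the colouring
    variable).  Row count equals the subject count.
    """
    names = attribution.feature_names
    for f in (feature, interaction_feature):
        if f not in names:
            raise ValueError(f"unknown feature {f!r}")
    if isinstance(features, pd.DataFrame):
        X = features[names].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    j = names.index(feature)
    ji = names.index(interaction_feature)
    return pd.DataFrame(
        {
            "feature_value": X[:, j],
            "shap_value": attribution.phi[:, j],
            "interaction_value": X[:, ji],
        }
    )
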