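"""Importance-ranked incremental feature selection ("feature ladder").

Starting from a fixed clinical/APOE baseline set, features are added in
descending mean-|Shapley| order until each configured total size is
reached; every step retrains the model under the same cross-validation
folds, isolating the effect of the feature set.  Printed step sizes are
*total* feature counts (baseline included).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import cross_validate
from .simulate import BASELINE_FEATURES

__all__ = ["LadderResult", "run_feature_ladder", "DEFAULT_LADDER_SIZES"]

DEFAULT_LADDER_SIZES = (5, 10, 20, 30, 40, None)  # None = all features


@dataclass
class LadderResult:
    """Per-step feature sets and cross-validated metrics."""

    frame: pd.DataFrame  # step_size, n_features, features (list), metrics
    model_kind: str
    baseline_features: tuple

    def feature_sets(self) -> list:
        return [list(f) for f in self.frame["features"]]

    def to_csv(self, path):
        out = self.frame.copy()
        out["features"] = out["features"].map(json.dumps)
        out.to_csv(path, index=False)


def _normalize_ranking(ranking) -> list:
    if isinstance(ranking, pd.DataFrame):
        if "feature" not in ranking.columns:
            raise ValueError("ranking frame needs a 'feature' column")
        return list(ranking["feature"])
    return list(ranking)


def run_feature_ladder(
    cohort,
    ranking,
    folds,
    ladder_sizes=DEFAULT_LADDER_SIZES,
    baseline_features=BASELINE_FEATURES,
    model_kind: str = "ffn",
    ffn_config=None,
    ridge: float = 0.0,
    seed: int = 0,
) -> LadderResult:
    """Retrain under CV at each ladder step; returns a :class:`LadderResult`.

    `ranking` is an ordered feature list (or a frame with a ``feature``
    column) by descending importance; baseline features are excluded from
    the ranking walk since they are always present.  Feature sets are
    nested by construction.
    """
    baseline = [f for f in baseline_features]
    missing = [f for f in baseline if f not in cohort.feature_names]
    if missing:
        raise ValueError(f"baseline feature(s) not in cohort: {missing}")
    ranked = [f for f in _normalize_ranking(ranking) if f not in baseline]
    unknown = [f for f in ranked if f not in cohort.feature_names]
    if unknown:
        raise ValueError(f"unknown feature(s) in ranking: {unknown}")
    non_baseline = [f for f in cohort.feature_names if f not in baseline]
    uncovered = [f for f in non_baseline if f not in ranked]
    if uncovered:
        raise ValueError(f"ranking does not cover feature(s): {uncovered}")

    p_total = len(cohort.feature_names)
    sizes = [p_total if s is None else int(s) for s in ladder_sizes]
    if any(b > a for a, b in zip(sizes[1:], sizes[:-1])):
        raise ValueError("ladder sizes must be increasing")
    if sizes[0] < len(baseline):
        raise ValueError(
            f"first ladder size {sizes[0]} is below the baseline set size "
            f"{len(baseline)}"
        )

    rows = []
    for size in sizes:
        extra = ranked[: max(0, size - len(baseline))]
        feats = baseline + extra
        sub = cohort.select_features(feats)
        cv = cross_validate(sub, model_kind, folds, ffn_config=ffn_config,
                            ridge=ridge, seed=seed)
        test = cv.frame[cv.frame.split == "test"]
        rows.append({
            "step_size": size,
            "n_features": len(feats),
            "features": feats,
            "mean_c_index": float(test.c_index.mean()),
            "std_c_index": float(test.c_index.std(ddof=1)),
            "mean_ibs": float(test.ibs.mean()),
            "std_ibs": float(test.ibs.std(ddof=1)),
        })
    frame = pd.DataFrame(rows)
    # nestedness is structural; assert it anyway as a cheap invariant
    for prev, cur in zip(frame["features"], frame["features"][1:]):
        assert set(prev) <= set(cur)
    return LadderResult(frame=frame, model_kind=model_kind,
                        baseline_features=tuple(baseline))
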