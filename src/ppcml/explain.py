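"""Shapley-value attributions for fitted risk models.

Tree learners (XGBoost, LightGBM) get exact tree-path Shapley values from
the boosters' native contribution predictors, on the margin (log-odds)
scale.  Other learners (LR, SVM) get a seeded permutation-sampling Shapley
estimate against a background sample, also on the log-odds scale, built so
that per-sample additivity (base value + attributions = model output) holds
to floating-point precision.

Pairwise interaction strengths come from the native interaction predictor
for XGBoost models and from a sampled second-difference Shapley-interaction
estimator otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .automl import FittedRiskModel

__all__ = [
    "AttributionMatrix",
    "shap_values",
    "importance_ranking",
    "interaction_matrix",
]

_EPS = 1e-12


@dataclass(frozen=True)
class AttributionMatrix:
    """Signed per-sample, per-feature contributions on the model-output scale."""

    values: np.ndarray  # (n_samples, n_features)
    base_value: float
    feature_names: tuple[str, ...]
    scale: str = "log_odds"

    def model_output(self) -> np.ndarray:
        """Reconstructed model output: base value + per-row attribution sum."""
        return self.base_value + self.values.sum(axis=1)


def _check_columns(model: FittedRiskModel, table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in model.feature_names if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing model features: {missing}")
    return table[model.feature_names]


def _margin_fn(model: FittedRiskModel):
    """Model output as log-odds, defined for every learner type."""

    def f(X: np.ndarray) -> np.ndarray:
        p = np.clip(model.estimator.predict_proba(X)[:, 1], _EPS, 1 - _EPS)
        return np.log(p / (1.0 - p))

    return f


def _tree_contribs(model: FittedRiskModel, X: np.ndarray) -> tuple[np.ndarray, float]:
    if model.model_name == "xgboost":
        import xgboost as xgb

        dm = xgb.DMatrix(X, feature_names=list(model.feature_names))
        contribs = model.estimator.get_booster().predict(dm, pred_contribs=True)
    else:  # lightgbm
        contribs = np.asarray(model.estimator.predict(X, pred_contrib=True))
    # last column is the expected value (bias) term
    return contribs[:, :-1], float(contribs[0, -1])


def _sampling_shap(
    f,
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley values with exact per-sample additivity.

    For each permutation, features are switched one at a time from the
    background to the explained sample; the telescoping sum of output changes
    attributes f(x) - E[f(background)] exactly, so averaging permutations
    preserves additivity identically.
    """
    n, m = X.shape
    b = len(background)
    base = float(f(background).mean())
    values = np.zeros((n, m))
    for _ in range(n_permutations):
        order = rng.permutation(m)
        for i in range(n):
            # (b, m) matrix morphing from background rows to the sample row
            current = background.copy()
            prev = f(current).mean()
            for j in order:
                current[:, j] = X[i, j]
                cur = f(current).mean()
                values[i, j] += cur - prev
                prev = cur
    return values / n_permutations, base


def shap_values(
    model: FittedRiskModel,
    table: pd.DataFrame,
    background: pd.DataFrame | None = None,
    n_permutations: int = 20,
    seed: int = 0,
) -> AttributionMatrix:
    """Shapley attribution matrix for each row of ``table``.

    Exact tree-path values for XGBoost/LightGBM; permutation-sampling
    estimate (against ``background``, default the first 100 rows of
    ``table``) for LR/SVM.  All values are on the log-odds scale and satisfy
    base + row-sum = model output.
    """
    Xdf = _check_columns(model, table)
    X = Xdf.to_numpy(dtype=float)
    if model.model_name in ("xgboost", "lightgbm"):
        values, base = _tree_contribs(model, X)
    else:
        bg = (_check_columns(model, background) if background is not None
              else Xdf.iloc[:100])
        rng = np.random.default_rng(seed)
        values, base = _sampling_shap(
            _margin_fn(model), X, bg.to_numpy(dtype=float), n_permutations, rng
        )
    return AttributionMatrix(
        values=values, base_value=base,
        feature_names=tuple(model.feature_names),
    )


def importance_ranking(attr: AttributionMatrix) -> pd.DataFrame:
    """Features ordered by mean absolute attribution (ties broken by name)."""
    if attr.values.size == 0:
        raise ValueError("attribution matrix is empty")
    mean_abs = np.abs(attr.values).mean(axis=0)
    df = pd.DataFrame({"feature": attr.feature_names, "mean_abs_shap": mean_abs})
    return (
        df.sort_values(["mean_abs_shap", "feature"], ascending=[False, True])
        .reset_index(drop=True)
    )


def _sampled_interactions(
    f,
    X: np.ndarray,
    background: np.ndarray,
    n_subsets: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean |Shapley interaction| estimate via sampled second differences.

    For a pair (i, j) and a random coalition S (drawn from a random
    permutation prefix excluding i, j):
    D = f(S+ij) - f(S+i) - f(S+j) + f(S), averaged over the background.
    """
    n, m = X.shape
    out = np.zeros((m, m))
    for i_row in range(n):
        x = X[i_row]
        for _ in range(n_subsets):
            order = rng.permutation(m)
            cut = rng.integers(0, m + 1)
            S = set(order[:cut].tolist())
            for i in range(m):
                for j in range(i + 1, m):
                    Sij = S - {i, j}
                    rows = []
                    for extra in (Sij, Sij | {i}, Sij | {j}, Sij | {i, j}):
                        mat = background.copy()
                        for k in extra:
                            mat[:, k] = x[k]
                        rows.append(f(mat).mean())
                    d = rows[3] - rows[1] - rows[2] + rows[0]
                    out[i, j] += abs(d) / 2.0
    out /= n * n_subsets
    return out + out.T


def interaction_matrix(
    model: FittedRiskModel,
    table: pd.DataFrame,
    background: pd.DataFrame | None = None,
    n_subsets: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Symmetric feature-interaction strength matrix.

    Diagonal entries are main-effect strengths (mean |Shapley value|),
    off-diagonals are mean |pairwise interaction attribution|.  Exact for
    XGBoost (native interaction predictor); sampled estimate otherwise.
    """
    Xdf = _check_columns(model, table)
    X = Xdf.to_numpy(dtype=float)
    names = list(model.feature_names)
    m = len(names)
    if model.model_name == "xgboost":
        import xgboost as xgb

        dm = xgb.DMatrix(X, feature_names=names)
        inter = model.estimator.get_booster().predict(dm, pred_interactions=True)
        strength = np.abs(inter[:, :m, :m]).mean(axis=0)
    else:
        bg_df = (_check_columns(model, background) if background is not None
                 else Xdf.iloc[:50])
        rng = np.random.default_rng(seed)
        strength = _sampled_interactions(
            _margin_fn(model), X, bg_df.to_numpy(dtype=float), n_subsets, rng
        )
        attr = shap_values(model, table, background=background, seed=seed)
        np.fill_diagonal(strength, np.abs(attr.values).mean(axis=0))
    strength = (strength + strength.T) / 2.0  # enforce exact symmetry
    return pd.DataFrame(strength, index=names, columns=names)
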