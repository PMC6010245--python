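"""The linear fibrosis index: feature selection, fitting and cross-validation.

The index is an ordinary-least-squares regression of the Brunt stage on a
subset of the 100 collagen features, with predictions clamped at zero (the
index is a continuous severity score: never negative, allowed to exceed 4).
Features are chosen by sequential forward selection: starting from the empty
set, the feature whose inclusion most reduces the residual sum of squares of
the OLS fit is added greedily, by default until 14 features are selected.

Validation uses leave-one-out cross-validation: the model is refit n times
on n−1 subjects and scored on the held-out subject.  By default the feature
subset is selected once on the full cohort (mirroring a two-phase
select-then-validate protocol, which leaks the selection step); passing
``reselect_per_fold=True`` re-runs selection inside every fold for a
leakage-free estimate.

:class:`BIndexRegressor` follows the scikit-learn estimator protocol
(``fit`` / ``predict`` / ``get_params``) and composes with sklearn model
selection; :func:`sequential_forward_selection`, :func:`fit_b_index`,
:func:`predict_b_index` and :func:`loocv_predict` are thin functional
wrappers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class SelectionResult:
    """Inclusion order and RSS trajectory of sequential forward selection."""

    features: list[str]
    rss_path: list[float]
    stopping_rule: str = "k_max"

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features in selection")


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _ols(Xd: np.ndarray, y: np.ndarray):
    """OLS with intercept.  Returns (coef_with_intercept, rss) or None if
    the design is singular.  Columns are equilibrated to unit norm before
    the rank test so that wildly different feature scales (percentages vs
    per-mm² counts) cannot masquerade as rank deficiency."""
    design = np.column_stack([np.ones(len(y)), Xd])
    norms = np.linalg.norm(design, axis=0)
    if (norms == 0).any():
        return None
    scaled = design / norms
    if np.linalg.matrix_rank(scaled) < scaled.shape[1]:
        return None
    beta, *_ = np.linalg.lstsq(scaled, y, rcond=None)
    beta = beta / norms
    resid = y - design @ beta
    return beta, float(resid @ resid)


def sequential_forward_selection(
    X,
    y,
    k_max: int = 14,
    rss_tol: float | None = None,
    standardize: bool = True,
) -> SelectionResult:
    """Greedy forward selection under the residual-sum-of-squares criterion.

    At each step the candidate feature minimising the RSS of the OLS fit on
    the current set plus that candidate is added.  Selection stops at
    ``k_max`` features, or earlier if ``rss_tol`` is given and the best
    relative RSS improvement falls below it.  Candidates producing a
    singular design (collinear with the current set) are skipped with a
    warning.  RSS is invariant to column scaling of an OLS fit, so
    standardisation only improves conditioning; it never changes the order.
    """
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if len(Xf) <= k_max:
        raise ValueError("need more samples than k_max")
    cols = list(Xf.columns)
    mat = Xf.to_numpy(dtype=float)
    if standardize:
        mu = mat.mean(axis=0)
        sd = mat.std(axis=0)
        sd[sd == 0] = 1.0
        mat = (mat - mu) / sd

    selected: list[int] = []
    rss_path: list[float] = []
    current_rss = float(np.sum((y - y.mean()) ** 2))
    stopping = "k_max"
    skipped_any = False
    while len(selected) < min(k_max, len(cols)):
        best_j, best_rss = None, np.inf
        for j in range(len(cols)):
            if j in selected:
                continue
            fit = _ols(mat[:, selected + [j]], y)
            if fit is None:
                skipped_any = True
                continue
            if fit[1] < best_rss:
                best_j, best_rss = j, fit[1]
        if best_j is None:
            stopping = "no_admissible_candidate"
            break
        if rss_tol is not None and current_rss > 0:
            if (current_rss - best_rss) / current_rss < rss_tol:
                stopping = "rss_tol"
                break
        selected.append(best_j)
        rss_path.append(best_rss)
        current_rss = best_rss
    if skipped_any:
        warnings.warn(
            "collinear candidate feature(s) skipped during selection",
            stacklevel=2,
        )
    return SelectionResult([cols[j] for j in selected], rss_path, stopping)


class BIndexRegressor(BaseEstimator, RegressorMixin):
    """Clamped-at-zero linear fibrosis index over forward-selected features.

    Parameters
    ----------
    k : int
        Number of features retained by sequential forward selection.
    selected : sequence of str, optional
        Skip selection and fit OLS on exactly these features.
    rss_tol : float, optional
        Early-stopping tolerance on the relative RSS improvement.
    standardize : bool
        Z-score features internally; fitted ``intercept_`` / ``coef_`` are
        always reported on the original feature scale.

    Attributes
    ----------
    selected_features_ : list of str
    intercept_ : float
    coef_ : ndarray, coefficient per selected feature
    selection_ : SelectionResult or None
    """

    def __init__(self, k: int = 14, selected=None, rss_tol: float | None = None,
                 standardize: bool = True):
        self.k = k
        self.selected = selected
        self.rss_tol = rss_tol
        self.standardize = standardize

    def fit(self, X, y):
        Xf = _as_frame(X)
        y = np.asarray(y, dtype=float)
        if len(Xf) != len(y):
            raise ValueError("X and y lengths differ")
        if self.selected is not None:
            names = list(self.selected)
            self.selection_ = None
        else:
            self.selection_ = sequential_forward_selection(
                Xf, y, k_max=self.k, rss_tol=self.rss_tol,
                standardize=self.standardize,
            )
            names = self.selection_.features
        if len(names) >= len(Xf):
            raise ValueError("more selected features than samples")
        mat = Xf.loc[:, names].to_numpy(dtype=float)
        fit = _ols(mat, y)
        if fit is None:
            raise ValueError(
                "singular design on the selected features; remove collinear "
                "columns or select fewer features"
            )
        beta, rss = fit
        self.selected_features_ = names
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.rss_ = rss
        self.n_features_in_ = Xf.shape[1]
        self.feature_names_in_ = np.asarray(Xf.columns)
        return self

    def decision_function(self, X):
        """The unclamped linear score."""
        check_is_fitted(self, "coef_")
        Xf = _as_frame(X)
        missing = [n for n in self.selected_features_ if n not in Xf.columns]
        if missing:
            raise ValueError(f"missing selected features: {missing}")
        mat = Xf.loc[:, self.selected_features_].to_numpy(dtype=float)
        return self.intercept_ + mat @ self.coef_

    def predict(self, X):
        """The fibrosis index: linear score clamped at zero."""
        return np.clip(self.decision_function(X), 0.0, None)

    # -- serialisation ------------------------------------------------
    def to_json(self) -> str:
        check_is_fitted(self, "coef_")
        return json.dumps(
            {
                "intercept": self.intercept_,
                "coefficients": dict(
                    zip(self.selected_features_, self.coef_.tolist())
                ),
                "selection_order": (
                    self.selection_.features if self.selection_ else None
                ),
                "rss_path": self.selection_.rss_path if self.selection_ else None,
                "params": self.get_params(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "BIndexRegressor":
        obj = json.loads(text)
        params = obj.get("params", {})
        params["selected"] = list(obj["coefficients"])
        model = cls(**{k: v for k, v in params.items()
                       if k in ("k", "selected", "rss_tol", "standardize")})
        model.selected_features_ = list(obj["coefficients"])
        model.intercept_ = float(obj["intercept"])
        model.coef_ = np.array(
            [obj["coefficients"][n] for n in model.selected_features_]
        )
        model.selection_ = None
        return model


# -- functional wrappers ---------------------------------------------------

def fit_b_index(X, y, selected) -> BIndexRegressor:
    """OLS fibrosis index on a fixed feature set."""
    return BIndexRegressor(selected=list(selected)).fit(X, y)


def predict_b_index(model: BIndexRegressor, x) -> np.ndarray:
    """Clamped index for one record or a table of records."""
    if isinstance(x, (pd.Series, dict)):
        x = pd.DataFrame([x])
    return model.predict(x)


def loocv_predict(
    X,
    y,
    k: int = 14,
    reselect_per_fold: bool = False,
    rss_tol: float | None = None,
    standardize: bool = True,
) -> np.ndarray:
    """Leave-one-out cross-validated fibrosis indexes, in input order.

    Each subject is scored by a model fit on the other n−1.  With the
    default ``reselect_per_fold=False`` the feature subset is selected once
    on the full table and only the OLS coefficients are refit per fold.
    Folds with a singular design yield NaN with a warning.
    """
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects for leave-one-out")
    fixed = None
    if not reselect_per_fold:
        fixed = sequential_forward_selection(
            Xf, y, k_max=k, rss_tol=rss_tol, standardize=standardize
        ).features
    out = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xtr, ytr = Xf.iloc[mask], y[mask]
        try:
            if fixed is not None:
                model = BIndexRegressor(selected=fixed).fit(Xtr, ytr)
            else:
                model = BIndexRegressor(
                    k=k, rss_tol=rss_tol, standardize=standardize
                ).fit(Xtr, ytr)
            out[i] = model.predict(Xf.iloc[[i]])[0]
        except ValueError:
            warnings.warn(f"singular design in fold {i}; score set to NaN",
                          stacklevel=2)
            out[i] = np.nan
        mask[i] = True
    return out
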